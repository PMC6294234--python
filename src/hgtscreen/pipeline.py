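"""End-to-end orchestration of the transfer-detection cascade.

Stages run in fixed order per locus: homology hits -> conservation filter
-> multi-host filter -> NJ tree with bootstrap -> external-branch-length
filter -> Ks filter -> host-clade placement -> acceptance, followed by the
downstream analyses on accepted loci (closest-host Ka/Ks, branch-model
omega LRT, origin placement, donor-chromosome clustering).  Every
threshold is a named config field defaulting to the screen's canonical
value, and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import homology, origins, trio
from .homology import STAGES, ScreenDecision
from .io_formats import SequenceRecord
from .kaks import align_codons
from .phylo import (
    PlacementResult,
    Tree,
    bootstrap_support,
    branch_length_filter,
    ks_filter,
    placement_test,
)

log = logging.getLogger("hgtscreen.pipeline")


@dataclass
class PipelineConfig:
    """Every screening threshold, as a named field."""

    min_identity_pct: float = 75.0
    min_hit_len: int = 300
    conservation_margin_bits: float = 0.0
    min_host_species: int = 2
    branch_length_factor: float = 2.0
    ks_threshold: float = 1.0
    bootstrap_reps: int = 100
    support_threshold: float = 75.0
    #: relaxed thresholds used only to recover an outgroup homolog for the
    #: gene tree / trio (the outgroup is usually too diverged to clear the
    #: screening thresholds themselves)
    tree_min_identity_pct: float = 50.0
    tree_min_len: int = 100
    require_placement: bool = True
    run_trio: bool = True
    cluster_max_gap: int = 100_000
    seed: int = 0


@dataclass
class ScreenInputs:
    """In-memory inputs of one screening run."""

    transcripts: List[SequenceRecord]
    host_sets: Dict[str, List[SequenceRecord]]
    outgroup_sets: Dict[str, List[SequenceRecord]]
    host_species_tree: Optional[Tree] = None
    homolog_coords: Optional[pd.DataFrame] = None
    _indexes: dict = field(default_factory=dict, repr=False)

    def subject_index(self, kind: str, sp: str) -> homology.SubjectIndex:
        key = (kind, sp)
        if key not in self._indexes:
            sets = self.host_sets if kind == "host" else self.outgroup_sets
            self._indexes[key] = homology.SubjectIndex(sets[sp])
        return self._indexes[key]


@dataclass
class LocusResult:
    decision: ScreenDecision
    tree: Optional[Tree] = None
    closest_host: Optional[str] = None
    kaks = None
    placement: Optional[PlacementResult] = None
    origin: Optional[origins.OriginAssignment] = None
    lrt_p: float = float("nan")


@dataclass
class PipelineReport:
    decisions: List[ScreenDecision]
    results: Dict[str, LocusResult]
    stage_counts: Dict[str, int]
    accepted: pd.DataFrame
    events: Optional[origins.TransferEventSet] = None

    @property
    def accepted_ids(self) -> list:
        return list(self.accepted["locus_id"]) if len(self.accepted) else []

    def decisions_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            rows.append(
                {
                    "locus_id": d.locus_id,
                    "final_stage": d.stage,
                    "verdict": d.verdict,
                    **{f"m_{k}": v for k, v in d.metrics.items()},
                }
            )
        return pd.DataFrame(rows)


def _representative_loci(transcripts, locus_of=None):
    """One representative transcript per locus: the longest."""
    groups: dict = {}
    for rec in transcripts:
        key = locus_of(rec.id) if locus_of else rec.id
        cur = groups.get(key)
        if cur is None or len(rec.seq) > len(cur.seq):
            groups[key] = rec
    return groups


def screen_locus(
    rec: SequenceRecord,
    inputs: ScreenInputs,
    config: PipelineConfig,
    locus_seed: int = 0,
) -> LocusResult:
    """Run the full per-locus cascade and record the verdict trail."""
    d = ScreenDecision(locus_id=rec.id)
    out = LocusResult(decision=d)
    host_hits = []
    for sp in sorted(inputs.host_sets):
        host_hits.extend(
            homology.find_hits(
                rec, inputs.subject_index("host", sp),
                config.min_identity_pct, config.min_hit_len,
            )
        )
    if not d.record("blast_hit", bool(host_hits), n_host_hits=len(host_hits)):
        return out
    outgroup_hits = []
    for sp in sorted(inputs.outgroup_sets):
        outgroup_hits.extend(
            homology.find_hits(
                rec, inputs.subject_index("outgroup", sp),
                config.min_identity_pct, config.min_hit_len,
            )
        )
    passed = homology.conservation_filter(
        host_hits, outgroup_hits, config.conservation_margin_bits
    )
    if not d.record(
        "conservation",
        passed,
        best_host_bits=homology.best_bits(host_hits),
        best_outgroup_bits=homology.best_bits(outgroup_hits),
    ):
        return out
    n_sp = len({h.subject_species for h in host_hits})
    if not d.record(
        "multi_host",
        homology.multi_host_filter(host_hits, config.min_host_species),
        n_host_species=n_sp,
    ):
        return out
    # per-species best subject sequences for the gene tree
    by_sp = homology.hits_by_species(host_hits)
    subj_recs = []
    seq_of = {
        r.id: r for subjects in inputs.host_sets.values() for r in subjects
    }
    for sp in sorted(by_sp):
        best = max(by_sp[sp], key=lambda h: h.score_bits)
        subj_recs.append(seq_of[best.subject_id])
    # outgroup homolog for the gene tree, recovered at relaxed thresholds
    out_rec = None
    oseq_of = {
        r.id: r for subjects in inputs.outgroup_sets.values() for r in subjects
    }
    tree_out_hits = list(outgroup_hits)
    if not tree_out_hits:
        for sp in sorted(inputs.outgroup_sets):
            tree_out_hits.extend(
                homology.find_hits(
                    rec, inputs.subject_index("outgroup", sp),
                    config.tree_min_identity_pct, config.tree_min_len,
                )
            )
    if tree_out_hits:
        best_o = max(tree_out_hits, key=lambda h: h.score_bits)
        out_rec = oseq_of[best_o.subject_id]
    tree = None
    if len(subj_recs) + (1 if out_rec else 0) >= 2:
        members = [rec] + subj_recs + ([out_rec] if out_rec else [])
        try:
            aln = align_codons(members)
            tree = bootstrap_support(
                aln, n_reps=config.bootstrap_reps, seed=locus_seed
            )
        except ValueError as exc:
            log.warning("locus %s: tree failed (%s)", rec.id, exc)
            d.record("branch_length", False, tree_error=1.0)
            return out
    out.tree = tree
    host_tip_names = [r.id for r in subj_recs]
    if tree is not None and len(host_tip_names) >= 2:
        passed, place = branch_length_filter(
            tree, rec.id, host_tip_names, config.branch_length_factor
        )
        out.placement = place
        if not d.record(
            "branch_length",
            passed,
            external_branch=place.external_branch_len,
            longest_host_branch=place.longest_host_branch,
        ):
            return out
    else:
        d.record("branch_length", True)
    passed, closest, res = ks_filter(rec, subj_recs, config.ks_threshold)
    out.closest_host = closest
    out.kaks = res
    if not d.record(
        "ks",
        passed,
        ks=res.Ks if res else float("inf"),
        ka=res.Ka if res else float("nan"),
    ):
        return out
    if config.require_placement and tree is not None and out_rec is not None:
        place = placement_test(
            tree, rec.id, host_tip_names, [out_rec.id]
        )
        out.placement = place
        if not d.record(
            "placement",
            bool(place.nested_in_host_clade),
            nested=float(bool(place.nested_in_host_clade)),
        ):
            return out
    else:
        # no outgroup homolog in the tree: the Ks evidence stands alone
        d.record("placement", True, nested=float("nan"))
    d.record("accepted", True)
    # downstream: branch-model omega LRT on the trio
    if config.run_trio and closest is not None and out_rec is not None:
        try:
            host_rec = seq_of[closest]
            taln = align_codons([rec, host_rec, out_rec])
            _, _, lrt = trio.fit_branch_models(taln, hgt_index=0)
            out.lrt_p = lrt.p_value
        except ValueError as exc:
            log.warning("locus %s: trio fit failed (%s)", rec.id, exc)
    return out


def run_screen(
    inputs: ScreenInputs,
    config: Optional[PipelineConfig] = None,
    locus_of=None,
) -> PipelineReport:
    """Screen every locus and assemble the pipeline report.

    Stage counts are the number of loci surviving each stage, so they are
    weakly decreasing along the cascade.
    """
    config = config or PipelineConfig()
    reps = _representative_loci(inputs.transcripts, locus_of)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 99)))
    decisions, results = [], {}
    for i, (locus, rec) in enumerate(sorted(reps.items())):
        locus_seed = int(rng.integers(0, 2**31 - 1))
        res = screen_locus(rec, inputs, config, locus_seed=locus_seed)
        decisions.append(res.decision)
        results[locus] = res
    stage_counts = {"input": len(reps)}
    for stage in STAGES:
        stage_counts[stage] = sum(
            1
            for d in decisions
            if _passed_stage(d, stage)
        )
    accepted_rows = []
    species_tree = inputs.host_species_tree
    for locus, res in sorted(results.items()):
        if not res.decision.accepted:
            continue
        origin = None
        if species_tree is not None and res.tree is not None:
            try:
                outg = [
                    r.id
                    for subjects in inputs.outgroup_sets.values()
                    for r in subjects
                    if r.id in set(res.tree.tip_names())
                ]
                closest_sp = (
                    res.closest_host.split("|", 1)[0]
                    if res.closest_host
                    else None
                )
                origin = origins.assign_origin(
                    res.tree,
                    species_tree,
                    locus,
                    outgroup_tips=outg,
                    support_threshold=config.support_threshold,
                    gene_id=locus,
                    closest_species=closest_sp,
                )
                res.origin = origin
            except (KeyError, ValueError) as exc:
                log.warning("locus %s: origin failed (%s)", locus, exc)
        r = res.kaks
        accepted_rows.append(
            {
                "locus_id": locus,
                "closest_host": res.closest_host,
                "Ks": r.Ks if r else float("nan"),
                "Ka": r.Ka if r else float("nan"),
                "Ka_Ks": r.ratio if r else float("nan"),
                "origin_branch": origin.branch if origin else None,
                "origin_upper_bound": origin.upper_bound_node if origin else None,
                "origin_ambiguous": origin.ambiguous if origin else None,
                "lrt_p": res.lrt_p,
            }
        )
    accepted = pd.DataFrame(
        accepted_rows,
        columns=[
            "locus_id", "closest_host", "Ks", "Ka", "Ka_Ks", "origin_branch",
            "origin_upper_bound", "origin_ambiguous", "lrt_p",
        ],
    )
    events = None
    if inputs.homolog_coords is not None and len(accepted):
        fams = {
            locus: results[locus].closest_host.split("|", 1)[-1]
            for locus in accepted["locus_id"]
            if results[locus].closest_host
        }
        coords = inputs.homolog_coords
        sel = coords[coords["gene_id"].isin(set(fams.values()))]
        ranks = dict(zip(coords["gene_id"], coords["rank"]))
        if len(sel):
            events = origins.detect_clusters(
                sel, max_gap=config.cluster_max_gap, gene_ranks=ranks
            )
            cluster_of = {}
            for ci, cl in enumerate(events.clusters):
                for g in cl["members"]:
                    cluster_of[g] = ci
            accepted["cluster_id"] = [
                cluster_of.get(fams.get(l)) for l in accepted["locus_id"]
            ]
    return PipelineReport(
        decisions=decisions,
        results=results,
        stage_counts=stage_counts,
        accepted=accepted,
        events=events,
    )


def _passed_stage(d: ScreenDecision, stage: str) -> bool:
    order = {s: i for i, s in enumerate(STAGES)}
    reached = order[d.stage]
    want = order[stage]
    if reached > want:
        return True
    if reached == want:
        return d.verdict == "pass"
    return False


def run_reverse_direction(
    inputs: ScreenInputs,
    config: Optional[PipelineConfig] = None,
    species: Optional[Sequence[str]] = None,
) -> Dict[str, PipelineReport]:
    """Screen in the opposite direction (parasite-to-host transfer).

    For each host species its CDS set becomes the query transcript set,
    the parasite-side family (parasite transcripts + outgroup) plays the
    host-family role, and the remaining host species act as the vertical
    reference against which conservation is judged.
    """
    config = config or PipelineConfig()
    parasite_side = {
        "parasite": inputs.transcripts,
        **inputs.outgroup_sets,
    }
    reports = {}
    chosen = set(species) if species is not None else set(inputs.host_sets)
    for sp, queries in sorted(inputs.host_sets.items()):
        if sp not in chosen:
            continue
        others = {
            osp: recs for osp, recs in inputs.host_sets.items() if osp != sp
        }
        sub = ScreenInputs(
            transcripts=queries,
            host_sets=parasite_side,
            outgroup_sets=others,
        )
        reports[sp] = run_screen(sub, config)
    return reports
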