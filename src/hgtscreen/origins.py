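"""Placing transfer origins on the host species tree and counting
transfer events from donor-chromosome clustering.

A transfer's origin branch is the species-tree edge subtending exactly
the host taxa that form the transferred gene's sister group in its gene
tree; the upper (older) time bound is the speciation at the top of that
edge and the lower (younger) bound is always the present, because the
true donor may be an unsampled close relative of the sampled sister.

Genes whose homologs sit close together on a donor chromosome (interval
gap below a threshold, or adjacent gene ranks in the donor annotation)
are merged into one putative transfer event by single-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Optional, Sequence, Tuple

import pandas as pd

from .phylo import Tree


@dataclass
class OriginAssignment:
    gene_id: str
    branch: Optional[str]  # species-tree edge, named by its child node
    upper_bound_node: Optional[str]
    lower_bound: str = "present"
    ambiguous: bool = False
    candidate_branches: tuple = ()
    sister_species: tuple = ()


@dataclass
class TransferEventSet:
    clusters: list  # of dicts: chromosome, members, span_bp

    @property
    def n_events(self) -> int:
        return len(self.clusters)


def _default_species_of(tip: str) -> str:
    return tip.split("|", 1)[0]


def assign_origin(
    gene_tree: Tree,
    host_species_tree: Tree,
    parasite_tip: str,
    outgroup_tips: Sequence[str] = (),
    species_of: Callable[[str], str] = _default_species_of,
    support_threshold: float = 75.0,
    gene_id: Optional[str] = None,
    closest_species: Optional[str] = None,
) -> OriginAssignment:
    """Place one transferred gene's origin on the host species tree.

    The gene tree is rooted on the outgroup; the species set of the
    parasite gene's sister group is looked up as a clade of the species
    tree.  A monophyletic sister group maps to a unique branch; a
    non-monophyletic one, or an attachment with bootstrap support below
    the threshold, yields an ambiguous assignment whose candidates are the
    branches inside the smallest species-tree clade containing the sister
    species.

    When ``closest_species`` (the minimum-Ks host) is given and falls
    outside the tree-derived sister group, the two lines of evidence
    disagree and the assignment is likewise flagged ambiguous, with the
    candidate region widened to contain both.
    """
    gene_id = gene_id or parasite_tip
    names = set(gene_tree.tip_names())
    og = [o for o in outgroup_tips if o in names]
    t = gene_tree.reroot_on_outgroup(og) if og else gene_tree
    host_tips = set(host_species_tree.tip_names())
    par = t.find_tip(parasite_tip)
    node = par
    clade = frozenset((parasite_tip,))
    support = None
    while node.parent is not None:
        node = node.parent
        clade = t.tipset(node)
        sister_species = {
            species_of(x) for x in clade - {parasite_tip}
        } & host_tips
        if sister_species:
            support = node.support
            break
    else:
        sister_species = set()
    if not sister_species:
        return OriginAssignment(
            gene_id=gene_id, branch=None, upper_bound_node=None,
            ambiguous=True,
        )
    sister = frozenset(sister_species)
    # find the species-tree node whose tip set is exactly the sister group
    target = None
    containing = host_species_tree.root
    for n in host_species_tree.postorder():
        ts = host_species_tree.tipset(n)
        if ts == sister:
            target = n
            break
    low_support = support is not None and support < support_threshold
    ks_conflict = (
        closest_species is not None
        and closest_species in host_tips
        and closest_species not in sister
    )
    if ks_conflict:
        sister = frozenset(sister | {closest_species})
        target = None
    if target is not None and not low_support:
        parent = target.parent
        return OriginAssignment(
            gene_id=gene_id,
            branch=target.name,
            upper_bound_node=(
                parent.name if parent is not None else host_species_tree.root.name
            ),
            ambiguous=False,
            sister_species=tuple(sorted(sister)),
        )
    # ambiguous: candidates are the branches inside the smallest clade
    # containing every sister species; for a low-support (but
    # monophyletic) attachment the uncertainty is about the attachment
    # edge itself, so the region widens one level up
    if target is not None and low_support:
        containing = target.parent or host_species_tree.root
    else:
        for n in host_species_tree.postorder():
            if sister <= host_species_tree.tipset(n):
                containing = n
                break
    cands = []
    stack = [containing]
    while stack:
        n = stack.pop()
        cands.append(n.name)
        stack.extend(n.children)
    branch = target.name if target is not None else None
    upper = None
    if target is not None and target.parent is not None:
        upper = target.parent.name
    return OriginAssignment(
        gene_id=gene_id,
        branch=branch,
        upper_bound_node=upper,
        ambiguous=True,
        candidate_branches=tuple(sorted(cands)),
        sister_species=tuple(sorted(sister)),
    )


def detect_clusters(
    coords,
    max_gap: int = 100_000,
    gene_ranks: Optional[Dict[str, int]] = None,
) -> TransferEventSet:
    """Cluster transferred genes by donor-chromosome proximity.

    ``coords`` maps gene_id -> (chromosome, start, end), or is a DataFrame
    with those columns.  Single-linkage along each chromosome: two genes
    join one cluster when their interval gap is at most ``max_gap`` or
    (when ``gene_ranks`` is given) their donor-annotation gene ranks are
    adjacent.  Each cluster is one putative transfer event.
    """
    if isinstance(coords, pd.DataFrame):
        if coords["gene_id"].duplicated().any():
            dup = coords.loc[coords["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate coordinates for gene {dup.iloc[0]!r}")
        coords = {
            r.gene_id: (r.chromosome, int(r.start), int(r.end))
            for r in coords.itertuples()
        }
    seen: dict = {}
    for gid, (chrom, start, end) in coords.items():
        if gid in seen:
            raise ValueError(f"duplicate coordinates for gene {gid!r}")
        if end < start:
            raise ValueError(f"gene {gid!r}: end < start")
        seen[gid] = True
    by_chrom: dict = {}
    for gid, (chrom, start, end) in coords.items():
        by_chrom.setdefault(chrom, []).append((start, end, gid))
    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom])
        current = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            gap = cur[0] - prev[1]
            rank_adjacent = False
            if gene_ranks is not None:
                r1, r2 = gene_ranks.get(prev[2]), gene_ranks.get(cur[2])
                rank_adjacent = (
                    r1 is not None and r2 is not None and abs(r2 - r1) <= 1
                )
            if gap <= max_gap or rank_adjacent:
                current.append(cur)
            else:
                clusters.append((chrom, current))
                current = [cur]
        clusters.append((chrom, current))
    out = []
    for chrom, members in clusters:
        span = max(e for _, e, _ in members) - min(s for s, _, _ in members)
        out.append(
            {
                "chromosome": chrom,
                "members": [g for _, _, g in members],
                "span_bp": int(span),
            }
        )
    return TransferEventSet(clusters=out)
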