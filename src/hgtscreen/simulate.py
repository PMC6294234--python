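"""Host-family / outgroup / parasite gene-family simulator.

Emulates the data regime the screen was designed for: a host family of
several taxa whose pairwise synonymous divergence stays below saturation
(max Ks around 0.6), a far more diverged outgroup lineage with the
parasite sister to it, vertically inherited gene families, and injected
HGT events that are either DNA-mediated (genomic copy, introns preserved)
or mRNA-mediated (spliced copy with a poly-A tract).  Short paired-end
reads (90 bp; 500 bp genomic / 200 bp mRNA inserts) can be generated from
any template.

Branch lengths are in expected synonymous substitutions per synonymous
site; coding sequences evolve under a GY94 codon process and introns under
a neutral Jukes-Cantor nucleotide process at a configurable multiple of
the synonymous rate.  A fixed seed makes every artifact bit-for-bit
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import exp
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._codon import CODONS, SENSE, revcomp
from .gy94 import CodonModel, _clock_factor, uniform_freqs
from .io_formats import GeneModel, SequenceRecord, write_fasta, write_fastq, write_gene_models
from .phylo import Node, Tree

DEFAULT_HOST_TREE = (
    "(((H1:0.05,H2:0.05)n1:0.10,(H3:0.05,H4:0.05)n2:0.10)n5:0.15,"
    "((H5:0.05,H6:0.05)n3:0.10,(H7:0.05,H8:0.05)n4:0.10)n6:0.15)hostroot;"
)
DEFAULT_OUTER_TREE = "(hosts:0.45,(outgroup:0.28,parasite:0.28)outpar:0.17)root;"

_BASES = np.array(list("ACGT"))


@dataclass
class CodonModelConfig:
    kappa: float = 2.0
    omega_background: float = 0.2
    codon_freqs: str = "uniform"


@dataclass
class IntronModelConfig:
    n_introns: tuple = (2, 5)  # inclusive uniform draw
    intron_len: tuple = (80, 300)
    rate_multiplier: float = 1.0


@dataclass
class ReadModelConfig:
    read_len: int = 90
    insert_genomic: int = 500
    insert_mrna: int = 200
    #: fractional SD of the insert-size distribution; without dispersion a
    #: fixed insert leaves unsequenced dead zones on short templates
    insert_sd_frac: float = 0.1
    depth: float = 30.0
    error_rate: float = 0.0


@dataclass
class WgdConfig:
    enabled: bool = False
    lineage: Optional[str] = None
    divergence: float = 0.07  # nucleotide divergence of the duplicated copy


@dataclass
class HgtEvent:
    """A single transfer: donor branch, relative age on it, and mode.

    ``age_fraction`` runs from 0 (the branch's child end; the present for
    a terminal donor branch) to 1 (the branch's parent end).  ``mode`` is
    'dna' (genomic copy, introns preserved) or 'mrna' (spliced copy with a
    poly-A tract).  ``linked_group`` marks events transferred together as
    one donor segment; ``recipient`` redirects the copy into a host
    species (parasite-to-host transfer) instead of the parasite.
    """

    family_index: int
    donor_lineage: str
    age_fraction: float
    mode: str = "dna"
    omega_post: Optional[float] = None
    linked_group: Optional[int] = None
    recipient: Optional[str] = None


@dataclass
class SimConfig:
    seed: int = 0
    host_tree: str = DEFAULT_HOST_TREE
    outer_tree: str = DEFAULT_OUTER_TREE
    n_families: int = 100
    n_codons: int = 300
    codon_model: CodonModelConfig = field(default_factory=CodonModelConfig)
    intron_model: IntronModelConfig = field(default_factory=IntronModelConfig)
    hgt_events: list = field(default_factory=list)
    read_model: ReadModelConfig = field(default_factory=ReadModelConfig)
    wgd: WgdConfig = field(default_factory=WgdConfig)
    polya_len: int = 15
    flank_len: int = 300
    #: per-family rate multiplier range for vertical families; spans slow,
    #: conserved genes (the conservation filter's false-positive regime)
    #: through fast ones.  Families carrying an injected event evolve at
    #: rate 1 so the event's nominal donor divergence is realized.
    rate_range: tuple = (0.35, 1.2)


@dataclass
class TruthEntry:
    family: int
    locus_id: str
    is_hgt: bool
    mode: str = ""
    donor_lineage: str = ""
    donor_tip: str = ""
    age: float = 0.0
    expected_donor_ks: float = 0.0
    linked_group: Optional[int] = None
    rate: float = 1.0
    intron_positions: list = field(default_factory=list)
    intron_lengths: list = field(default_factory=list)
    genomic_seq: str = ""
    cds_seq: str = ""


@dataclass
class SimTruth:
    entries: list = field(default_factory=list)

    def hgt_locus_ids(self):
        return [e.locus_id for e in self.entries if e.is_hgt]

    def vertical_locus_ids(self):
        return [e.locus_id for e in self.entries if not e.is_hgt]

    def entry(self, locus_id):
        for e in self.entries:
            if e.locus_id == locus_id:
                return e
        raise KeyError(locus_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": e.family,
                    "locus_id": e.locus_id,
                    "is_hgt": e.is_hgt,
                    "mode": e.mode,
                    "donor_lineage": e.donor_lineage,
                    "donor_tip": e.donor_tip,
                    "age": e.age,
                    "expected_donor_ks": e.expected_donor_ks,
                    "linked_group": e.linked_group,
                    "n_introns": len(e.intron_positions),
                    "intron_positions": ",".join(
                        str(p) for p in e.intron_positions
                    ),
                }
                for e in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# species tree assembly


def build_species_tree(config: SimConfig) -> Tree:
    """Graft the host-family tree into the outer (outgroup+parasite) tree."""
    outer = Tree.from_newick(config.outer_tree)
    host = Tree.from_newick(config.host_tree)
    for tip in outer.tips():
        if tip.name == "hosts":
            host.root.length = tip.length
            host.root.name = host.root.name or "hostroot"
            parent = tip.parent
            parent.children[parent.children.index(tip)] = host.root
            host.root.parent = parent
            break
    else:
        raise ValueError("outer_tree must contain a tip named 'hosts'")
    i = 0
    for n in outer.preorder():
        if not n.is_tip and not n.name:
            n.name = f"b{i}"
            i += 1
        if n.parent is not None:
            if n.length is None:
                raise ValueError(f"branch {n.name!r} has no length")
            if n.length < 0:
                raise ValueError(f"branch {n.name!r} has negative length")
    return outer


def _depth_below(node: Node) -> float:
    """Minimum path length from a node down to any descendant tip."""
    if node.is_tip:
        return 0.0
    return min((c.length or 0.0) + _depth_below(c) for c in node.children)


def _first_tip_below(node: Node) -> str:
    while not node.is_tip:
        node = node.children[0]
    return node.name


# ---------------------------------------------------------------------------
# sequence evolution primitives

_model_cache: dict = {}


def _get_model(kappa: float, omega: float):
    key = (round(kappa, 10), round(omega, 10))
    if key not in _model_cache:
        model = CodonModel(kappa, omega, None, normalize="syn")
        factor = _clock_factor(float(kappa), float(omega), None)
        _model_cache[key] = (model, factor)
    return _model_cache[key]


def _evolve_codons(parent: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    child = parent.copy()
    for c in np.unique(parent):
        idx = np.nonzero(parent == c)[0]
        cum = np.cumsum(P[c])
        child[idx] = np.searchsorted(cum, rng.random(len(idx)))
    return np.minimum(child, 60)


def _evolve_nucs(seq: str, d: float, rng) -> str:
    """Jukes-Cantor evolution of a nucleotide string by distance d."""
    if d <= 0 or not seq:
        return seq
    p = 0.75 * (1.0 - exp(-4.0 * d / 3.0))
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _random_dna(n: int, rng) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _codon_string(idx: np.ndarray) -> str:
    return "".join(CODONS[SENSE[i]] for i in idx)


def build_genomic(cds: str, positions, intron_seqs) -> tuple:
    """Interleave a CDS with introns at the given CDS nucleotide offsets.

    Returns (genomic_seq, exon_intervals) with intervals 0-based half-open
    on the genomic sequence.
    """
    if len(positions) != len(intron_seqs):
        raise ValueError("positions/introns length mismatch")
    pieces, exons = [], []
    prev = 0
    offset = 0
    for pos, intr in zip(positions, intron_seqs):
        pieces.append(cds[prev:pos])
        exons.append((offset, offset + (pos - prev)))
        offset += pos - prev
        pieces.append(intr)
        offset += len(intr)
        prev = pos
    pieces.append(cds[prev:])
    exons.append((offset, offset + len(cds) - prev))
    return "".join(pieces), exons


# ---------------------------------------------------------------------------
# family evolution and HGT injection


@dataclass
class FamilyData:
    """One gene family: sequences at every species-tree node plus introns."""

    family_index: int
    codons: dict  # node name -> codon index array (0..60)
    introns: dict  # node name -> list of intron strings
    intron_positions: list  # CDS nucleotide offsets, shared by the family
    rate: float = 1.0  # family-specific rate multiplier
    hgt: list = field(default_factory=list)  # (event, product dict)

    def cds(self, node: str) -> str:
        return _codon_string(self.codons[node])


def evolve_family(config: SimConfig, family_index: int, tree: Optional[Tree] = None) -> FamilyData:
    """Evolve one gene family along the species tree.

    The root CDS is drawn from the codon frequencies; codons substitute
    under the GY94 process, introns under neutral Jukes-Cantor at
    ``rate_multiplier`` times the synonymous rate.  No indels occur in
    exons.

    When the family carries an injected event (config.hgt_events), the
    donor branch is evolved in two segments split at the transfer point,
    and the point's sequence is stored under the node name
    ``_transfer_point`` so the transferred copy shares the donor lineage's
    realized history up to the event.
    """
    tree = tree or build_species_tree(config)
    cm = config.codon_model
    model, clock = _get_model(cm.kappa, cm.omega_background)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, family_index, 1))
    )
    event_families = {ev.family_index for ev in config.hgt_events}
    lo, hi = config.rate_range
    rate = 1.0 if family_index in event_families else float(
        rng.uniform(lo, hi)
    )
    n = config.n_codons
    root_codons = rng.choice(61, size=n, p=uniform_freqs())
    im = config.intron_model
    n_introns = int(rng.integers(im.n_introns[0], im.n_introns[1] + 1))
    # intron positions with a minimum exon length of 35 nt, so every exon
    # is a usable anchor for reconstruction and splice checks
    min_exon = 35
    span = 3 * n - (n_introns + 1) * min_exon
    if span <= 0:
        raise ValueError("CDS too short for the requested intron count")
    offsets = np.sort(rng.choice(np.arange(span), n_introns, replace=False))
    positions = [
        int(offsets[i] + (i + 1) * min_exon) for i in range(n_introns)
    ]
    root_introns = []
    for _ in range(n_introns):
        ln = int(rng.integers(im.intron_len[0], im.intron_len[1] + 1))
        s = _random_dna(ln, rng)
        root_introns.append("GT" + s[2:-2] + "AG")
    event = next(
        (ev for ev in config.hgt_events if ev.family_index == family_index),
        None,
    )
    codons = {tree.root.name: root_codons}
    introns = {tree.root.name: root_introns}
    for node in tree.preorder():
        if node.parent is None:
            continue
        d = (node.length or 0.0) * rate
        src_codons = codons[node.parent.name]
        src_introns = introns[node.parent.name]
        if event is not None and node.name == event.donor_lineage:
            if not (0.0 <= event.age_fraction <= 1.0):
                raise ValueError(
                    f"age_fraction {event.age_fraction} outside donor branch"
                )
            d_top = d * (1.0 - event.age_fraction)
            P = model.transition(d_top * clock)
            point = _evolve_codons(src_codons, P, rng)
            point_introns = [
                _evolve_nucs(s, im.rate_multiplier * d_top, rng)
                for s in src_introns
            ]
            codons["_transfer_point"] = point
            introns["_transfer_point"] = point_introns
            src_codons, src_introns = point, point_introns
            d = d * event.age_fraction
        P = model.transition(d * clock)
        codons[node.name] = _evolve_codons(src_codons, P, rng)
        introns[node.name] = [
            _evolve_nucs(s, im.rate_multiplier * d, rng) for s in src_introns
        ]
    return FamilyData(family_index, codons, introns, positions, rate=rate)


def inject_hgt(
    family: FamilyData, event: HgtEvent, config: SimConfig, tree: Optional[Tree] = None
) -> dict:
    """Inject one transfer event into an evolved family.

    The donor sequence is taken at ``age_fraction`` along the donor branch
    and then evolves independently for the wall-clock time back to the
    present.  Returns a product dict (cds, genomic, exons, introns,
    truth fields) and records it on the family.
    """
    tree = tree or build_species_tree(config)
    nodes = {n.name: n for n in tree.preorder()}
    if event.donor_lineage not in nodes:
        raise ValueError(f"unknown donor lineage {event.donor_lineage!r}")
    child = nodes[event.donor_lineage]
    if child.parent is None:
        raise ValueError("cannot transfer from the root branch")
    a = event.age_fraction
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"age_fraction {a} outside the donor branch")
    if event.mode not in ("dna", "mrna"):
        raise ValueError(f"unknown transfer mode {event.mode!r}")
    L = child.length or 0.0
    cm = config.codon_model
    model, clock = _get_model(cm.kappa, cm.omega_background)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, family.family_index, 2))
    )
    im = config.intron_model
    # the transfer point shares the donor lineage's realized history: it
    # was stored by evolve_family when it split the donor branch
    if "_transfer_point" not in family.codons:
        raise ValueError(
            "family was evolved without this event; evolve_family must see "
            "the event (via config.hgt_events) so the donor branch is split "
            "at the transfer point"
        )
    point_codons = family.codons["_transfer_point"]
    point_introns = family.introns["_transfer_point"]
    # post-transfer evolution for the wall-clock age of the event
    age = a * L + _depth_below(child)
    omega_post = event.omega_post or cm.omega_background
    pmodel, pclock = _get_model(cm.kappa, omega_post)
    P2 = pmodel.transition(age * pclock)
    final_codons = _evolve_codons(point_codons, P2, rng)
    final_introns = [
        _evolve_nucs(s, im.rate_multiplier * age, rng) for s in point_introns
    ]
    cds = _codon_string(final_codons)
    if event.mode == "dna":
        genomic, exons = build_genomic(
            cds, family.intron_positions, final_introns
        )
        transcript = cds
        positions = list(family.intron_positions)
        lengths = [len(s) for s in final_introns]
    else:  # mrna: spliced copy with a poly-A tract, no introns
        transcript = cds + "A" * config.polya_len
        genomic, exons = transcript, [(0, len(transcript))]
        positions, lengths = [], []
    donor_tip = _first_tip_below(child)
    product = {
        "event": event,
        "cds": cds,
        "transcript": transcript,
        "genomic": genomic,
        "exons": exons,
        "introns": final_introns,
        "intron_positions": positions,
        "intron_lengths": lengths,
        "age": age,
        "donor_tip": donor_tip,
        "expected_donor_ks": a * L + _depth_below(child) + age,
    }
    family.hgt.append(product)
    return product


# ---------------------------------------------------------------------------
# read generation


def generate_reads(
    template: str,
    read_model: ReadModelConfig,
    rng,
    insert: Optional[int] = None,
    id_prefix: str = "read",
    role: str = "genomic_read",
) -> list:
    """Paired-end reads from a template: uniform fragment starts, exact
    insert size, forward/reverse mates, per-base substitution errors."""
    if read_model.depth <= 0:
        raise ValueError("depth must be > 0")
    insert = insert or read_model.insert_genomic
    rl = read_model.read_len
    L = len(template)
    if L < insert:
        warnings.warn(
            f"{id_prefix}: template length {L} < insert {insert}; skipped"
        )
        return []
    n_frags = max(int(round(read_model.depth * L / (2.0 * rl))), 1)
    sd = read_model.insert_sd_frac * insert
    inserts = np.clip(
        np.round(rng.normal(insert, sd, size=n_frags)).astype(int),
        2 * rl,
        L,
    )
    starts = np.array(
        [rng.integers(0, L - ins + 1) for ins in inserts]
    )
    reads = []

    def seq_with_errors(s: str) -> str:
        if read_model.error_rate <= 0:
            return s
        arr = np.array(list(s))
        hits = np.nonzero(rng.random(len(arr)) < read_model.error_rate)[0]
        for i in hits:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr)

    for i, (st, ins) in enumerate(zip(starts, inserts)):
        frag = template[st : st + ins]
        r1 = seq_with_errors(frag[:rl])
        r2 = seq_with_errors(revcomp(frag[-rl:]))
        reads.append(
            SequenceRecord(f"{id_prefix}_{i}/1", "", r1, role=role)
        )
        reads.append(
            SequenceRecord(f"{id_prefix}_{i}/2", "", r2, role=role)
        )
    return reads


# ---------------------------------------------------------------------------
# whole-dataset assembly


@dataclass
class SimulatedData:
    """Everything the pipeline consumes, in memory, plus the ground truth."""

    config: SimConfig
    species_tree: Tree
    host_species: list
    parasite_transcripts: list
    host_cds: dict
    outgroup_cds: dict
    truth: SimTruth
    coords: pd.DataFrame
    families: dict

    def host_species_tree(self) -> Tree:
        return Tree.from_newick(self.config.host_tree)

    def family_of_locus(self, locus_id: str) -> int:
        return self.truth.entry(locus_id).family

    # -- genomic structures ------------------------------------------------

    def host_gene_model(self, species: str, family: int):
        """GeneModel + region sequence for one host gene (gene on a
        per-gene contig with a flanking pad on each side)."""
        fam = self.families[family]
        cds = fam.cds(species)
        genomic, exons = build_genomic(
            cds, fam.intron_positions, fam.introns[species]
        )
        pad = self.config.flank_len
        rng = np.random.default_rng(
            np.random.SeedSequence((self.config.seed, family, 7))
        )
        region = _random_dna(pad, rng) + genomic + _random_dna(pad, rng)
        chrom = f"{species}_fam{family:04d}"
        model = GeneModel(
            gene_id=f"{species}|fam{family:04d}",
            species=species,
            chromosome=chrom,
            strand="+",
            exons=[(a + pad, b + pad) for a, b in exons],
            cds_seq=cds,
        )
        rec = SequenceRecord(chrom, species, region, role="host_cds")
        return model, rec

    def parasite_gene_region(self, locus_id: str) -> tuple:
        """(region sequence, exon intervals on it, transcript) for one
        parasite locus, with flanking pads; used for read generation and
        reconstruction tests."""
        e = self.truth.entry(locus_id)
        fam = self.families[e.family]
        if e.is_hgt:
            product = next(
                p for p in fam.hgt if _locus_id(e.family, True) == locus_id
            )
            genomic, exons = product["genomic"], product["exons"]
            transcript = product["transcript"]
        else:
            cds = fam.cds("parasite")
            genomic, exons = build_genomic(
                cds, fam.intron_positions, fam.introns["parasite"]
            )
            transcript = cds
        pad = self.config.flank_len
        rng = np.random.default_rng(
            np.random.SeedSequence((self.config.seed, e.family, 8))
        )
        region = _random_dna(pad, rng) + genomic + _random_dna(pad, rng)
        exons = [(a + pad, b + pad) for a, b in exons]
        return region, exons, transcript

    def genomic_read_templates(self, locus_ids=None) -> dict:
        """Genomic read templates per locus (incl. WGD duplicates)."""
        ids = locus_ids or [e.locus_id for e in self.truth.entries]
        out = {}
        for lid in ids:
            region, _, _ = self.parasite_gene_region(lid)
            templates = [region]
            w = self.config.wgd
            if w.enabled and w.lineage == "parasite":
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (self.config.seed, self.family_of_locus(lid), 9)
                    )
                )
                templates.append(_evolve_nucs(region, w.divergence, rng))
            out[lid] = templates
        return out

    def reads(self, locus_ids=None, kind: str = "genomic") -> dict:
        """Paired-end reads per locus; kind='genomic' or 'mrna'."""
        rm = self.config.read_model
        out = {}
        if kind == "genomic":
            for lid, templates in self.genomic_read_templates(
                locus_ids
            ).items():
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (self.config.seed, self.family_of_locus(lid), 10)
                    )
                )
                reads = []
                for k, tpl in enumerate(templates):
                    reads.extend(
                        generate_reads(
                            tpl,
                            rm,
                            rng,
                            insert=rm.insert_genomic,
                            id_prefix=f"{lid}_g{k}",
                            role="genomic_read",
                        )
                    )
                out[lid] = reads
        elif kind == "mrna":
            ids = locus_ids or [e.locus_id for e in self.truth.entries]
            for lid in ids:
                _, _, transcript = self.parasite_gene_region(lid)
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (self.config.seed, self.family_of_locus(lid), 11)
                    )
                )
                out[lid] = generate_reads(
                    transcript,
                    rm,
                    rng,
                    insert=rm.insert_mrna,
                    id_prefix=f"{lid}_m",
                    role="mrna_read",
                )
        else:
            raise ValueError(f"unknown read kind {kind!r}")
        return out

    # -- output ------------------------------------------------------------

    def emit(self, outdir):
        """Write every pipeline input under one directory keyed by seed."""
        out = Path(outdir) / f"sim_seed{self.config.seed}"
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.parasite_transcripts, out / "parasite_transcripts.fa")
        hosts_dir = out / "hosts"
        hosts_dir.mkdir(exist_ok=True)
        for sp, recs in self.host_cds.items():
            write_fasta(recs, hosts_dir / f"{sp}.fa")
        for sp, recs in self.outgroup_cds.items():
            write_fasta(recs, out / f"outgroup_{sp}.fa")
        # host gene models for the first host species
        sp = self.host_species[0]
        models, regions = [], []
        for k in sorted(self.families):
            m, r = self.host_gene_model(sp, k)
            models.append(m)
            regions.append(r)
        write_gene_models(models, out / f"{sp}_genes.gff3")
        write_fasta(regions, out / f"{sp}_genome.fa")
        self.coords.to_csv(out / "homolog_coords.tsv", sep="\t", index=False)
        self.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "species_tree.nwk").write_text(
            self.species_tree.to_newick() + "\n"
        )
        hgt_ids = set(self.truth.hgt_locus_ids())
        gread, mread = [], []
        for lid, rs in self.reads(sorted(hgt_ids), kind="genomic").items():
            gread.extend(rs)
        for lid, rs in self.reads(sorted(hgt_ids), kind="mrna").items():
            mread.extend(rs)
        write_fastq(gread, out / "genomic_reads.fastq")
        write_fastq(mread, out / "mrna_reads.fastq")
        return out


def _locus_id(family: int, hgt: bool, recipient: Optional[str] = None) -> str:
    base = f"locus{family:04d}"
    if recipient:
        return f"{recipient}|fam{family:04d}r"
    return base + "h" if hgt else base


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Simulate every input the screening pipeline consumes."""
    tree = build_species_tree(config)
    host_species = Tree.from_newick(config.host_tree).tip_names()
    by_family: dict = {}
    for ev in config.hgt_events:
        if ev.family_index in by_family:
            raise ValueError(
                f"family {ev.family_index} has more than one injected event"
            )
        if not (0 <= ev.family_index < config.n_families):
            raise ValueError(f"event family {ev.family_index} out of range")
        by_family[ev.family_index] = ev
    families: dict = {}
    truth = SimTruth()
    parasite_transcripts = []
    host_cds = {sp: [] for sp in host_species}
    outgroup_cds = {"outgroup": []}
    extra_host_recs: dict = {}
    for k in range(config.n_families):
        fam = evolve_family(config, k, tree)
        families[k] = fam
        for sp in host_species:
            host_cds[sp].append(
                SequenceRecord(
                    f"{sp}|fam{k:04d}", sp, fam.cds(sp), role="host_cds"
                )
            )
        outgroup_cds["outgroup"].append(
            SequenceRecord(
                f"outgroup|fam{k:04d}",
                "outgroup",
                fam.cds("outgroup"),
                role="outgroup_cds",
            )
        )
        vert_id = _locus_id(k, False)
        parasite_transcripts.append(
            SequenceRecord(
                vert_id, "parasite", fam.cds("parasite"),
                role="parasite_transcript",
            )
        )
        truth.entries.append(
            TruthEntry(
                family=k,
                locus_id=vert_id,
                is_hgt=False,
                rate=fam.rate,
                intron_positions=list(fam.intron_positions),
                intron_lengths=[len(s) for s in fam.introns["parasite"]],
                cds_seq=fam.cds("parasite"),
            )
        )
        ev = by_family.get(k)
        if ev is not None:
            product = inject_hgt(fam, ev, config, tree)
            lid = _locus_id(k, True, ev.recipient)
            if ev.recipient:
                extra_host_recs.setdefault(ev.recipient, []).append(
                    SequenceRecord(
                        lid, ev.recipient, product["cds"], role="host_cds"
                    )
                )
            else:
                parasite_transcripts.append(
                    SequenceRecord(
                        lid,
                        "parasite",
                        product["transcript"],
                        role="parasite_transcript",
                    )
                )
            truth.entries.append(
                TruthEntry(
                    family=k,
                    locus_id=lid,
                    is_hgt=True,
                    mode=ev.mode,
                    donor_lineage=ev.donor_lineage,
                    donor_tip=product["donor_tip"],
                    age=product["age"],
                    expected_donor_ks=product["expected_donor_ks"],
                    linked_group=ev.linked_group,
                    intron_positions=product["intron_positions"],
                    intron_lengths=product["intron_lengths"],
                    genomic_seq=product["genomic"],
                    cds_seq=product["cds"],
                )
            )
    for sp, recs in extra_host_recs.items():
        host_cds[sp].extend(recs)
    coords = _assign_coords(config, families, by_family, host_species)
    return SimulatedData(
        config=config,
        species_tree=tree,
        host_species=host_species,
        parasite_transcripts=parasite_transcripts,
        host_cds=host_cds,
        outgroup_cds=outgroup_cds,
        truth=truth,
        coords=coords,
        families=families,
    )


def _assign_coords(config, families, by_family, host_species) -> pd.DataFrame:
    """Virtual donor-annotation coordinates for every family's homolog.

    Unlinked genes are spaced ~150 kb apart; families sharing a
    ``linked_group`` (one transfer event) sit on consecutive gene ranks
    within a few tens of kb, mirroring co-transferred donor segments.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 12)))
    order, seen = [], set()
    groups: dict = {}
    for k, ev in by_family.items():
        if ev.linked_group is not None:
            groups.setdefault(ev.linked_group, []).append(k)
    for k in sorted(families):
        if k in seen:
            continue
        ev = by_family.get(k)
        if ev is not None and ev.linked_group is not None:
            block = sorted(groups[ev.linked_group])
        else:
            block = [k]
        order.append(block)
        seen.update(block)
    # donor homologs are scattered over the annotation: shuffle the block
    # order so event families are not artificially rank-adjacent
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]
    n_chrom = 5
    per_chrom = -(-len(order) // n_chrom)
    rows = []
    ref = host_species[0]
    chrom_i, rank, pos = 0, 0, 50_000
    placed = 0
    for block in order:
        if placed >= per_chrom:
            chrom_i += 1
            rank, pos, placed = 0, 50_000, 0
        for j, k in enumerate(block):
            fam = families[k]
            glen = 3 * config.n_codons + sum(
                len(s) for s in fam.introns[ref]
            )
            if j > 0:
                pos += int(rng.integers(5_000, 20_000))
            rows.append(
                {
                    "gene_id": f"fam{k:04d}",
                    "species": ref,
                    "chromosome": f"chr{chrom_i + 1}",
                    "start": pos,
                    "end": pos + glen,
                    "rank": rank,
                }
            )
            pos += glen
            rank += 1
        pos += int(150_000 + rng.integers(0, 20_000))
        # unsampled annotation genes sit between simulated families, so
        # ranks of distinct blocks are never adjacent
        rank += int(rng.integers(5, 30))
        placed += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stock scenarios


def default_scenario(
    seed: int = 1, n_vertical: int = 100, n_hgt: int = 10
) -> SimConfig:
    """The default study-like scenario: 8 host taxa, 1 outgroup, 1
    parasite; vertical families plus injected transfers whose divergence
    to the closest sampled donor spans Ks 0.05-0.5; two of the transfers
    form one linked two-gene event."""
    events = []
    # (donor branch, age fraction) pairs spanning donor Ks 0.05..0.5;
    # transfer points sit strictly inside their donor branches so the
    # sister group stays identifiable in the gene tree
    placements = [
        ("H1", 0.5, "dna", 1),  # Ks 0.05; linked pair
        ("H1", 0.5, "dna", 1),  # Ks 0.05
        ("H2", 0.75, "mrna", None),  # Ks 0.075
        ("n1", 0.25, "dna", None),  # Ks 0.15
        ("n1", 0.5, "dna", None),  # Ks 0.20
        ("n2", 0.75, "mrna", None),  # Ks 0.25
        ("n3", 0.5, "dna", None),  # Ks 0.20
        ("n5", 0.25, "dna", None),  # Ks 0.375
        ("n6", 0.5, "mrna", None),  # Ks 0.45
        ("n6", 2.0 / 3.0, "dna", None),  # Ks 0.50
    ]
    for i in range(n_hgt):
        donor, a, mode, grp = placements[i % len(placements)]
        events.append(
            HgtEvent(
                family_index=n_vertical + i,
                donor_lineage=donor,
                age_fraction=a,
                mode=mode,
                linked_group=grp,
            )
        )
    return SimConfig(
        seed=seed,
        n_families=n_vertical + n_hgt,
        hgt_events=events,
    )


def wgd_scenario(seed: int = 1, n_families: int = 4) -> SimConfig:
    """Small scenario with a parasite-lineage whole-genome duplication
    (duplicate copies ~7% diverged), used for the coverage-inflation and
    gap-closure-ambiguity signatures."""
    cfg = default_scenario(seed=seed, n_vertical=n_families - 1, n_hgt=1)
    cfg.hgt_events = [
        HgtEvent(
            family_index=n_families - 1,
            donor_lineage="H1",
            age_fraction=0.5,
            mode="dna",
        )
    ]
    cfg.n_families = n_families
    cfg.wgd = WgdConfig(enabled=True, lineage="parasite", divergence=0.07)
    return cfg
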