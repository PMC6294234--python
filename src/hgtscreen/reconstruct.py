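"""Reconstruction of genomic regions of transferred genes from paired-end
reads, and the downstream genomic diagnostics.

``fill_gap`` grows contigs inward from the two exons flanking an intron by
overlap-consensus extension until the two sides meet; duplicated loci
surface as extension branch points and leave the gap open with an
ambiguity flag.  ``splice_check`` verifies each intron by demanding at
least one mRNA read matching the exon-exon junction with a fixed exact
anchor on both sides.  ``orf_integrity`` reports premature stops and
frameshift-causing indels against the host coding sequence, and
``coverage_contamination_check`` compares read depth of transfer
candidates against background genes at 100/95/90% read-identity tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from ._codon import STOP_CODONS, revcomp
from .io_formats import GeneModel, SequenceRecord


@dataclass
class GapFillParams:
    min_overlap: int = 30
    max_mismatch: int = 0
    max_iterations: int = 200
    max_gap: int = 50_000
    min_support: int = 1
    ambiguity_fraction: float = 0.5


@dataclass
class GapFillResult:
    left_contig: str
    right_contig: str
    closed: bool
    gap_seq: str = ""
    iterations: int = 0
    supporting_reads: int = 0
    ambiguous: bool = False


@dataclass
class SpliceStatus:
    intron_index: int
    spliced: bool
    junction_reads: int

    def __post_init__(self):
        assert self.spliced == (self.junction_reads >= 1)


@dataclass
class IntegrityReport:
    premature_stops: int
    frameshift_indels: int

    @property
    def intact(self) -> bool:
        return self.premature_stops == 0 and self.frameshift_indels == 0


@dataclass
class CoverageProfile:
    gene_id: str
    depth_at_identity: Dict[int, float]


# ---------------------------------------------------------------------------
# gap filling


def _read_seqs(reads) -> list:
    return [r.seq if hasattr(r, "seq") else str(r) for r in reads]


def _build_index(seqs: Sequence[str], k: int) -> dict:
    index: dict = {}
    for s in seqs:
        for variant in (s, revcomp(s)):
            for i in range(len(variant) - k + 1):
                index.setdefault(variant[i : i + k], []).append((variant, i))
    return index


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest exact overlap (suffix of left == prefix of right)."""
    for ov in range(min(len(left), len(right)), min_overlap - 1, -1):
        if left[-ov:] == right[:ov]:
            return ov
    return 0


def _extend_once(contig: str, index: dict, params: GapFillParams):
    """One rightward extension step by overlap consensus.

    Returns (extension_string, n_supporting, ambiguous).
    """
    k = params.min_overlap
    seed = contig[-k:]
    extensions = []
    for read, off in sorted(index.get(seed, ())):
        ov = off + k  # read[:ov] should match the contig suffix
        ov_eff = min(ov, len(contig))
        if _mismatches(read[off + k - ov_eff : off + k], contig[-ov_eff:]) > params.max_mismatch:
            continue
        tail = read[off + k :]
        if tail:
            extensions.append(tail)
    if not extensions:
        return "", 0, False
    out = []
    pos = 0
    while True:
        votes: dict = {}
        for e in extensions:
            if len(e) > pos:
                votes[e[pos]] = votes.get(e[pos], 0) + 1
        if not votes:
            break
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        top_base, top = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0
        if top < params.min_support:
            break
        if second > 0 and second >= params.ambiguity_fraction * top:
            return "".join(out), len(extensions), True  # branch point
        out.append(top_base)
        extensions = [e for e in extensions if len(e) > pos and e[pos] == top_base]
        pos += 1
    return "".join(out), len(extensions), False


def fill_gap(
    left_exon: str,
    right_exon: str,
    reads: Iterable,
    params: Optional[GapFillParams] = None,
) -> GapFillResult:
    """Close the genomic gap between two exons using paired-end reads.

    Contigs anchored on both exons are extended toward each other by reads
    overlapping a contig end by at least ``min_overlap`` with at most
    ``max_mismatch`` mismatches; the consensus is the majority base, with
    lexicographic tie-breaking handled as an ambiguity stop.  The gap is
    closed when the two contigs overlap exactly by at least
    ``min_overlap``.
    """
    params = params or GapFillParams()
    if len(left_exon) < params.min_overlap or len(right_exon) < params.min_overlap:
        raise ValueError("exons must be at least min_overlap long")
    seqs = _read_seqs(reads)
    index = _build_index(seqs, params.min_overlap)
    left = left_exon.upper()
    right_rc = revcomp(right_exon.upper())  # extend rightward in rc space
    iterations = 0
    support = 0
    ambiguous = False

    def result(closed: bool, ov: int = 0):
        right = revcomp(right_rc)
        gap = ""
        if closed:
            merged = left + right[ov:]
            gap = merged[len(left_exon) : len(merged) - len(right_exon)]
        return GapFillResult(
            left_contig=left,
            right_contig=right,
            closed=closed,
            gap_seq=gap,
            iterations=iterations,
            supporting_reads=support,
            ambiguous=ambiguous,
        )

    while iterations < params.max_iterations:
        ov = _find_overlap(left, revcomp(right_rc), params.min_overlap)
        if ov:
            return result(True, ov)
        iterations += 1
        grew = 0
        for which in (0, 1):
            contig = left if which == 0 else right_rc
            ext, n, amb = _extend_once(contig, index, params)
            support += n
            if amb:
                ambiguous = True
            if ext:
                grew += len(ext)
                if which == 0:
                    left = contig + ext
                else:
                    right_rc = contig + ext
            if ambiguous:
                return result(False)
        total_new = (len(left) - len(left_exon)) + (len(right_rc) - len(right_exon))
        if grew == 0 or total_new > params.max_gap:
            return result(False)
    return result(False)


# ---------------------------------------------------------------------------
# splice verification


def splice_check(
    genomic_seq: str,
    exons: Sequence[Tuple[int, int]],
    mrna_reads: Iterable,
    anchor: int = 10,
) -> List[SpliceStatus]:
    """Verify intron splicing from mRNA reads.

    For each intron, the exon-exon junction sequence (``anchor`` exact
    nucleotides on each side, as it appears on the spliced transcript) is
    searched in the mRNA reads (both orientations); an intron counts as
    spliced when at least one read contains the full junction.
    """
    seqs = _read_seqs(mrna_reads)
    out = []
    g = genomic_seq.upper()
    for i in range(len(exons) - 1):
        left_end = exons[i][1]
        right_start = exons[i + 1][0]
        junction = (
            g[max(left_end - anchor, exons[i][0]) : left_end]
            + g[right_start : min(right_start + anchor, exons[i + 1][1])]
        )
        count = 0
        jrc = revcomp(junction)
        for s in seqs:
            if junction in s or jrc in s:
                count += 1
        out.append(
            SpliceStatus(intron_index=i, spliced=count >= 1, junction_reads=count)
        )
    return out


# ---------------------------------------------------------------------------
# ORF integrity


def _global_dna_aligner() -> Align.PairwiseAligner:
    # gap penalties deliberately steep: substitution-diverged homologs
    # must not accrue spurious (frameshift-mimicking) gap runs
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -16.0
    aligner.extend_gap_score = -4.0
    return aligner


def orf_integrity(parasite_cds: str, host_cds: str) -> IntegrityReport:
    """Premature stops and frameshift indels in a transferred coding
    sequence, assessed against its host homolog.

    The two sequences are globally aligned at the DNA level; frameshift
    indels are gap runs whose length is not a multiple of 3, and premature
    stops are parasite codons reading as stops in the host-anchored frame
    before the host's final codon.  Substitutions that change amino acids
    are not counted as damage.
    """
    aligner = _global_dna_aligner()
    try:
        aln = aligner.align(host_cds.upper(), parasite_cds.upper())[0]
    except Exception as exc:  # pragma: no cover
        raise ValueError("no alignment found") from exc
    h, p = str(aln[0]), str(aln[1])
    # frameshift indels: gap runs of length not divisible by 3 in either row
    frameshifts = 0
    for row in (h, p):
        run = 0
        for ch in row + "X":
            if ch == "-":
                run += 1
            else:
                if run and run % 3:
                    frameshifts += 1
                run = 0
    # premature stops in the host codon frame
    par_at_host: list = []
    for x, y in zip(h, p):
        if x != "-":
            par_at_host.append(y)
    n_host_codons = len(par_at_host) // 3
    stops = 0
    for k in range(n_host_codons - 1):  # exclude the terminal host codon
        codon = "".join(par_at_host[3 * k : 3 * k + 3])
        if codon in STOP_CODONS:
            stops += 1
    return IntegrityReport(premature_stops=stops, frameshift_indels=frameshifts)


# ---------------------------------------------------------------------------
# intron position conservation


def intron_cds_offsets(gene) -> List[int]:
    """Intron positions as CDS nucleotide offsets (phase-aware)."""
    if isinstance(gene, GeneModel):
        offsets, acc = [], 0
        for a, b in gene.exons[:-1]:
            acc += b - a
            offsets.append(acc)
        return offsets
    cds, positions = gene  # (cds_seq, [offsets]) pair
    return list(positions)


def _cds_of(gene) -> str:
    return gene.cds_seq if isinstance(gene, GeneModel) else gene[0]


def intron_position_conservation(parasite_gene, host_gene) -> Tuple[int, int]:
    """Shared / total intron positions between a reconstructed parasite
    gene and its host homolog.

    Both CDSs are codon-aligned; an intron position is shared when both
    genes interrupt the aligned CDS at the same aligned nucleotide
    coordinate.  ``total`` is the host's intron count.  Accepts GeneModel
    objects or (cds_seq, intron_offsets) pairs.
    """
    from .kaks import align_codons

    p_cds, h_cds = _cds_of(parasite_gene), _cds_of(host_gene)
    aln = align_codons(
        [SequenceRecord("p", "", p_cds), SequenceRecord("h", "", h_cds)]
    )
    rows = aln.rows

    def to_column(row: str, pos: int) -> int:
        seen = 0
        for col, ch in enumerate(row):
            if ch != "-":
                if seen == pos:
                    return col
                seen += 1
        return len(row)

    p_cols = {to_column(rows[0], q) for q in intron_cds_offsets(parasite_gene)}
    h_cols = [to_column(rows[1], q) for q in intron_cds_offsets(host_gene)]
    shared = sum(1 for c in h_cols if c in p_cols)
    return shared, len(h_cols)


# ---------------------------------------------------------------------------
# coverage / contamination diagnostics


def _map_read(seq: str, index: dict, genes: dict, k: int):
    """Best exact-seeded placement of a read; returns (gene, start, matches)."""
    best = None
    for variant in (seq, revcomp(seq)):
        tried = set()
        # sliding (not strided) seed windows: a diverged read still maps
        # as long as any clean k-mer survives anywhere in it
        for i in range(0, len(variant) - k + 1):
            for gene_id, pos in index.get(variant[i : i + k], ()):
                start = pos - i
                key = (gene_id, start)
                if key in tried or start < 0:
                    continue
                tried.add(key)
                target = genes[gene_id]
                if start + len(variant) > len(target):
                    continue
                m = sum(
                    x == y
                    for x, y in zip(variant, target[start : start + len(variant)])
                )
                if best is None or m > best[2]:
                    best = (gene_id, start, m)
    return best


def coverage_contamination_check(
    hgt_genes: Dict[str, str],
    background_genes: Dict[str, str],
    genomic_reads: Iterable,
    identity_tiers: Sequence[int] = (100, 95, 90),
    seed_k: int = 15,
    flag_ratio: float = 0.5,
) -> Tuple[Dict[str, CoverageProfile], bool]:
    """Mean per-base read depth per gene at read-identity tiers, and a
    contamination verdict.

    Each read is placed once (best placement over all genes, exact-seed
    candidates, identity = matches/read length); it contributes coverage
    at every tier whose identity threshold it meets (100 means exactly
    100%, other tiers are strict > thresholds, so depth is non-decreasing
    as identity relaxes).  Contamination is flagged when the median depth
    of transfer candidates falls below ``flag_ratio`` times the median
    background depth at the 100% tier.
    """
    if not background_genes:
        raise ValueError("background gene set is empty")
    genes = {**hgt_genes, **background_genes}
    index: dict = {}
    for gid, s in genes.items():
        for i in range(len(s) - seed_k + 1):
            index.setdefault(s[i : i + seed_k], []).append((gid, i))
    cover = {
        gid: {tier: np.zeros(len(s)) for tier in identity_tiers}
        for gid, s in genes.items()
    }
    for r in genomic_reads:
        seq = r.seq if hasattr(r, "seq") else str(r)
        placed = _map_read(seq, index, genes, seed_k)
        if placed is None:
            continue
        gid, start, matches = placed
        ident = 100.0 * matches / len(seq)
        for tier in identity_tiers:
            ok = ident >= 100.0 if tier == 100 else ident > tier
            if ok:
                cover[gid][tier][start : start + len(seq)] += 1
    profiles = {
        gid: CoverageProfile(
            gene_id=gid,
            depth_at_identity={
                tier: float(cov.mean()) for tier, cov in tiers.items()
            },
        )
        for gid, tiers in cover.items()
    }
    tier0 = identity_tiers[0]
    hgt_med = median(
        profiles[g].depth_at_identity[tier0] for g in hgt_genes
    ) if hgt_genes else 0.0
    bg_med = median(profiles[g].depth_at_identity[tier0] for g in background_genes)
    flagged = bool(hgt_genes) and hgt_med < flag_ratio * bg_med
    return profiles, flagged
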