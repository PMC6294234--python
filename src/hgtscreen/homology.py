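"""Stage 1 of the screening cascade: local-identity homology search and
the conservation and multi-host-species filters.

The internal hit finder is a k-mer-seeded gapped local aligner with
BLASTN-like affine scoring (match +2, mismatch -3, gap open 5, gap extend
2).  A hit qualifies when its identity is strictly above the identity
threshold (default 75%, gap columns counting against identity) over
strictly more than the length threshold (default 300 alignment columns).
Both strands of the subject are searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from ._codon import revcomp
from .io_formats import HomologyHit, SequenceRecord

#: screening stages in cascade order
STAGES = (
    "blast_hit",
    "conservation",
    "multi_host",
    "branch_length",
    "ks",
    "placement",
    "accepted",
)

#: fixed affine transform from raw affine score to a bit-like score
_BITS_PER_RAW = 0.5


@dataclass
class ScreenDecision:
    """Per-locus verdict trail through the screening cascade."""

    locus_id: str
    stage: str = "blast_hit"
    verdict: str = "pass"
    metrics: dict = field(default_factory=dict)
    trail: list = field(default_factory=list)

    def record(self, stage: str, passed: bool, **metrics):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.stage = stage
        self.verdict = "pass" if passed else "fail"
        self.metrics.update(metrics)
        self.trail.append((stage, self.verdict))
        return passed

    @property
    def accepted(self) -> bool:
        return self.stage == "accepted" and self.verdict == "pass"


def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class SubjectIndex:
    """Reusable k-mer index over a subject set (both strands).

    Building the index once per subject collection makes repeated
    ``find_hits`` calls over many queries cheap: a query only pays for
    subjects it genuinely shares seeds with.
    """

    def __init__(self, records: Sequence[SequenceRecord], k: int = 12):
        self.records = list(records)
        self.k = k
        self._index: dict = {}
        for i, rec in enumerate(self.records):
            for strand, seq in ((1, rec.seq), (-1, revcomp(rec.seq))):
                for km in _kmers(seq, k):
                    self._index.setdefault(km, []).append((i, strand))

    def candidates(self, query_seq: str, min_seeds: int = 2) -> dict:
        """(subject index, strand) -> shared seed count, filtered to
        candidates with at least ``min_seeds`` distinct shared k-mers."""
        counts: dict = {}
        for km in _kmers(query_seq, self.k):
            for key in self._index.get(km, ()):
                counts[key] = counts.get(key, 0) + 1
        return {k: v for k, v in counts.items() if v >= min_seeds}


def _min_qualifying_score(min_identity_pct: float, min_len: int) -> float:
    """Lower bound on the local-alignment raw score of any qualifying hit.

    With match +2, mismatch -3 and per-gap-column cost at most 5, a hit
    with identity > f over c > min_len columns scores at least
    (2+5)*f*c - 5*c, minimized at c = min_len + 1.  Non-positive bounds
    disable the shortcut.
    """
    f = min_identity_pct / 100.0
    c = min_len + 1
    return max((7.0 * f - 5.0) * c, 0.0)


def _alignment_stats(aln) -> tuple:
    """(matches, mismatches, gaps, columns) of a pairwise alignment."""
    a, b = str(aln[0]), str(aln[1])
    matches = mismatches = gaps = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, gaps, len(a)


def find_hits(
    query: SequenceRecord,
    subjects: Iterable[SequenceRecord],
    min_identity_pct: float = 75.0,
    min_len: int = 300,
    k: int = 12,
    both_strands: bool = True,
) -> list:
    """Local-homology hits of one query against a set of subject CDSs.

    Subjects sharing no exact k-mer with the query (either strand) are
    skipped; the rest are aligned with the affine local aligner.  Only the
    best local alignment per subject(+strand) is considered, and only hits
    with identity strictly above ``min_identity_pct`` over strictly more
    than ``min_len`` columns are returned.  A query shorter than
    ``min_len`` yields an empty result.
    """
    if len(query.seq) <= min_len:
        return []
    aligner = _dna_aligner()
    if isinstance(subjects, SubjectIndex):
        index = subjects
        if index.k != k:
            raise ValueError("index k-mer size differs from requested k")
    else:
        index = SubjectIndex(list(subjects), k=k)
    score_floor = _min_qualifying_score(min_identity_pct, min_len)
    cands = index.candidates(query.seq)
    by_subject: dict = {}
    for (i, strand), nseeds in cands.items():
        if strand < 0 and not both_strands:
            continue
        by_subject.setdefault(i, []).append((nseeds, strand))
    hits = []
    for i in sorted(by_subject):
        subj = index.records[i]
        best = None
        for _, strand in sorted(by_subject[i], reverse=True):
            sseq = subj.seq if strand > 0 else revcomp(subj.seq)
            score = aligner.score(query.seq, sseq)
            if best is None or score > best[0]:
                best = (score, sseq, strand)
        score, sseq, strand = best
        if score < score_floor:  # cannot contain a qualifying alignment
            continue
        aln = aligner.align(query.seq, sseq)[0]
        matches, mismatches, gaps, cols = _alignment_stats(aln)
        if cols == 0:
            continue
        ident = 100.0 * matches / cols
        if not (ident > min_identity_pct and cols > min_len):
            continue
        (qrange, srange) = aln.aligned
        q_start = int(qrange[0][0]) if len(qrange) else 0
        q_end = int(qrange[-1][1]) if len(qrange) else 0
        s_start = int(srange[0][0]) if len(srange) else 0
        s_end = int(srange[-1][1]) if len(srange) else 0
        if strand < 0:  # report subject coordinates on its forward strand
            L = len(subj.seq)
            s_start, s_end = L - s_end, L - s_start
        hits.append(
            HomologyHit(
                query_id=query.id,
                subject_id=subj.id,
                subject_species=subj.species,
                pct_identity=ident,
                aln_len=cols,
                matches=matches,
                mismatches=mismatches,
                gaps=gaps,
                score_bits=score * _BITS_PER_RAW,
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
            )
        )
    hits.sort(key=lambda h: (-h.score_bits, h.subject_id))
    return hits


def best_bits(hits: Sequence[HomologyHit]) -> float:
    return max((h.score_bits for h in hits), default=0.0)


def conservation_filter(
    host_hits: Sequence[HomologyHit],
    outgroup_hits: Sequence[HomologyHit],
    margin_bits: float = 0.0,
) -> bool:
    """Screen out conserved (vertically explained) loci.

    A locus fails (is conserved, not a transfer candidate) when the best
    outgroup score is at least the best host score minus the margin; the
    tie goes to the vertical explanation.  Returns True when the locus
    survives as an HGT candidate.
    """
    return best_bits(outgroup_hits) + margin_bits < best_bits(host_hits)


def multi_host_filter(host_hits: Sequence[HomologyHit], min_species: int = 2) -> bool:
    """Require qualifying hits in at least ``min_species`` distinct host
    species (species count, not hit count)."""
    return len({h.subject_species for h in host_hits}) >= min_species


def hits_by_species(hits: Sequence[HomologyHit]) -> dict:
    out: dict = {}
    for h in hits:
        out.setdefault(h.subject_species, []).append(h)
    return out
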