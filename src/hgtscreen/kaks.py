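"""Codon-aware alignment and Nei-Gojobori (1986) Ka/Ks with the
Jukes-Cantor multiple-hit correction.

The estimator counts synonymous/nonsynonymous sites per codon (changes to
stop codons count as nonsynonymous, so S + N = 3 per codon), averages
difference counts over all minimal mutational pathways between two codons
(pathways through stops excluded), and corrects the per-site fractions
pS = Sd/S and pN = Nd/N with d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import (
    IS_SENSE,
    ND_TABLE,
    NONSYN_SITES,
    SD_TABLE,
    SYN_SITES,
    encode_codons,
    has_internal_stop,
    translate,
)

_GAP_CODON = "---"


class SaturationError(ValueError):
    """Observed difference fraction at or beyond the Jukes-Cantor limit."""


def jc_correct(p: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 0.75; raises SaturationError at or beyond the
    saturation boundary.
    """
    if p < 0.0:
        raise ValueError(f"difference fraction must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"p={p} >= 0.75: distance undefined (saturated)"
        )
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """Nei-Gojobori site/difference counts and JC-corrected distances."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float
    saturated_s: bool = False
    saturated_n: bool = False
    n_codons_compared: int = 0
    n_codons_skipped: int = 0


@dataclass
class CodonAlignment:
    """A codon-aware multiple alignment; gaps occur in whole-codon units."""

    taxa: list
    rows: list

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3:
            raise ValueError("alignment length not divisible by 3")
        self._codons = None

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def codons(self):
        """Rows encoded as codon-index arrays (-1 for gap/ambiguous)."""
        if self._codons is None:
            self._codons = [encode_codons(r) for r in self.rows]
        return self._codons

    def subset_codons(self, cols: Sequence[int]) -> "CodonAlignment":
        rows = [
            "".join(r[3 * c : 3 * c + 3] for c in cols) for r in self.rows
        ]
        return CodonAlignment(list(self.taxa), rows)

    def pair(self, i: int, j: int):
        return self.codons[i], self.codons[j]


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _prepare(seq) -> tuple:
    """Trim trailing partial codons; reject internal stops."""
    sid = getattr(seq, "id", "seq")
    s = (seq.seq if hasattr(seq, "seq") else str(seq)).upper()
    if len(s) % 3:
        warnings.warn(
            f"{sid}: length {len(s)} not divisible by 3; trailing partial "
            "codon trimmed",
            stacklevel=3,
        )
        s = s[: len(s) - len(s) % 3]
    pos = has_internal_stop(s)
    if pos:
        raise ValueError(f"{sid}: internal stop codon at codon {pos}")
    return sid, s


def _kmer_profile(seq: str, k: int = 4):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_codons(seqs) -> CodonAlignment:
    """Codon alignment by protein-level alignment back-translated to codons.

    Sequences are translated, aligned at the protein level (center-star
    progressive scheme: every sequence is aligned to the center sequence,
    chosen by shared-k-mer similarity, with Needleman-Wunsch/BLOSUM62 and
    affine gaps), and the residue alignment is mapped back onto codons, so
    gaps only ever occupy whole-codon columns.
    """
    ids, dnas = [], []
    for s in seqs:
        sid, dna = _prepare(s)
        ids.append(sid)
        dnas.append(dna)
    if len(dnas) < 2:
        return CodonAlignment(ids, dnas)
    prots = [translate(d) for d in dnas]
    prots = [p[:-1] + "X" if p.endswith("*") else p for p in prots]
    # pick center by mean shared-k-mer similarity
    profs = [_kmer_profile(p) for p in prots]
    center = 0
    if len(prots) > 2:
        best = -1.0
        for i, pi in enumerate(profs):
            sim = sum(
                len(pi & pj) / max(1, min(len(pi), len(pj)))
                for j, pj in enumerate(profs)
                if j != i
            )
            if sim > best:
                best = sim
                center = i
    aligner = _protein_aligner()
    n_center = len(prots[center])
    # per-sequence alignment to the center, as column lists of
    # (center_residue_index_or_None, seq_residue_index_or_None)
    colmaps = {}
    for i, p in enumerate(prots):
        if i == center:
            continue
        aln = aligner.align(prots[center], p)[0]
        ca, sa = str(aln[0]), str(aln[1])
        cols, ci, si = [], 0, 0
        for x, y in zip(ca, sa):
            cols.append(
                (ci if x != "-" else None, si if y != "-" else None)
            )
            if x != "-":
                ci += 1
            if y != "-":
                si += 1
        colmaps[i] = cols
    # merged layout: number of insertion columns before each center residue
    ins_before = [0] * (n_center + 1)
    for cols in colmaps.values():
        run, pos = 0, 0
        for c_idx, _ in cols:
            if c_idx is None:
                run += 1
            else:
                ins_before[pos] = max(ins_before[pos], run)
                run, pos = 0, c_idx + 1
        ins_before[n_center] = max(ins_before[n_center], run)
    total_cols = n_center + sum(ins_before)
    col_of_center = []
    acc = 0
    for c in range(n_center):
        acc += ins_before[c]
        col_of_center.append(acc)
        acc += 1

    def place(i):
        out = [_GAP_CODON] * total_cols
        if i == center:
            for c in range(n_center):
                out[col_of_center[c]] = dnas[i][3 * c : 3 * c + 3]
            return out
        run = []
        pos = 0
        for c_idx, s_idx in colmaps[i]:
            if c_idx is None:
                run.append(s_idx)
            else:
                base = col_of_center[c_idx]
                for k, sidx in enumerate(reversed(run)):
                    if sidx is not None:
                        out[base - 1 - k] = dnas[i][3 * sidx : 3 * sidx + 3]
                run = []
                if s_idx is not None:
                    out[base] = dnas[i][3 * s_idx : 3 * s_idx + 3]
                pos = c_idx + 1
        base = total_cols
        for k, sidx in enumerate(reversed(run)):
            if sidx is not None:
                out[base - 1 - k] = dnas[i][3 * sidx : 3 * sidx + 3]
        return out

    rows = ["".join(place(i)) for i in range(len(dnas))]
    return CodonAlignment(ids, rows)


# ---------------------------------------------------------------------------
# NG86 counting


def _ng86_arrays(a: np.ndarray, b: np.ndarray):
    valid = (a >= 0) & (b >= 0) & IS_SENSE[np.clip(a, 0, 63)] & IS_SENSE[
        np.clip(b, 0, 63)
    ]
    av, bv = a[valid], b[valid]
    sd = SD_TABLE[av, bv]
    nd = ND_TABLE[av, bv]
    ok = ~np.isnan(sd)  # pairs whose every pathway crosses a stop are skipped
    av, bv, sd, nd = av[ok], bv[ok], sd[ok], nd[ok]
    S = 0.5 * (SYN_SITES[av] + SYN_SITES[bv]).sum()
    N = 0.5 * (NONSYN_SITES[av] + NONSYN_SITES[bv]).sum()
    n_used = len(av)
    n_skipped = int(len(a) - n_used)
    return S, N, float(sd.sum()), float(nd.sum()), n_used, n_skipped


def ng86_counts(a, b):
    """Nei-Gojobori site and difference counts for two aligned codon rows.

    Accepts aligned DNA strings or codon-index arrays; gap and ambiguous
    codons are excluded pairwise.  Returns (S, N, Sd, Nd).
    """
    if isinstance(a, str):
        a = encode_codons(a)
    if isinstance(b, str):
        b = encode_codons(b)
    if len(a) != len(b):
        raise ValueError("rows differ in codon length")
    S, N, Sd, Nd, _, _ = _ng86_arrays(np.asarray(a), np.asarray(b))
    return S, N, Sd, Nd


def ka_ks_pair(a: np.ndarray, b: np.ndarray) -> KaKsResult:
    """Ka/Ks from two encoded codon rows (fast path used by the screen)."""
    S, N, Sd, Nd, n_used, n_skipped = _ng86_arrays(
        np.asarray(a), np.asarray(b)
    )
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    sat_s = pS >= 0.75
    sat_n = pN >= 0.75
    Ks = np.inf if sat_s else jc_correct(pS)
    Ka = np.inf if sat_n else jc_correct(pN)
    ratio = Ka / Ks if (Ks > 0 and np.isfinite(Ks)) else np.nan
    return KaKsResult(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        saturated_s=sat_s,
        saturated_n=sat_n,
        n_codons_compared=n_used,
        n_codons_skipped=n_skipped,
    )


def ka_ks(a, b) -> KaKsResult:
    """Ka, Ks and their ratio for two aligned codon rows.

    Ks = jc(Sd/S), Ka = jc(Nd/N); saturated components are set to the
    infinity sentinel with a flag; the ratio is NaN when Ks is 0 or
    saturated.
    """
    if isinstance(a, str):
        a = encode_codons(a)
    if isinstance(b, str):
        b = encode_codons(b)
    if len(a) != len(b):
        raise ValueError("rows differ in codon length")
    return ka_ks_pair(a, b)
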