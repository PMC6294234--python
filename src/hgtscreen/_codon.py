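"""Genetic-code tables shared by the Ka/Ks estimator, the codon simulator
and the codon-model likelihoods.

Codons are encoded as integers in base 4 (A=0, C=1, G=2, T=3), so codon
index = 16*b1 + 4*b2 + b3.  All pairwise Nei-Gojobori quantities are
precomputed once at import into dense 64x64 tables; per-alignment work then
reduces to table lookups over integer codon arrays.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_standard.stop_codons)

#: amino acid per codon index; '*' for stops
AA = np.array(
    ["*" if c in STOP_CODONS else _standard.forward_table[c] for c in CODONS]
)

#: indices of the 61 sense codons of the standard code
SENSE = np.array([i for i, c in enumerate(CODONS) if c not in STOP_CODONS])
SENSE_INDEX = {int(c): k for k, c in enumerate(SENSE)}  # codon idx -> 0..60
IS_SENSE = np.zeros(64, dtype=bool)
IS_SENSE[SENSE] = True

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def encode_codons(seq: str) -> np.ndarray:
    """Encode a DNA string into an int array of codon indices.

    Codons containing characters outside ACGT (N, gaps, ...) encode as -1.
    Trailing bases that do not fill a codon are dropped.
    """
    n = len(seq) // 3
    out = np.empty(n, dtype=np.int64)
    s = seq.upper()
    for k in range(n):
        c = s[3 * k : 3 * k + 3]
        out[k] = CODON_INDEX.get(c, -1)
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)


def _single_change_class(codon: str, pos: int, new_base: str):
    """Classify the mutation codon[pos] -> new_base.

    Returns 'syn', 'nonsyn' or 'stop' (mutation creating a stop codon).
    Mutations *from* a stop codon are never queried here.
    """
    mutant = codon[:pos] + new_base + codon[pos + 1 :]
    if mutant in STOP_CODONS:
        return "stop"
    if _standard.forward_table[mutant] == _standard.forward_table[codon]:
        return "syn"
    return "nonsyn"


def _site_counts():
    """Nei-Gojobori (1986) synonymous site count per sense codon.

    Each codon position contributes s/3 synonymous sites where s is the
    number of the three possible changes at that position that are
    synonymous.  Changes to stop codons count as nonsynonymous, so
    S + N == 3 for every codon.
    """
    syn = np.zeros(64)
    for ci in SENSE:
        codon = CODONS[ci]
        s = 0.0
        for pos in range(3):
            for nb in BASES:
                if nb == codon[pos]:
                    continue
                if _single_change_class(codon, pos, nb) == "syn":
                    s += 1.0
        syn[ci] = s / 3.0
    return syn


SYN_SITES = _site_counts()  # per sense codon; 0 for stops (unused)
NONSYN_SITES = np.where(IS_SENSE, 3.0 - SYN_SITES, 0.0)


def _pathway_counts(a: str, b: str):
    """Average synonymous/nonsynonymous difference counts between two sense
    codons over all minimal mutational pathways, excluding pathways that
    pass through a stop codon (NG86 convention).

    Returns (sd, nd); (nan, nan) if every pathway is blocked by a stop.
    """
    diff_pos = [p for p in range(3) if a[p] != b[p]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = a
        s = n = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _standard.forward_table[cur] == _standard.forward_table[nxt]:
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        if ok:
            total_s += s
            total_n += n
            n_paths += 1
    if n_paths == 0:
        return float("nan"), float("nan")
    return total_s / n_paths, total_n / n_paths


def _pair_tables():
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for ci in SENSE:
        for cj in SENSE:
            if cj < ci:
                sd[ci, cj] = sd[cj, ci]
                nd[ci, cj] = nd[cj, ci]
            else:
                s, n = _pathway_counts(CODONS[ci], CODONS[cj])
                sd[ci, cj] = s
                nd[ci, cj] = n
    return sd, nd


#: NG86 pathway-averaged difference counts, indexed [codon_i, codon_j]
SD_TABLE, ND_TABLE = _pair_tables()

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(seq: str, to_stop: bool = False) -> str:
    """Translate a DNA string; codons with ambiguity translate as 'X'."""
    aas = []
    for k in range(len(seq) // 3):
        c = seq[3 * k : 3 * k + 3].upper()
        i = CODON_INDEX.get(c)
        aa = "X" if i is None else AA[i]
        if to_stop and aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


def has_internal_stop(seq: str) -> int:
    """Return 1-based codon position of the first internal stop, else 0."""
    n = len(seq) // 3
    for k in range(n - 1):
        c = seq[3 * k : 3 * k + 3].upper()
        if c in STOP_CODONS:
            return k + 1
    return 0
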