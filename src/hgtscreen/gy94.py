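"""Goldman-Yang-style (GY94) codon substitution model.

Rates between sense codons differing at exactly one position are
proportional to the target-codon frequency, multiplied by kappa for
transitions and omega for nonsynonymous changes; all other rates are zero
(stop codons are absorbing-excluded).  The matrix is time-reversible, so
transition probabilities come from a symmetrized eigendecomposition.

Branch lengths throughout the simulator are expressed in expected
synonymous substitutions per synonymous site ("Ks units").  The clock is
calibrated numerically so that the expected value of the NG86/JC Ks
estimate between two sequences at nominal divergence 0.3 equals 0.3; see
docs/methods.md for the rationale.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ._codon import (
    AA,
    CODONS,
    SD_TABLE,
    SENSE,
    SYN_SITES,
    is_transition,
)

NSENSE = len(SENSE)  # 61


def _pair_classes():
    """(is_single_change, is_transition, is_synonymous) over sense pairs."""
    single = np.zeros((NSENSE, NSENSE), dtype=bool)
    ts = np.zeros((NSENSE, NSENSE), dtype=bool)
    syn = np.zeros((NSENSE, NSENSE), dtype=bool)
    for i, ci in enumerate(SENSE):
        for j, cj in enumerate(SENSE):
            if i == j:
                continue
            a, b = CODONS[ci], CODONS[cj]
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) == 1:
                single[i, j] = True
                ts[i, j] = is_transition(*diffs[0])
                syn[i, j] = AA[ci] == AA[cj]
    return single, ts, syn

_SINGLE, _TS, _SYN = _pair_classes()

#: NG86 synonymous site counts per sense codon (0..60 indexing)
SYN_SITES_SENSE = SYN_SITES[SENSE]
#: NG86 pathway difference counts restricted to sense codons
SD_SENSE = SD_TABLE[np.ix_(SENSE, SENSE)]


def uniform_freqs() -> np.ndarray:
    return np.full(NSENSE, 1.0 / NSENSE)


def f3x4_freqs(codon_counts: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed per-position base counts.

    ``codon_counts`` is a length-61 vector of sense-codon counts; the
    position-specific base compositions are accumulated from it.
    """
    pos_freq = np.zeros((3, 4))
    for k, ci in enumerate(SENSE):
        c = CODONS[ci]
        for p in range(3):
            pos_freq[p, "ACGT".index(c[p])] += codon_counts[k]
    pos_freq /= np.maximum(pos_freq.sum(axis=1, keepdims=True), 1e-300)
    freqs = np.empty(NSENSE)
    for k, ci in enumerate(SENSE):
        c = CODONS[ci]
        freqs[k] = np.prod(
            [pos_freq[p, "ACGT".index(c[p])] for p in range(3)]
        )
    s = freqs.sum()
    if s <= 0:
        return uniform_freqs()
    return freqs / s


def rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, normalize: str = "syn"
) -> np.ndarray:
    """GY94 rate matrix over the 61 sense codons.

    normalize='syn' scales the matrix so the expected flux of synonymous
    substitutions per NG86 synonymous site equals 1 per unit time (the
    simulator's Ks-unit clock); normalize='none' leaves the raw scale
    (useful when branch lengths are free parameters, as in the trio fit).
    """
    Q = np.where(_SINGLE, freqs[None, :], 0.0)
    Q = Q * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize == "syn":
        syn_flux = (freqs[:, None] * np.where(_SYN, Q, 0.0)).sum()
        mean_sites = float(freqs @ SYN_SITES_SENSE)
        Q = Q * (mean_sites / syn_flux)
    elif normalize == "mean":
        flux = -(freqs * np.diag(Q)).sum()
        Q = Q / flux
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return Q


class CodonModel:
    """A parameterized GY94 model with cached eigendecomposition."""

    def __init__(self, kappa, omega, freqs=None, normalize="syn"):
        if kappa <= 0 or omega <= 0:
            raise ValueError("kappa and omega must be > 0")
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.freqs = uniform_freqs() if freqs is None else np.asarray(freqs)
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")
        self.Q = rate_matrix(self.kappa, self.omega, self.freqs, normalize)
        d = np.sqrt(np.maximum(self.freqs, 1e-300))
        B = (d[:, None] * self.Q) / d[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        self._w = w
        self._L = V / d[:, None] * 1.0  # D^-1 V
        self._R = (V * d[:, None]).T  # V^T D
        self._pcache: dict = {}

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to be a proper stochastic matrix."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        key = round(t, 12)
        P = self._pcache.get(key)
        if P is None:
            P = (self._L * np.exp(self._w * t)) @ self._R
            np.maximum(P, 0.0, out=P)
            P /= P.sum(axis=1, keepdims=True)
            self._pcache[key] = P
        return P

    def expected_ks_estimate(self, t: float) -> float:
        """Expected NG86/JC Ks estimate between two tips at divergence t."""
        from .kaks import jc_correct

        P = self.transition(t)
        joint = self.freqs[:, None] * P
        e_sd = float((joint * SD_SENSE).sum())
        e_sites = float(
            (
                joint
                * 0.5
                * (SYN_SITES_SENSE[:, None] + SYN_SITES_SENSE[None, :])
            ).sum()
        )
        p = e_sd / e_sites
        if p >= 0.7499:
            return float("inf")
        return jc_correct(p)


@lru_cache(maxsize=16)
def _clock_factor(kappa: float, omega: float, freqs_key) -> float:
    """Time-stretch factor mapping nominal Ks-unit branch lengths onto
    model time, anchored at a reference divergence of 0.3."""
    freqs = None if freqs_key is None else np.array(freqs_key)
    model = CodonModel(kappa, omega, freqs)
    d_ref = 0.3
    f = lambda t: model.expected_ks_estimate(t) - d_ref
    t_star = brentq(f, 1e-4, 5.0, xtol=1e-10)
    return t_star / d_ref


def calibrated_model(kappa, omega, freqs=None) -> tuple:
    """A Ks-unit CodonModel plus its clock factor (nominal->model time)."""
    key = None if freqs is None else tuple(np.round(freqs, 12))
    factor = _clock_factor(float(kappa), float(omega), key)
    return CodonModel(kappa, omega, freqs), factor
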