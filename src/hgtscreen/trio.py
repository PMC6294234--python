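"""Branch-model omega test on a three-taxon trifurcation.

For each accepted transfer we take the trio (transferred gene, closest
donor homolog, outgroup homolog) and compare two GY94 codon models on the
single-internal-node trifurcation tree: a null with one omega shared by
all three branches, and an alternative where the branch leading to the
transferred gene has its own omega.  Twice the log-likelihood difference
is referred to chi-square with 1 df.

Branch lengths are in expected substitutions per codon (each branch's rate
matrix is normalized to unit mean flux); codon frequencies default to
F3x4 estimated from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .gy94 import NSENSE, CodonModel, f3x4_freqs, uniform_freqs
from ._codon import SENSE_INDEX
from .kaks import CodonAlignment, ka_ks_pair

_OMEGA_BOUNDS = (1e-4, 99.0)
_KAPPA_BOUNDS = (1e-4, 99.0)
_T_BOUNDS = (1e-7, 50.0)


@dataclass
class TrioModelFit:
    kappa: float
    omega_background: float
    omega_hgt: float
    branch_lengths: np.ndarray
    codon_freqs: np.ndarray
    logL: float
    converged: bool = True

    def __post_init__(self):
        if abs(float(np.sum(self.codon_freqs)) - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float
    significant_at_5pct: bool


# ---------------------------------------------------------------------------
# likelihood


def _patterns(aln: CodonAlignment, log_dropped: bool = True):
    """Unique sense-codon site patterns and counts for a 3-row alignment.

    Columns where any row has a gap or untranslatable codon are dropped.
    """
    if len(aln.rows) != 3:
        raise ValueError("trio alignment must have exactly 3 rows")
    cods = np.stack(aln.codons)  # (3, ncod), -1 for gap/ambiguous
    sense = np.full(64, -1, dtype=np.int64)
    for c, k in SENSE_INDEX.items():
        sense[c] = k
    mapped = np.where(cods >= 0, sense[np.clip(cods, 0, 63)], -1)
    ok = (mapped >= 0).all(axis=0)
    dropped = int((~ok).sum())
    if dropped and log_dropped:
        warnings.warn(f"{dropped} gap/ambiguous codon columns dropped")
    pats, counts = np.unique(mapped[:, ok], axis=1, return_counts=True)
    return pats, counts.astype(float)


_MODEL_CACHE: dict = {}


def _model(kappa: float, omega: float, freqs_key, freqs) -> CodonModel:
    key = (round(kappa, 12), round(omega, 12), freqs_key)
    m = _MODEL_CACHE.get(key)
    if m is None:
        m = CodonModel(kappa, omega, freqs, normalize="mean")
        if len(_MODEL_CACHE) > 256:
            _MODEL_CACHE.clear()
        _MODEL_CACHE[key] = m
    return m


def _loglik(pats, counts, freqs, freqs_key, kappa, omegas, ts) -> float:
    prod = np.ones((NSENSE, pats.shape[1]))
    for b in range(3):
        m = _model(kappa, float(omegas[b]), freqs_key, freqs)
        P = m.transition(float(ts[b]))
        prod *= P[:, pats[b]]
    site = freqs @ prod
    if np.any(site <= 0):
        return -np.inf
    return float(counts @ np.log(site))


def trio_likelihood(aln: CodonAlignment, params: TrioModelFit, hgt_index: int = 0) -> float:
    """Log-likelihood of a trio alignment under a TrioModelFit.

    Branch ``hgt_index`` uses ``omega_hgt``; the other two use
    ``omega_background``.
    """
    pats, counts = _patterns(aln)
    omegas = np.full(3, params.omega_background)
    omegas[hgt_index] = params.omega_hgt
    freqs = np.asarray(params.codon_freqs)
    freqs_key = round(float(freqs[0]), 14), round(float(freqs[-1]), 14)
    return _loglik(
        pats, counts, freqs, freqs_key, params.kappa, omegas,
        np.asarray(params.branch_lengths),
    )


# ---------------------------------------------------------------------------
# fitting


def _start_values(aln: CodonAlignment):
    """Crude NG86-based starting values for (omega, branch lengths)."""
    c = aln.codons
    ratios, d = [], np.zeros((3, 3))
    for i in range(3):
        for j in range(i + 1, 3):
            r = ka_ks_pair(c[i], c[j])
            if np.isfinite(r.ratio) and r.ratio > 0:
                ratios.append(r.ratio)
            ncod = max(r.n_codons_compared, 1)
            subs = (r.Ka if np.isfinite(r.Ka) else 1.0) * r.N + (
                r.Ks if np.isfinite(r.Ks) else 1.0
            ) * r.S
            d[i, j] = d[j, i] = subs / ncod
    omega0 = float(np.clip(np.median(ratios) if ratios else 0.3, 0.02, 5.0))
    ts = np.empty(3)
    for i in range(3):
        j, k = [x for x in range(3) if x != i]
        ts[i] = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 1e-3)
    return omega0, ts


def _fit(pats, counts, freqs, freqs_key, x0, two_ratio, hgt_index):
    """Maximize the trio likelihood over log-transformed parameters."""

    def unpack(x):
        kappa = np.exp(x[0])
        if two_ratio:
            om_bg, om_hgt = np.exp(x[1]), np.exp(x[2])
            ts = np.exp(x[3:6])
        else:
            om_bg = om_hgt = np.exp(x[1])
            ts = np.exp(x[2:5])
        omegas = np.full(3, om_bg)
        omegas[hgt_index] = om_hgt
        return kappa, om_bg, om_hgt, omegas, ts

    def nll(x):
        kappa, _, _, omegas, ts = unpack(x)
        return -_loglik(pats, counts, freqs, freqs_key, kappa, omegas, ts)

    nt = 3
    bounds = (
        [tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_OMEGA_BOUNDS))] * (2 if two_ratio else 1)
        + [tuple(np.log(_T_BOUNDS))] * nt
    )
    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    kappa, om_bg, om_hgt, _, ts = unpack(res.x)
    return TrioModelFit(
        kappa=kappa,
        omega_background=om_bg,
        omega_hgt=om_hgt,
        branch_lengths=ts,
        codon_freqs=freqs,
        logL=-float(res.fun),
        converged=bool(res.success),
    ), res


def fit_branch_models(
    aln: CodonAlignment,
    hgt_index: int = 0,
    freqs: str = "f3x4",
    extra_starts: Optional[Sequence[float]] = None,
):
    """Fit the 1-ratio (null) and 2-ratio (alternative) branch models.

    Returns (null_fit, alt_fit, LRTResult).  The alternative is seeded at
    the null optimum (so the LRT statistic cannot go materially negative)
    and refitted from additional omega_hgt starts (default 0.1, 0.5, 1.5)
    whenever the seeded fit fails to converge or degrades.
    """
    pats, counts = _patterns(aln)
    if freqs == "f3x4":
        cnt = np.zeros(NSENSE)
        for b in range(3):
            np.add.at(cnt, pats[b], counts)
        fvec = f3x4_freqs(cnt)
    elif freqs == "uniform":
        fvec = uniform_freqs()
    else:
        raise ValueError(f"unknown frequency model {freqs!r}")
    fvec = np.maximum(fvec, 1e-10)
    fvec /= fvec.sum()
    freqs_key = round(float(fvec[0]), 14), round(float(fvec[-1]), 14)
    omega0, ts0 = _start_values(aln)
    x0_null = np.log(np.concatenate([[2.0, omega0], ts0]))
    null_fit, _ = _fit(pats, counts, fvec, freqs_key, x0_null, False, hgt_index)
    x0_alt = np.log(
        np.concatenate(
            [
                [null_fit.kappa, null_fit.omega_background,
                 null_fit.omega_background],
                np.maximum(null_fit.branch_lengths, 1e-6),
            ]
        )
    )
    alt_fit, res = _fit(pats, counts, fvec, freqs_key, x0_alt, True, hgt_index)
    starts = list(extra_starts) if extra_starts is not None else []
    if alt_fit.logL < null_fit.logL - 1e-6 or not alt_fit.converged:
        starts = starts or [0.1, 0.5, 1.5]
    for om in starts:
        x0 = np.log(
            np.concatenate(
                [
                    [null_fit.kappa, null_fit.omega_background, om],
                    np.maximum(null_fit.branch_lengths, 1e-6),
                ]
            )
        )
        cand, _ = _fit(pats, counts, fvec, freqs_key, x0, True, hgt_index)
        if cand.logL > alt_fit.logL:
            alt_fit = cand
    stat = 2.0 * (alt_fit.logL - null_fit.logL)
    if stat < -1e-6:
        warnings.warn(f"LRT statistic {stat:.3g} below zero; clamped")
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1))
    return null_fit, alt_fit, LRTResult(
        stat=stat, df=1, p_value=p, significant_at_5pct=p < 0.05
    )


# ---------------------------------------------------------------------------
# trio simulation (for calibration/power experiments)


def simulate_trio(
    n_codons: int,
    kappa: float,
    omega_background: float,
    omega_hgt: float,
    branch_lengths,
    seed: int,
    hgt_index: int = 0,
    taxa=("hgt", "donor", "outgroup"),
) -> CodonAlignment:
    """Simulate a trifurcation trio under the branch model.

    Branch lengths are in expected substitutions per codon under each
    branch's own rate matrix (the same units the fit reports).
    """
    from ._codon import CODONS
    from .gy94 import SENSE

    rng = np.random.default_rng(seed)
    freqs = uniform_freqs()
    root = rng.choice(NSENSE, size=n_codons, p=freqs)
    omegas = np.full(3, omega_background)
    omegas[hgt_index] = omega_hgt
    rows = []
    for b in range(3):
        m = CodonModel(kappa, float(omegas[b]), None, normalize="mean")
        P = m.transition(float(branch_lengths[b]))
        child = root.copy()
        for c in np.unique(root):
            idx = np.nonzero(root == c)[0]
            cum = np.cumsum(P[c])
            child[idx] = np.searchsorted(cum, rng.random(len(idx)))
        child = np.minimum(child, NSENSE - 1)
        rows.append("".join(CODONS[SENSE[i]] for i in child))
    return CodonAlignment(list(taxa), rows)
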