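"""HKY85 + discrete-gamma maximum likelihood trees (Felsenstein pruning)
for homolog verification.

Used on the wider homolog sets of accepted transfer candidates: all codon
positions are analyzed as nucleotide columns under HKY with 4 gamma rate
categories (alpha optimized by golden section), starting from an NJ
topology and hill-climbing with nearest-neighbor interchanges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc

from .phylo import Node, Tree, distance_matrix, neighbor_joining

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma categories."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    probs = np.arange(1, ncat) / ncat
    # quantiles of Gamma(alpha, mean 1)
    from scipy.stats import gamma as gamma_dist

    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts * alpha, [np.inf]])
    upper = gammainc(alpha + 1.0, bounds[1:])
    lower = gammainc(alpha + 1.0, bounds[:-1])
    return (upper - lower) * ncat


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix normalized to unit mean substitution rate."""
    Q = np.repeat(freqs[None, :], 4, axis=0).astype(float)
    for i in range(4):
        for j in range(4):
            if {i, j} in ({0, 2}, {1, 3}):  # A<->G, C<->T transitions
                Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = -(freqs * np.diag(Q)).sum()
    return Q / flux


class HKYGamma:
    """HKY + discrete gamma with cached eigendecomposition."""

    def __init__(self, kappa: float, freqs: np.ndarray, alpha: float, ncat: int = 4):
        self.kappa = float(kappa)
        self.freqs = np.asarray(freqs, dtype=float)
        self.alpha = float(alpha)
        self.rates = gamma_category_rates(alpha, ncat)
        Q = hky_rate_matrix(self.kappa, self.freqs)
        d = np.sqrt(self.freqs)
        B = (d[:, None] * Q) / d[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        self._w = w
        self._L = V / d[:, None]
        self._R = (V * d[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        """Per-category transition matrices, shape (ncat, 4, 4)."""
        ts = np.maximum(self.rates * t, 0.0)
        P = np.einsum(
            "ij,cj,jk->cik", self._L, np.exp(np.outer(ts, self._w)), self._R
        )
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def _pack_alignment(taxa: Sequence[str], rows: Sequence[str]):
    """Site-pattern compression: tip partial likelihood arrays (4,) per
    pattern, with ambiguity/gap as all-ones."""
    mat = np.array(
        [[_NUC_INDEX.get(ch, 4) for ch in row.upper()] for row in rows],
        dtype=np.int8,
    )
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    tip_partials = {}
    eye = np.vstack([np.eye(4), np.ones(4)])
    for i, name in enumerate(taxa):
        tip_partials[name] = eye[pats[i]]  # (npat, 4)
    return tip_partials, counts.astype(float)


def empirical_base_freqs(rows: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for row in rows:
        for ch in row.upper():
            i = _NUC_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    f = counts / counts.sum()
    return np.maximum(f, 1e-6) / np.maximum(f, 1e-6).sum()


def tree_loglik(
    tree: Tree,
    tip_partials: dict,
    counts: np.ndarray,
    model: HKYGamma,
) -> float:
    """Pruning log-likelihood; invariant to taxon input order."""
    npat = len(counts)
    ncat = len(model.rates)
    site = np.zeros(npat)
    per_cat = np.empty((ncat, npat))
    partials: dict = {}
    nodes = list(tree.postorder())
    for cat in range(ncat):
        pass  # vectorized below
    # compute per category to bound memory
    for cat in range(ncat):
        partials.clear()
        for n in nodes:
            if n.is_tip:
                partials[id(n)] = tip_partials[n.name]
                continue
            prod = np.ones((npat, 4))
            for c in n.children:
                t = max(c.length or 0.0, 0.0)
                P = model.transition(t)[cat]
                prod *= partials[id(c)] @ P.T
            partials[id(n)] = prod
        per_cat[cat] = partials[id(tree.root)] @ model.freqs
    site = per_cat.mean(axis=0)
    if np.any(site <= 0):
        return -np.inf
    return float(counts @ np.log(site))


def _edges(tree: Tree):
    return [n for n in tree.preorder() if n.parent is not None]


def optimize_branch_lengths(
    tree: Tree,
    tip_partials,
    counts,
    kappa: float,
    freqs,
    alpha: float,
    maxiter: int = 60,
) -> float:
    """Optimize all branch lengths (log scale) by L-BFGS-B; in-place."""
    model = HKYGamma(kappa, freqs, alpha)
    edges = _edges(tree)
    x0 = np.log(np.maximum([e.length or 1e-3 for e in edges], 1e-6))

    def nll(x):
        for e, v in zip(edges, x):
            e.length = float(np.exp(v))
        return -tree_loglik(tree, tip_partials, counts, model)

    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(20.0))] * len(edges),
        options={"maxiter": maxiter, "ftol": 1e-9},
    )
    for e, v in zip(edges, res.x):
        e.length = float(np.exp(v))
    return -float(res.fun)


def _optimize_alpha(tree, tip_partials, counts, kappa, freqs, alpha0):
    """Golden-section optimization of the gamma shape parameter."""

    def nll(log_a):
        model = HKYGamma(kappa, freqs, float(np.exp(log_a)))
        return -tree_loglik(tree, tip_partials, counts, model)

    res = minimize_scalar(
        nll,
        bracket=(np.log(max(alpha0, 0.05)) - 1.0, np.log(max(alpha0, 0.05))),
        method="golden",
        options={"xtol": 1e-3, "maxiter": 40},
    )
    return float(np.clip(np.exp(res.x), 0.02, 100.0))


def _nni_neighbors(tree: Tree):
    """Trees one NNI move away (internal edges of the unrooted tree)."""
    out = []
    base = tree.to_newick()
    for idx, n in enumerate(tree.preorder()):
        if n.is_tip or n.parent is None:
            continue
        if len(n.children) != 2:
            continue
        for swap in (0, 1):
            t2 = Tree.from_newick(base)
            nodes2 = t2.preorder()
            v = nodes2[idx]
            u = v.parent
            siblings = [c for c in u.children if c is not v]
            if not siblings:
                continue
            s = siblings[0]
            c = v.children[swap]
            # exchange s and c
            u.children[u.children.index(s)] = c
            v.children[swap] = s
            s_len, c_len = s.length, c.length
            s.parent, c.parent = v, u
            s.length, c.length = c_len, s_len
            out.append(t2)
    return out


def estimate_kappa(rows: Sequence[str]) -> float:
    """Rough transition/transversion-based kappa estimate."""
    ts = tv = 0
    pairs = min(len(rows), 4)
    for i in range(pairs):
        for j in range(i + 1, pairs):
            for x, y in zip(rows[i].upper(), rows[j].upper()):
                if x == y or x not in "ACGT" or y not in "ACGT":
                    continue
                if {x, y} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 2.0
    return float(np.clip(2.0 * ts / tv, 0.5, 20.0))


@dataclass
class MLResult:
    tree: Tree
    logL: float
    kappa: float
    alpha: float
    freqs: np.ndarray


def ml_tree(
    taxa: Sequence[str],
    rows: Sequence[str],
    max_nni_rounds: int = 5,
    start: Optional[Tree] = None,
) -> MLResult:
    """HKY+gamma ML tree: NJ start, branch-length + alpha optimization,
    NNI hill climbing.

    With fewer than 4 taxa the NJ tree is returned with optimized branch
    lengths only (no topology search is possible).
    """
    from .kaks import CodonAlignment

    tip_partials, counts = _pack_alignment(taxa, rows)
    freqs = empirical_base_freqs(rows)
    kappa = estimate_kappa(rows)
    if start is None:
        aln = CodonAlignment(
            list(taxa), [r + "-" * ((3 - len(r) % 3) % 3) for r in rows]
        )
        M = distance_matrix(aln, metric="total_jc")
        if np.isnan(M).any():
            M = np.where(np.isnan(M), np.nanmax(M) * 1.5 + 1.0, M)
            np.fill_diagonal(M, 0.0)
        tree = neighbor_joining(M, list(taxa))
    else:
        tree = start.copy()
    for e in _edges(tree):
        e.length = max(e.length or 1e-3, 1e-6)
    alpha = 1.0
    logL = optimize_branch_lengths(tree, tip_partials, counts, kappa, freqs, alpha)
    alpha = _optimize_alpha(tree, tip_partials, counts, kappa, freqs, alpha)
    logL = optimize_branch_lengths(tree, tip_partials, counts, kappa, freqs, alpha)
    if len(taxa) >= 4:
        for _ in range(max_nni_rounds):
            improved = False
            for cand in _nni_neighbors(tree):
                cl = optimize_branch_lengths(
                    cand, tip_partials, counts, kappa, freqs, alpha, maxiter=30
                )
                if cl > logL + 1e-6:
                    tree, logL = cand, cl
                    improved = True
                    break
            if not improved:
                break
        alpha = _optimize_alpha(tree, tip_partials, counts, kappa, freqs, alpha)
        logL = optimize_branch_lengths(
            tree, tip_partials, counts, kappa, freqs, alpha
        )
    return MLResult(tree=tree, logL=logL, kappa=kappa, alpha=alpha, freqs=freqs)


def filter_homologs_by_bitscore(hits, host_best_bits: float):
    """Half-bit-score inclusion rule for homolog-verification sets: keep
    subjects scoring at least half the best host-species bit score."""
    return [h for h in hits if h.score_bits >= 0.5 * host_best_bits]


def verify_homolog_tree(
    hgt_record,
    homolog_records,
    max_nni_rounds: int = 5,
) -> MLResult:
    """ML verification tree of an accepted transfer with its homolog set.

    Sequences are codon-aligned, all three codon positions are analyzed as
    nucleotide columns, and the search runs NJ + NNI under HKY+gamma.
    With fewer than 4 taxa the NJ tree with optimized branch lengths is
    returned (a warning is emitted).
    """
    import warnings

    from .kaks import align_codons

    records = [hgt_record] + list(homolog_records)
    if len(records) < 4:
        warnings.warn("fewer than 4 taxa: returning NJ-based tree only")
    aln = align_codons(records)
    return ml_tree(aln.taxa, aln.rows, max_nni_rounds=max_nni_rounds)
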