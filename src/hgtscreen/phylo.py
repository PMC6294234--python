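"""Trees and the distance-based stages of the screening cascade.

Holds a light phylogenetic tree class with newick round-trip, Saitou-Nei
neighbor joining, codon-column bootstrap, and the per-locus tests the
screen applies to gene trees: the external-branch-length rule, the Ks rule
and the host-clade placement test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import ParseError


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name="", length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = []
        self.parent = None

    def add(self, child: "Node"):
        child.parent = self
        self.children.append(child)

    @property
    def is_tip(self):
        return not self.children


class Tree:
    """Rooted tree data structure (an unrooted tree is stored with a
    multifurcating root)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def tips(self):
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self):
        return [n.name for n in self.tips()]

    def find_tip(self, name: str) -> Node:
        for n in self.tips():
            if n.name == name:
                return n
        raise KeyError(f"tip {name!r} not in tree")

    def tipset(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def mrca(self, names: Iterable[str]) -> Node:
        names = set(names)
        for n in self.postorder():
            if not n.is_tip:
                if names <= self.tipset(n):
                    return n
        if names <= self.tipset(self.root):
            return self.root
        raise KeyError(f"tips {sorted(names)} not all present")

    # -- newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        s = text.strip()
        if s.endswith(";"):
            s = s[:-1]
        pos = 0

        def parse_node() -> Node:
            nonlocal pos
            node = Node()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse_node())
                    if pos >= len(s):
                        raise ParseError("unbalanced parentheses in newick")
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise ParseError(f"unexpected {s[pos]!r} at {pos}")
            # label
            start = pos
            while pos < len(s) and s[pos] not in ":,()":
                pos += 1
            label = s[start:pos].strip()
            if label:
                if node.children:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
                else:
                    node.name = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                try:
                    node.length = float(s[start:pos])
                except ValueError as exc:
                    raise ParseError(f"bad branch length at {start}") from exc
            return node

        root = parse_node()
        if pos != len(s):
            raise ParseError("unbalanced parentheses in newick")
        return cls(root)

    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_tip:
                lab = n.name
            else:
                inner = ",".join(fmt(c) for c in n.children)
                if n.support is not None:
                    lab = f"({inner}){n.support:g}"
                else:
                    lab = f"({inner}){n.name}"
            if n.length is not None:
                lab += f":{n.length:.10g}"
            return lab

        return fmt(self.root) + ";"

    def __str__(self):
        return self.to_newick()

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length, n.support)
            for c in n.children:
                m.add(clone(c))
            return m

        return Tree(clone(self.root))

    def suppress_unifurcations(self):
        """Merge degree-2 internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for n in list(self.preorder()):
                if n is self.root:
                    if len(n.children) == 1 and not n.children[0].is_tip:
                        child = n.children[0]
                        child.parent = None
                        child.length = None
                        self.root = child
                        changed = True
                    continue
                if len(n.children) == 1:
                    (child,) = n.children
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                    parent = n.parent
                    parent.children[parent.children.index(n)] = child
                    child.parent = parent
                    changed = True
        return self

    def induced_subtree(self, keep: Iterable[str]) -> "Tree":
        """Restrict to a tip set, suppressing pass-through nodes and summing
        their branch lengths."""
        keep = set(keep)
        t = self.copy()

        def prune(n: Node) -> Optional[Node]:
            if n.is_tip:
                return n if n.name in keep else None
            kept = [c for c in [prune(c) for c in n.children] if c is not None]
            n.children = []
            for c in kept:
                n.add(c)
            return n if kept else None

        root = prune(t.root)
        if root is None:
            raise ValueError("no requested tips present")
        t.root = root
        root.parent = None
        return t.suppress_unifurcations()

    def reroot_on(self, node: Node, fraction: float = 0.5) -> "Tree":
        """Insert a new root on the edge above ``node`` (in-place)."""
        if node.parent is None:
            return self
        # collect path node.parent -> ... -> old root
        path = []
        p = node.parent
        while p is not None:
            path.append(p)
            p = p.parent
        # detach node from its parent
        old_parent = node.parent
        old_parent.children.remove(node)
        # reverse parent-child relations along the path
        for a, b in zip(path, path[1:]):
            b.children.remove(a)
            a.add(b)
            b.length = a.length
            b.support = a.support
        old_root = path[-1]
        elen = node.length
        new_root = Node()
        half = None if elen is None else elen * fraction
        rest = None if elen is None else elen - half
        node.length = half
        node.parent = None
        old_parent.length = rest
        old_parent.support = node.support if not node.is_tip else None
        new_root.add(node)
        new_root.add(old_parent)
        self.root = new_root
        self.suppress_unifurcations()
        return self

    def reroot_on_outgroup(self, outgroup_names: Iterable[str]) -> "Tree":
        """Root the tree on the outgroup (tip or outgroup MRCA edge)."""
        og = [n for n in outgroup_names if n in set(self.tip_names())]
        if not og:
            raise ValueError("no outgroup tip present; tree is unrootable")
        t = self.copy()
        t.reroot_on(t.find_tip(og[0]))
        if len(og) > 1:
            m = t.mrca(og)
            if m is not t.root and m.parent is not t.root:
                t.reroot_on(m)
            elif m is not t.root:
                t.reroot_on(m)
        return t

    # -- comparisons -------------------------------------------------------

    def bipartitions(self) -> set:
        """Non-trivial unrooted splits as normalized frozenset pairs."""
        all_tips = frozenset(self.tip_names())
        splits = set()
        for n in self.postorder():
            if n is self.root or n.parent is None:
                continue
            side = self.tipset(n)
            other = all_tips - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(frozenset((side, other)))
        return splits

    def same_topology(self, other: "Tree") -> bool:
        """Unrooted topological identity (equal tip and split sets)."""
        if set(self.tip_names()) != set(other.tip_names()):
            return False
        return self.bipartitions() == other.bipartitions()

    def patristic(self, a: str, b: str) -> float:
        ta, tb = self.find_tip(a), self.find_tip(b)
        anc_a = {}
        d = 0.0
        n = ta
        while n is not None:
            anc_a[id(n)] = d
            d += n.length or 0.0
            n = n.parent
        d = 0.0
        n = tb
        while n is not None:
            if id(n) in anc_a:
                return d + anc_a[id(n)]
            d += n.length or 0.0
            n = n.parent
        raise ValueError("disconnected tips")


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(M: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the adjacent (sister) branch.  Masked (NaN) entries are
    refused.  Returns an unrooted tree (trifurcating root) for >= 3 taxa.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or n != len(labels):
        raise ValueError("matrix/label shape mismatch")
    if np.isnan(M).any():
        bad = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if np.isnan(M[i, j])
        ]
        raise ValueError(f"masked (saturated) distances for pairs: {bad}")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [Node(name=lab) for lab in labels]
    D = M.copy()
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = Node()
        nodes[ai].length = li
        nodes[aj].length = lj
        parent.add(nodes[ai])
        parent.add(nodes[aj])
        # distances from the new node
        dnew = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=0.0)
        D[-1, active] = dnew
        D[active, -1] = dnew
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    root = Node()
    if len(active) == 2:
        a, b = active
        d = D[a, b]
        nodes[a].length = d / 2.0
        nodes[b].length = d / 2.0
        root.add(nodes[a])
        root.add(nodes[b])
    else:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        la = max(la, 0.0)
        lb = max(lb, 0.0)
        lc = max(lc, 0.0)
        for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
            node.length = ln
            root.add(node)
    return Tree(root)


# ---------------------------------------------------------------------------
# Distance matrices and bootstrap


def distance_matrix(aln, metric: str = "ks"):
    """Pairwise distance matrix over a codon alignment.

    metric='ks': synonymous-site divergence (Jukes-Cantor corrected) from
    the Nei-Gojobori counts; metric='total_jc': Jukes-Cantor distance over
    all ungapped nucleotide columns.  Saturated pairs are returned as NaN.
    """
    from .kaks import jc_correct, ka_ks_pair

    taxa = aln.taxa
    n = len(taxa)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "ks":
                res = ka_ks_pair(aln.codons[i], aln.codons[j])
                d = res.Ks if not res.saturated_s else np.nan
            elif metric == "total_jc":
                a, b = aln.rows[i], aln.rows[j]
                pairs = [
                    (x, y)
                    for x, y in zip(a, b)
                    if x in "ACGT" and y in "ACGT"
                ]
                if not pairs:
                    d = np.nan
                else:
                    p = sum(x != y for x, y in pairs) / len(pairs)
                    d = jc_correct(p) if p < 0.75 else np.nan
            else:
                raise ValueError(f"unknown metric {metric!r}")
            M[i, j] = M[j, i] = d
    return M


def bootstrap_support(aln, n_reps: int = 100, seed: int = 0, metric: str = "ks"):
    """NJ tree with bootstrap supports from codon-column resampling.

    Support of an internal edge is the percentage of replicate NJ trees
    (on resampled codon columns) containing the same bipartition.
    Replicates whose resampled distance matrix has saturated pairs are
    discarded from the denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    M = distance_matrix(aln, metric=metric)
    tree = neighbor_joining(M, aln.taxa)
    counts: dict = {}
    rng = np.random.default_rng(seed)
    ncod = aln.length // 3
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncod, size=ncod)
        rep = aln.subset_codons(cols)
        try:
            Mr = distance_matrix(rep, metric=metric)
            t = neighbor_joining(Mr, rep.taxa)
        except ValueError:
            continue
        used += 1
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    denom = max(used, 1)
    all_tips = frozenset(aln.taxa)
    for node in tree.postorder():
        if node.is_tip or node.parent is None:
            continue
        side = tree.tipset(node)
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            split = frozenset((side, other))
            node.support = 100.0 * counts.get(split, 0) / denom
    return tree


# ---------------------------------------------------------------------------
# Per-locus screening tests


@dataclass
class PlacementResult:
    """Where the parasite gene attaches relative to the host clade."""

    nested_in_host_clade: Optional[bool] = None
    sister_taxon: Optional[frozenset] = None
    external_branch_len: float = 0.0
    longest_host_branch: float = 0.0


def branch_length_filter(
    tree: Tree, parasite_tip: str, host_tips: Sequence[str], factor: float = 2.0
):
    """Fail a locus whose parasite external branch is longer than ``factor``
    times the longest single edge among the host species subtree.

    Returns (passed, PlacementResult) with both lengths recorded; the
    comparison is strict (> factor x longest host edge fails).
    """
    host_tips = [h for h in host_tips if h in set(tree.tip_names())]
    if len(host_tips) < 2:
        raise ValueError("need >= 2 host tips in tree")
    par = tree.find_tip(parasite_tip)
    ext = par.length or 0.0
    sub = tree.induced_subtree(host_tips)
    longest = max(
        (n.length or 0.0) for n in sub.postorder() if n.parent is not None
    )
    passed = not (ext > factor * longest)
    return passed, PlacementResult(
        external_branch_len=ext, longest_host_branch=longest
    )


def ks_filter(parasite_seq, host_seqs, threshold: float = 1.0):
    """Keep loci whose closest host (minimum pairwise Ks) lies below the
    Ks threshold (default 1, roughly the within-family saturation horizon).

    Tie-break for the closest host: larger number of compared codons, then
    lexicographic id.  Returns (passed, closest_host_id, KaKsResult or None).
    """
    from .kaks import align_codons, ka_ks_pair

    best = None
    for host in host_seqs:
        aln = align_codons([parasite_seq, host])
        res = ka_ks_pair(aln.codons[0], aln.codons[1])
        if res.saturated_s:
            continue
        key = (res.Ks, -res.n_codons_compared, host.id)
        if best is None or key < best[0]:
            best = (key, host.id, res)
    if best is None:
        return False, None, None
    _, host_id, res = best
    return bool(res.Ks < threshold), host_id, res


def placement_test(
    tree: Tree,
    parasite_tip: str,
    host_tips: Iterable[str],
    outgroup_tips: Iterable[str],
) -> PlacementResult:
    """Test whether the parasite gene attaches inside (or sister to) the
    host clade rather than with the outgroup.

    The tree is rooted on the outgroup when it is not already rooted; the
    parasite is 'nested' when the smallest clade containing the parasite
    tip and at least one host tip contains no outgroup tip.
    """
    names = set(tree.tip_names())
    host_tips = [h for h in host_tips if h in names]
    outgroup_tips = [o for o in outgroup_tips if o in names]
    if parasite_tip not in names:
        raise ValueError(f"parasite tip {parasite_tip!r} absent")
    if not outgroup_tips:
        raise ValueError("no outgroup tip present; tree is unrootable")
    t = tree
    if len(t.root.children) > 2:  # unrooted: root on the outgroup
        t = tree.reroot_on_outgroup(outgroup_tips)
    par = t.find_tip(parasite_tip)
    node = par
    clade = frozenset((par.name,))
    while node.parent is not None and not (clade & set(host_tips)):
        node = node.parent
        clade = t.tipset(node)
    nested = bool(clade & set(host_tips)) and not (clade & set(outgroup_tips))
    sister = clade - {parasite_tip}
    ext = par.length or 0.0
    longest = 0.0
    if len(host_tips) >= 2:
        sub = t.induced_subtree(host_tips)
        longest = max(
            (n.length or 0.0) for n in sub.postorder() if n.parent is not None
        )
    return PlacementResult(
        nested_in_host_clade=nested,
        sister_taxon=frozenset(sister),
        external_branch_len=ext,
        longest_host_branch=longest,
    )
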