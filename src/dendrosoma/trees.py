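"""Physical tree architectures, neighbor joining, and topology congruence.

The physical architecture of a sampled tree (trunk and branches, lengths in
meters) doubles as the expected genealogy of its somatic mutations: a
mutation arising on a branch should be shared by the tips distal to it.
This module computes pairwise distances on the architecture, builds
Saitou-Nei neighbor-joining trees from somatic-SNV difference matrices, and
quantifies congruence between the two with the Robinson-Foulds metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import MutationMatrix


@dataclass
class PhysicalTree:
    """Rooted architecture with branch lengths in meters.

    ``edges`` are (parent, child, length_m) triples; the base (cambium)
    sample sits at the root. ``age`` is the tree's age in years and
    ``height`` its physical height in meters; both are optional metadata
    used by rate estimation.
    """

    edges: list[tuple[str, str, float]]
    tips: list[str]
    base: str
    age: float | None = None
    height: float | None = None
    children: dict[str, list[str]] = field(init=False, repr=False)
    parent: dict[str, str] = field(init=False, repr=False)
    length: dict[str, float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.children = {}
        self.parent = {}
        self.length = {}
        for p, c, l in self.edges:
            if l <= 0:
                raise ValueError(f"non-positive branch length on edge {p}->{c}")
            if c in self.parent:
                raise ValueError(f"node {c} has two parents")
            self.parent[c] = p
            self.length[c] = float(l)
            self.children.setdefault(p, []).append(c)
        nodes = set(self.parent) | set(self.children)
        roots = nodes - set(self.parent)
        if roots != {self.base}:
            raise ValueError(f"expected single root {self.base!r}, found {sorted(roots)}")
        # connectivity/acyclicity: walking up from every node must reach the root
        for n in nodes:
            seen = set()
            while n != self.base:
                if n in seen:
                    raise ValueError("cycle detected in architecture")
                seen.add(n)
                n = self.parent[n]
        leaves = {n for n in nodes if n not in self.children}
        if set(self.tips) != leaves:
            raise ValueError(f"declared tips {self.tips} != leaf nodes {sorted(leaves)}")
        if self.height is None:
            self.height = max(self.distance_to_root(t) for t in self.tips)

    # ------------------------------------------------------------ traversal
    def preorder_edges(self) -> list[tuple[str, str, float]]:
        out: list[tuple[str, str, float]] = []
        stack = [self.base]
        while stack:
            node = stack.pop()
            for child in sorted(self.children.get(node, []), reverse=True):
                out.append((node, child, self.length[child]))
                stack.append(child)
        return out

    def descendant_tips(self, node: str) -> list[str]:
        if node not in self.children:
            return [node] if node in self.tips else []
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children.get(n)
            if kids:
                stack.extend(kids)
            elif n in self.tips:
                out.append(n)
        return sorted(out)

    def distance_to_root(self, node: str) -> float:
        d = 0.0
        while node != self.base:
            d += self.length[node]
            node = self.parent[node]
        return d

    def _path_to_root(self, node: str) -> list[str]:
        path = [node]
        while node != self.base:
            node = self.parent[node]
            path.append(node)
        return path

    def total_branch_length(self) -> float:
        return float(sum(l for _, _, l in self.edges))

    # ------------------------------------------------------------ distances
    def pairwise_distance(self, labels: list[str] | None = None) -> pd.DataFrame:
        """Path-length matrix (meters) between tips via the LCA."""
        labels = list(labels or self.tips)
        up = {t: self._path_to_root(t) for t in labels}
        depth = {t: self.distance_to_root(t) for t in labels}
        node_depth: dict[str, float] = {}
        for t in labels:
            for n in up[t]:
                node_depth.setdefault(n, self.distance_to_root(n))
        d = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, a in enumerate(labels):
            seta = set(up[a])
            for b in labels[i + 1 :]:
                lca = next(n for n in up[b] if n in seta)
                val = depth[a] + depth[b] - 2 * node_depth[lca]
                d.loc[a, b] = d.loc[b, a] = val
        return d

    # ---------------------------------------------------------------- I/O
    def newick(self, include_base: bool = False) -> str:
        """Rooted Newick over the tip samples; labels quoted, 6 s.f. lengths."""

        def fmt(node: str) -> str:
            kids = self.children.get(node)
            if not kids:
                return f"'{node}':{self.length[node]:.6g}"
            inner = ",".join(fmt(k) for k in sorted(kids))
            if node == self.base:
                if include_base:
                    return f"({inner},'{node}':0)"
                return f"({inner})"
            return f"({inner}):{self.length[node]:.6g}"

        return fmt(self.base) + ";"

    def to_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def pairwise_physical_distance(tree: PhysicalTree) -> pd.DataFrame:
    """Meters of growth separating each pair of branch tips."""
    return tree.pairwise_distance()


def pairwise_snv_distance(matrix: MutationMatrix) -> pd.DataFrame:
    """Number of somatic-SNV sites differing between each pair of tips."""
    p = matrix.presence
    if p.isna().any().any():
        raise ValueError("presence matrix contains missing entries")
    x = p.to_numpy(dtype=np.int64)
    diff = (x[:, :, None] != x[:, None, :]).sum(axis=0)
    return pd.DataFrame(diff, index=p.columns, columns=p.columns)


# --------------------------------------------------------------------- NJ
def _check_distance_matrix(d: pd.DataFrame) -> None:
    vals = d.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(vals), 0.0):
        raise ValueError("distance matrix has nonzero diagonal")
    if (vals < -1e-9).any():
        raise ValueError("distance matrix has negative entries")


def neighbor_joining(d: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; exact ties are broken toward the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest leaf), so
    output is deterministic. Negative limb lengths are clamped to zero with
    the deficit moved to the sister limb, preserving the joined distance.
    """
    _check_distance_matrix(d)
    n0 = len(d)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    labels = [str(x) for x in d.index]
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist[_key(a, b)] = float(d.loc[a, b])
    newick = {a: f"'{a}'" for a in labels}
    active = sorted(labels)

    def get(a: str, b: str) -> float:
        return dist[_key(a, b)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * get(a, b) - r[a] - r[b]
                cand = (q, a, b)
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and (a, b) < (best[1], best[2])
                ):
                    best = cand
        _, a, b = best  # type: ignore[misc]
        dab = get(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb = _clamp_limbs(la, lb)
        new = min(a, b)
        frag = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
        for c in active:
            if c in (a, b):
                continue
            dn = (get(a, c) + get(b, c) - dab) / 2
            dist[_key(new, c)] = dn
        active = sorted(set(active) - {a, b} | {new})
        newick[new] = frag

    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2
    lb = get(a, b) - la
    lc = get(a, c) - la
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g},{newick[c]}:{lc:.6g});"


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _clamp_limbs(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        la, lb = 0.0, lb + la
    if lb < 0:
        la, lb = la + lb, 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_from_matrix(matrix: MutationMatrix) -> str:
    """NJ tree from the pairwise somatic-SNV difference matrix of the tips."""
    return neighbor_joining(pairwise_snv_distance(matrix))


# ------------------------------------------------------------------- RF
def bipartitions(newick: str) -> tuple[set[frozenset[str]], set[str]]:
    """Non-trivial bipartitions of an (un)rooted Newick tree.

    Each split is canonicalised as the side not containing the smallest
    taxon label, so the representation is rooting-independent.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    ref = min(taxa)
    n = len(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits, taxa


def topology_congruence(newick1: str, newick2: str) -> tuple[int, float]:
    """Robinson-Foulds distance and normalised congruence in [0, 1].

    RF is the size of the symmetric difference of the two trees'
    non-trivial bipartition sets, normalised by 2(n-3), the maximum for two
    fully resolved unrooted trees on n shared taxa.
    """
    s1, t1 = bipartitions(newick1)
    s2, t2 = bipartitions(newick2)
    if t1 != t2:
        raise ValueError(f"tip label sets differ: {sorted(t1 ^ t2)}")
    rf = len(s1 ^ s2)
    n = len(t1)
    norm = rf / (2 * (n - 3)) if n > 3 else 0.0
    return rf, norm


# ------------------------------------------------------------- patterns
def classify_patterns(matrix: MutationMatrix) -> dict:
    """Tally mutation-sharing patterns across the branch tips.

    Each site is categorised by the number of carrying tips k: ``Single``
    (k=1), ``Double`` (k=2), ``More`` (k>=3), relative to the base sample's
    reference genotype. Also returns the full histogram over the 2^t - 1
    possible carrier patterns that were observed.
    """
    p = matrix.presence
    k = p.sum(axis=1)
    if (k == 0).any():
        bad = p.index[k == 0][0]
        raise ValueError(f"site {bad} carried by no tip: not somatic relative to base")
    counts = {
        "Single": int((k == 1).sum()),
        "Double": int((k == 2).sum()),
        "More": int((k >= 3).sum()),
    }
    hist: dict[tuple[str, ...], int] = {}
    for _, row in p.iterrows():
        pattern = tuple(c for c in p.columns if row[c])
        hist[pattern] = hist.get(pattern, 0) + 1
    return {"counts": counts, "histogram": hist}
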