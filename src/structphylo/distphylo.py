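"""Similarity→distance transforms and distance-matrix phylogenetics.

Raw structural-similarity scores (0–1000 scale) are capped at 1000 and
mapped to distances d = max(0, 1 − score/1000), giving values in [0, 1]
with 0 for indistinguishable structures.  Trees are inferred by UPGMA,
neighbor joining (scikit-bio), and Fitch–Margoliash (NJ start +
nearest-neighbor-interchange hill climbing with 1/d² weighted
least-squares branch lengths), then midpoint-rooted; a majority-rule
consensus amalgamates trees across methods.  Trees are scikit-bio
``TreeNode`` objects throughout and serialize as Newick with supports as
internal-node labels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import skbio
import skbio.tree
from scipy.optimize import nnls

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "cap_scores",
    "similarity_to_distance",
    "sim_to_dist_matrix",
    "mean_similarity",
    "upgma",
    "neighbor_joining",
    "fitch_margoliash",
    "midpoint_root",
    "consensus",
    "robinson_foulds",
    "tree_splits",
    "write_newick",
    "parse_newick",
    "write_matrix",
    "read_matrix",
    "read_phylip_lower",
]

SCORE_CAP = 1000.0


@dataclass
class SimilarityMatrix:
    """Symmetric labelled matrix of raw similarity scores."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if n and not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class DistanceMatrix:
    """Symmetric labelled distances with zero diagonal, entries in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if n:
            if not np.allclose(self.values, self.values.T, atol=1e-9):
                raise ValueError("distance matrix must be symmetric")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                raise ValueError("distance matrix must have a zero diagonal")
            if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-9:
                raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_skbio(self) -> skbio.DistanceMatrix:
        v = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(v, 0.0)
        return skbio.DistanceMatrix(v, ids=self.labels)


def cap_scores(m: SimilarityMatrix, cap: float = SCORE_CAP) -> SimilarityMatrix:
    """Clip every entry at ``cap`` (outliers above are set to the cap)."""
    return SimilarityMatrix(list(m.labels), np.minimum(m.values, cap))


def similarity_to_distance(score: float, cap: float = SCORE_CAP) -> float:
    """Map one raw score to a distance: |score/cap − 1|, rectified at 0.

    After capping this equals max(0, 1 − score/cap): 1000 → 0.0, 0 → 1.0.
    """
    if score < 0:
        raise ValueError("similarity scores must be >= 0")
    return abs(min(score, cap) / cap - 1.0)


def sim_to_dist_matrix(m: SimilarityMatrix, cap: float = SCORE_CAP) -> DistanceMatrix:
    """Elementwise similarity→distance transform; diagonal forced to 0."""
    if np.any(m.values < 0):
        raise ValueError("similarity scores must be >= 0")
    d = np.abs(np.minimum(m.values, cap) / cap - 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.labels), d)


def mean_similarity(ms: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise arithmetic mean over matrices with identical labels."""
    if not ms:
        raise ValueError("need at least one matrix")
    labels = ms[0].labels
    for m in ms[1:]:
        if m.labels != labels:
            raise ValueError("label sets/order differ between matrices")
    return SimilarityMatrix(list(labels), np.mean([m.values for m in ms], axis=0))


# ---------------------------------------------------------------------------
# tree building


def upgma(d: DistanceMatrix) -> skbio.TreeNode:
    """Average-linkage agglomeration; rooted ultrametric tree.

    Ties are broken by the lowest (row, column) index pair of the current
    cluster list, so an equal-all-pairs matrix yields a caterpillar.
    """
    n = d.n
    if n < 2:
        raise ValueError("UPGMA needs >= 2 leaves")
    D = d.values.copy()
    nodes = [skbio.TreeNode(name=lab) for lab in d.labels]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or D[i, j] < best[0] - 1e-15:
                    best = (D[i, j], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        h = D[i, j] / 2.0
        parent = skbio.TreeNode()
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = max(0.0, h - heights[child_idx])
            parent.append(child)
        # average-linkage update into slot i
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (sizes[i] + sizes[j])
        nodes[i] = parent
        heights[i] = h
        sizes[i] += sizes[j]
        active.pop(aj)
    return nodes[active[0]]


def neighbor_joining(d: DistanceMatrix) -> skbio.TreeNode:
    """Saitou–Nei neighbor joining (scikit-bio); unrooted tree.

    Negative branch lengths are clamped to 0 with a warning.
    """
    if d.n < 3:
        raise ValueError("neighbor joining needs >= 3 leaves")
    tree = skbio.tree.nj(d.to_skbio(), neg_as_zero=False)
    negs = [node for node in tree.traverse() if node.length is not None and node.length < 0]
    if negs:
        warnings.warn(f"clamped {len(negs)} negative branch length(s) to 0")
        for node in negs:
            node.length = 0.0
    return tree


# --- Fitch–Margoliash: graph representation, WLS lengths, NNI search ------


def _tree_to_graph(tree: skbio.TreeNode) -> tuple[dict, int]:
    """Unrooted adjacency {node: set(neighbors)}; leaves keep their names."""
    adj: dict = {}
    counter = [0]
    ids: dict = {}

    def nid(node):
        if node not in ids:
            if node.is_tip():
                ids[node] = node.name
            else:
                ids[node] = counter[0]
                counter[0] += 1
        return ids[node]

    for node in tree.traverse():
        for child in node.children:
            a, b = nid(node), nid(child)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    # suppress a degree-2 root left over from the rooted representation
    root_id = nid(tree)
    if len(adj.get(root_id, ())) == 2:
        x, y = sorted(adj[root_id], key=str)
        adj[x].discard(root_id)
        adj[y].discard(root_id)
        adj[x].add(y)
        adj[y].add(x)
        del adj[root_id]
    return adj, counter[0]


def _graph_edges(adj: dict) -> list[tuple]:
    seen = set()
    out = []
    for u, nbrs in adj.items():
        for v in nbrs:
            key = tuple(sorted((str(u), str(v))))
            if key not in seen:
                seen.add(key)
                out.append((u, v))
    return out


def _edge_sides(adj: dict, edges: list[tuple], leaves: list[str]) -> list[frozenset]:
    """For each edge, the leaf set on its first-endpoint side."""
    sides = []
    for u, v in edges:
        stack, comp = [u], {u}
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp and not (x == u and y == v):
                    comp.add(y)
                    stack.append(y)
        sides.append(frozenset(l for l in leaves if l in comp))
    return sides


def _wls_lengths(adj: dict, d: DistanceMatrix, weight_cap: float = 1e6
                 ) -> tuple[np.ndarray, float, list[tuple], list[frozenset]]:
    """1/d² weighted least-squares branch lengths (non-negative) + objective."""
    leaves = d.labels
    edges = _graph_edges(adj)
    sides = _edge_sides(adj, edges, leaves)
    pairs = [(i, j) for i in range(d.n) for j in range(i + 1, d.n)]
    A = np.zeros((len(pairs), len(edges)))
    for e, side in enumerate(sides):
        for r, (i, j) in enumerate(pairs):
            if (leaves[i] in side) != (leaves[j] in side):
                A[r, e] = 1.0
    y = np.array([d.values[i, j] for i, j in pairs])
    w = np.where(y > 0, 1.0 / np.maximum(y, 1e-12) ** 2, weight_cap)
    w = np.minimum(w, weight_cap)
    sw = np.sqrt(w)
    x, _ = nnls(A * sw[:, None], y * sw)
    resid = y - A @ x
    objective = float(np.sum(w * resid ** 2))
    return x, objective, edges, sides


def _nni_neighbors(adj: dict):
    """Yield adjacency dicts one nearest-neighbor interchange away."""
    for u, v in _graph_edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue  # internal edges of a binary tree only
        a_nbrs = sorted((x for x in adj[u] if x != v), key=str)
        b_nbrs = sorted((x for x in adj[v] if x != u), key=str)
        a2 = a_nbrs[1]
        for b in b_nbrs:
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(a2)
            new[a2].discard(u)
            new[v].discard(b)
            new[b].discard(v)
            new[u].add(b)
            new[b].add(u)
            new[v].add(a2)
            new[a2].add(v)
            yield new


def _graph_to_tree(adj: dict, lengths: np.ndarray, edges: list[tuple]) -> skbio.TreeNode:
    elen = {tuple(sorted((str(u), str(v)))): float(l) for (u, v), l in zip(edges, lengths)}
    start = next(k for k in adj if isinstance(k, str))  # root at a leaf's neighbor
    start = next(iter(adj[start]))

    def build(node, parent):
        tn = skbio.TreeNode(name=node if isinstance(node, str) else None)
        for nb in sorted(adj[node], key=str):
            if nb == parent:
                continue
            child = build(nb, node)
            child.length = elen[tuple(sorted((str(node), str(nb))))]
            tn.append(child)
        return tn

    return build(start, None)


def fitch_margoliash(d: DistanceMatrix, max_rounds: int = 50) -> skbio.TreeNode:
    """Fitch–Margoliash tree: NJ start + NNI hill climbing under the
    1/d²-weighted least-squares objective.

    Branch lengths are non-negative (active-set solve); the achieved
    objective is stored on the returned root as ``fm_objective`` and never
    increases across accepted NNI steps.
    """
    if d.n < 3:
        raise ValueError("Fitch-Margoliash needs >= 3 leaves")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = neighbor_joining(d)
    adj, _ = _tree_to_graph(start)
    lengths, obj, edges, _ = _wls_lengths(adj, d)
    improved = True
    rounds = 0
    while improved and rounds < max_rounds:
        improved = False
        rounds += 1
        for cand in _nni_neighbors(adj):
            cl, cobj, cedges, _ = _wls_lengths(cand, d)
            if cobj < obj - 1e-12:
                adj, lengths, obj, edges = cand, cl, cobj, cedges
                improved = True
                break
    tree = _graph_to_tree(adj, lengths, edges)
    tree.fm_objective = obj
    return tree


def midpoint_root(t: skbio.TreeNode) -> skbio.TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    lengths = [n.length for n in t.traverse() if n.length is not None]
    if not lengths or all(l == 0 for l in lengths):
        raise ValueError("cannot midpoint-root a tree with all-zero branch lengths")
    return t.copy().root_at_midpoint()


# ---------------------------------------------------------------------------
# splits, consensus, Robinson-Foulds


def tree_splits(t: skbio.TreeNode, with_lengths: bool = False):
    """Non-trivial unrooted splits, each as the side excluding the
    alphabetically first leaf; optionally with the split's branch length."""
    leaves = sorted(tip.name for tip in t.tips())
    ref = leaves[0]
    universe = frozenset(leaves)
    out = {} if with_lengths else set()
    for node in t.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= len(leaves) - 2:
            if with_lengths:
                out[side] = float(node.length or 0.0)
            else:
                out.add(side)
    return out


def robinson_foulds(t1: skbio.TreeNode, t2: skbio.TreeNode) -> int:
    """Symmetric difference of unrooted non-trivial split sets."""
    l1 = {tip.name for tip in t1.tips()}
    l2 = {tip.name for tip in t2.tips()}
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    return len(tree_splits(t1) ^ tree_splits(t2))


def _compatible(s: frozenset, kept: list[frozenset]) -> bool:
    for k in kept:
        if not (s <= k or k <= s or not (s & k)):
            return False
    return True


def consensus(trees: list[skbio.TreeNode], threshold: float = 0.5) -> skbio.TreeNode:
    """Majority-rule consensus: splits in > ``threshold`` fraction of trees.

    Internal nodes carry ``support`` (occurrence fraction) and a branch
    length equal to the mean over the trees containing the split; leaf
    branch lengths average over all trees.
    """
    if len(trees) < 2:
        raise ValueError("consensus needs >= 2 trees")
    leafsets = [frozenset(tip.name for tip in t.tips()) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("trees must share an identical leaf set")
    leaves = sorted(leafsets[0])
    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    for t in trees:
        for side, ln in tree_splits(t, with_lengths=True).items():
            counts[side] = counts.get(side, 0) + 1
            lengths.setdefault(side, []).append(ln)
    n = len(trees)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), sorted(kv[0])))
    kept: list[frozenset] = []
    for side, c in ranked:
        if c / n > threshold and _compatible(side, kept):
            kept.append(side)
    # leaf branch lengths: mean over trees
    leaf_len = {
        leaf: float(np.mean([t.find(leaf).length or 0.0 for t in trees]))
        for leaf in leaves
    }
    root = skbio.TreeNode()
    tipnodes = {}
    for leaf in leaves:
        tn = skbio.TreeNode(name=leaf, length=leaf_len[leaf])
        root.append(tn)
        tipnodes[leaf] = tn
    def tipset(node) -> frozenset:
        if node.is_tip():
            return frozenset([node.name])
        return frozenset(t.name for t in node.tips())

    for side in sorted(kept, key=len):
        # group the current children of root (or deeper) whose tip sets ⊆ side
        parent = root
        while True:
            nxt = next((c for c in parent.children if not c.is_tip()
                        and side < tipset(c)), None)
            if nxt is None:
                break
            parent = nxt
        group = [c for c in parent.children if tipset(c) <= side]
        if not group or frozenset().union(*(tipset(c) for c in group)) != side:
            continue  # incompatible with an earlier, better-supported split
        node = skbio.TreeNode(length=float(np.mean(lengths[side])))
        node.support = counts[side] / n
        for c in group:
            parent.remove(c)
            node.append(c)
        parent.append(node)
    return root


# ---------------------------------------------------------------------------
# serialization


def _quote(name: str) -> str:
    if any(ch in name for ch in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(t: skbio.TreeNode) -> str:
    """Newick with 6-significant-digit branch lengths; internal labels are
    split supports when present, otherwise the node name."""

    def fmt(node) -> str:
        if node.is_tip():
            s = _quote(node.name or "")
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            sup = getattr(node, "support", None)
            if sup is not None:
                label = f"{sup:.6g}"
            elif node.name:
                label = _quote(node.name)
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{node.length:.6g}"
        return s

    return fmt(t) + ";"


def parse_newick(s: str) -> skbio.TreeNode:
    """Parse Newick; internal labels that parse as floats become supports."""
    depth = 0
    for pos, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise ValueError(f"unbalanced parentheses: {depth} '(' left open")
    t = skbio.TreeNode.read(io.StringIO(s))
    for node in t.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return t


# ---------------------------------------------------------------------------
# matrix text I/O


def write_matrix(m: SimilarityMatrix | DistanceMatrix) -> str:
    """Square labelled tab-separated text."""
    lines = ["\t" + "\t".join(m.labels)]
    for lab, row in zip(m.labels, m.values):
        lines.append(lab + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


def read_matrix(text: str, kind: str = "distance") -> SimilarityMatrix | DistanceMatrix:
    """Read the square labelled TSV written by :func:`write_matrix`."""
    lines = [l for l in text.splitlines() if l.strip()]
    labels = lines[0].split("\t")[1:]
    rows = []
    for l in lines[1:]:
        parts = l.split("\t")
        rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    cls = DistanceMatrix if kind == "distance" else SimilarityMatrix
    return cls(labels, values)


def read_phylip_lower(text: str, kind: str = "distance") -> SimilarityMatrix | DistanceMatrix:
    """Read a PHYLIP lower-triangular distance file."""
    lines = [l for l in text.splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, values = [], np.zeros((n, n))
    for i, line in enumerate(lines[1:n + 1]):
        parts = line.split()
        labels.append(parts[0])
        for j, v in enumerate(parts[1:i + 1]):
            values[i, j] = values[j, i] = float(v)
    cls = DistanceMatrix if kind == "distance" else SimilarityMatrix
    return cls(labels, values)
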