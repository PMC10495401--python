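"""Jukes-Cantor phylogenetics on a precomputed multiple alignment.

The JC69 model assumes equal base frequencies and a single exchange rate,
giving the distance ``d = -(3/4) ln(1 - (4/3) p)`` for an observed
mismatch fraction p, and transition probabilities

    P_same(t) = 1/4 + 3/4 exp(-4t/3)
    P_diff(t) = 1/4 - 1/4 exp(-4t/3)

with t in expected substitutions per site. Likelihoods are computed by
Felsenstein pruning over compressed site patterns; gaps and Ns are
marginalized as missing data. Distances use pairwise deletion of
gap/N columns.

Maximum likelihood: for small taxon sets every unrooted topology is
enumerated and branch lengths are optimized per topology by cyclic
one-dimensional search; for larger sets a neighbor-joining start is
refined by nearest-neighbor-interchange hill climbing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING = 4


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class Node:
    """Tree node; ``length`` is the branch above the node (ignored at root)."""

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def copy(self) -> "Node":
        return Node(self.name, [c.copy() for c in self.children],
                    self.length, self.support)

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if with_support and node.support is not None and not top:
                    body += f"{node.support:.0f}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self, True) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted tree, as canonical frozensets."""
        all_taxa = frozenset(self.leaf_names())
        splits: set[frozenset] = set()
        for node in self.postorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_taxa - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits


def same_topology(a: Node, b: Node) -> bool:
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return a.bipartitions() == b.bipartitions()


def parse_newick(text: str) -> Node:
    """Minimal newick parser (names, branch lengths, support on internals)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node.length = float(text[start:pos])
        return node

    return parse()


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal; inf marks saturation

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def jc_distance(p_mismatch: float) -> float:
    """JC69 distance for an observed mismatch fraction; inf when saturated."""
    if not 0.0 <= p_mismatch <= 1.0:
        raise ValueError("mismatch fraction must lie in [0, 1]")
    if p_mismatch >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-(4.0 / 3.0) * p_mismatch)


def encode_alignment(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode an aligned dict name->sequence as an (n_taxa, n_sites) int array."""
    taxa = list(msa)
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    n_sites = lengths.pop()
    arr = np.full((len(taxa), n_sites), MISSING, dtype=np.int8)
    for i, t in enumerate(taxa):
        row = np.frombuffer(msa[t].upper().encode(), dtype="S1")
        for base, code in _CODE.items():
            arr[i, row == base.encode()] = code
    return taxa, arr


def distance_matrix(msa: dict[str, str]) -> DistanceMatrix:
    """Pairwise JC distances with pairwise deletion of gap/N columns."""
    taxa, arr = encode_alignment(msa)
    n = len(taxa)
    mat = np.zeros((n, n))
    ok = arr != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable sites between {taxa[i]} and {taxa[j]}")
            p = float((arr[i, both] != arr[j, both]).mean())
            mat[i, j] = mat[j, i] = jc_distance(p)
    return DistanceMatrix(taxa=taxa, matrix=mat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> Node:
    """Canonical neighbor joining (Q-criterion), tie-broken by taxon names.

    Negative branch-length estimates are clamped to zero. The returned tree
    is unrooted, represented with a trifurcating top node.
    """
    nodes = [Node(name=t) for t in dm.taxa]
    # deterministic label for tie-breaking: smallest leaf name under each node
    labels = [t for t in dm.taxa]
    d = dm.matrix.astype(float).copy()
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                key = (q[ai, aj], min(labels[active[ai]], labels[active[aj]]),
                       max(labels[active[ai]], labels[active[aj]]))
                if best is None or key < best[0:3]:
                    best = (key[0], key[1], key[2], ai, aj)
        _, _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances to the new node
        newrow = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for ak in range(m):
            if ak in (ai, aj):
                continue
            other = active[ak]
            d[k, other] = d[other, k] = 0.5 * (d[i, other] + d[j, other] - dij)
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [a for a in active if a not in (i, j)] + [k]
    # join the final three under a trifurcating top node
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, l in ((i, li), (j, lj), (k, lk)):
            nodes[idx].length = max(l, 0.0)
        return Node(children=[nodes[i], nodes[j], nodes[k]])
    i, j = active
    nodes[i].length = 0.0
    nodes[j].length = max(d[i, j], 0.0)
    return Node(children=[nodes[i], nodes[j]])


# ---------------------------------------------------------------------------
# Likelihood


def _jc_pmatrix(t: float) -> np.ndarray:
    e = math.exp(-4.0 * max(t, 0.0) / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def compress_patterns(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their multiplicities."""
    patterns, counts = np.unique(arr, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _partials(node: Node, patterns: np.ndarray, taxon_index: dict[str, int]) -> np.ndarray:
    if node.is_leaf:
        states = patterns[taxon_index[node.name]]
        part = np.zeros((patterns.shape[1], 4))
        obs = states != MISSING
        part[obs, states[obs]] = 1.0
        part[~obs, :] = 1.0
        return part
    part = np.ones((patterns.shape[1], 4))
    for child in node.children:
        p = _jc_pmatrix(child.length)
        part *= _partials(child, patterns, taxon_index) @ p.T
    return part


def jc_loglik(tree: Node, msa: dict[str, str]) -> float:
    """Log-likelihood of the alignment under JC69 on the given tree.

    Uniform base frequencies; gap/N treated as missing and marginalized;
    site patterns compressed. The value is invariant to the placement of
    the (arbitrary) root because JC is time-reversible.
    """
    taxa, arr = encode_alignment(msa)
    patterns, counts = compress_patterns(arr)
    return _loglik_compressed(tree, patterns, counts, {t: i for i, t in enumerate(taxa)})


def _loglik_compressed(tree: Node, patterns: np.ndarray, counts: np.ndarray,
                       taxon_index: dict[str, int]) -> float:
    part = _partials(tree, patterns, taxon_index)
    site_lik = 0.25 * part.sum(axis=1)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(counts @ np.log(site_lik))


# ---------------------------------------------------------------------------
# ML search


def _all_edges(tree: Node) -> list[Node]:
    """Every node below the top node (each owns the branch above it)."""
    return [n for n in tree.postorder() if n is not tree]


def _site_likelihoods(tree: Node, patterns: np.ndarray,
                      taxon_index: dict[str, int]) -> np.ndarray:
    part = _partials(tree, patterns, taxon_index)
    return 0.25 * part.sum(axis=1)


_T_MIN, _T_MAX = 1e-9, 10.0


def optimize_branch_lengths(tree: Node, patterns: np.ndarray, counts: np.ndarray,
                            taxon_index: dict[str, int], tol: float = 1e-6,
                            max_passes: int = 50) -> float:
    """Cyclic per-branch optimization of every branch length in place.

    Under JC each site likelihood is linear in ``e = exp(-4t/3)`` when all
    other branches are held fixed, so one branch needs only two full-tree
    evaluations (at t=0 and t=inf) before a cheap bounded 1-D search over e.
    """
    edges = _all_edges(tree)
    prev = _loglik_compressed(tree, patterns, counts, taxon_index)
    for _ in range(max_passes):
        for edge in edges:
            edge.length = 0.0          # e = 1
            sl1 = _site_likelihoods(tree, patterns, taxon_index)
            edge.length = 1e9          # e ~ 0
            alpha = _site_likelihoods(tree, patterns, taxon_index)
            beta = sl1 - alpha

            def neg(e: float) -> float:
                v = alpha + beta * e
                if np.any(v <= 0):
                    return math.inf
                return -float(counts @ np.log(v))

            e_lo = math.exp(-4.0 * _T_MAX / 3.0)
            e_hi = math.exp(-4.0 * _T_MIN / 3.0)
            res = minimize_scalar(neg, bounds=(e_lo, e_hi), method="bounded",
                                  options={"xatol": 1e-12})
            edge.length = -0.75 * math.log(float(res.x))
        cur = _loglik_compressed(tree, patterns, counts, taxon_index)
        if cur - prev < tol:
            return cur
        prev = cur
    return prev


def enumerate_topologies(taxa: list[str]) -> list[Node]:
    """All unrooted topologies (trifurcating top node) for the taxon list."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    base = Node(children=[Node(name=t) for t in taxa[:3]])
    trees = [base]
    for name in taxa[3:]:
        grown: list[Node] = []
        for t in trees:
            for i in range(len(_all_edges(t))):
                c = t.copy()
                edge = _all_edges(c)[i]
                parent = _find_parent(c, edge)
                split = Node(children=[edge, Node(name=name)])
                parent.children[parent.children.index(edge)] = split
                grown.append(c)
        trees = grown
    return trees


def _find_parent(tree: Node, target: Node) -> Node:
    for node in tree.postorder():
        if target in node.children:
            return node
    raise ValueError("node not in tree")


def _nni_neighbors(tree: Node):
    """Trees one nearest-neighbor interchange away (internal edges only)."""
    for node in list(tree.postorder()):
        if node is tree or node.is_leaf:
            continue
        parent = _find_parent(tree, node)
        siblings = [c for c in parent.children if c is not node]
        if not siblings or len(node.children) != 2:
            continue
        sib = siblings[0]
        a, b = node.children
        for swap_child in (0, 1):
            t2 = tree.copy()
            # locate corresponding nodes in the copy by walking both trees
            pairs = list(zip(tree.postorder(), t2.postorder()))
            mapping = {id(x): y for x, y in pairs}
            node2 = mapping[id(node)]
            parent2 = mapping[id(parent)]
            sib2 = mapping[id(sib)]
            child2 = mapping[id((a, b)[swap_child])]
            parent2.children[parent2.children.index(sib2)] = child2
            node2.children[node2.children.index(child2)] = sib2
            sib2.length, child2.length = child2.length, sib2.length
            yield t2


def ml_search(msa: dict[str, str], max_exhaustive: int = 7) -> tuple[Node, float]:
    """Maximum-likelihood JC tree.

    Up to ``max_exhaustive`` taxa: exhaustive topology enumeration with
    per-topology branch-length optimization (ties broken by enumeration
    order). Beyond that: NJ starting tree refined by NNI hill climbing.
    Returns (tree, log-likelihood).
    """
    if len(msa) < 3:
        raise ValueError("ML search needs at least 3 taxa")
    taxa, arr = encode_alignment(msa)
    patterns, counts = compress_patterns(arr)
    index = {t: i for i, t in enumerate(taxa)}

    def optimized(tree: Node) -> float:
        for e in _all_edges(tree):
            if e.length <= 0:
                e.length = 0.05
        return optimize_branch_lengths(tree, patterns, counts, index)

    if len(taxa) <= max_exhaustive:
        best_tree, best_ll = None, -math.inf
        for cand in enumerate_topologies(taxa):
            ll = optimized(cand)
            if ll > best_ll + 1e-9:
                best_tree, best_ll = cand, ll
        return best_tree, best_ll

    tree = nj_tree(distance_matrix(msa))
    best_ll = optimized(tree)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(tree):
            ll = optimized(cand)
            if ll > best_ll + 1e-6:
                tree, best_ll = cand, ll
                improved = True
                break
    return tree, best_ll


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: dict[str, str], n_reps: int, seed: int,
                      method: str = "ml") -> Node:
    """Nonparametric bootstrap supports on the best tree.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is analyzed with ``ml_search`` (method="ml") or NJ (method="nj", much
    faster); support is the percentage of replicates whose tree contains
    each internal bipartition of the best tree. ``n_reps == 0`` returns the
    best tree without supports.
    """
    best, _ = ml_search(msa) if method == "ml" else (nj_tree(distance_matrix(msa)), 0.0)
    if n_reps == 0:
        return best
    taxa = list(msa)
    n_sites = len(msa[taxa[0]])
    rng = np.random.default_rng(seed)
    split_hits: dict[frozenset, int] = {s: 0 for s in best.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = {t: "".join(msa[t][c] for c in cols) for t in taxa}
        if method == "ml":
            rep_tree, _ = ml_search(rep)
        else:
            rep_tree = nj_tree(distance_matrix(rep))
        rep_splits = rep_tree.bipartitions()
        for s in split_hits:
            if s in rep_splits:
                split_hits[s] += 1
    all_taxa = frozenset(taxa)
    for node in best.postorder():
        if node is best or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
        if key in split_hits:
            node.support = 100.0 * split_hits[key] / n_reps
    return best
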