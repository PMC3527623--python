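"""Neighbor-joining trees with bootstrap supports.

Implements Saitou–Nei neighbor joining with a deterministic tie rule (the
lexicographically smallest id pair wins an equal Q-criterion) and the usual
negative-branch-length correction: a negative estimate is clamped to zero
and the deficit moved onto the sister branch so path lengths are preserved.

Nodal supports are nonparametric bootstraps: alignment columns are
resampled with replacement, a replicate NJ tree is built from each
resampled distance matrix, and the support of an internal edge of the
original tree is the percentage of replicates containing the same
(unrooted) bipartition.

The NJ algorithm here is intentionally in-package: the deterministic tie
rule and clamping convention are part of the tool's contract, and an
independent library implementation serves as the cross-check in the test
suite rather than as the production path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from barcodekit.distmat import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    Model,
    _base_mask,
    _encode,
    k2p,
)
from barcodekit.seqio import AlignedRecord

DEFAULT_COLLAPSE_EPSILON = 1e-9
MAX_REPLICATE_REDRAWS = 100


@dataclass
class SupportTree:
    """An NJ topology with branch lengths and optional bootstrap supports.

    ``supports`` maps a canonical bipartition key — the frozenset of leaf
    ids on the smaller side (ties broken lexicographically) — to an integer
    percentage.  Supports are also written onto internal node labels so
    newick output carries them.
    """

    tree: dendropy.Tree
    supports: dict[frozenset[str], int] = field(default_factory=dict)
    collapse_epsilon: float = DEFAULT_COLLAPSE_EPSILON
    n_bootstrap: int = 0

    @property
    def leaf_ids(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def clone(self) -> "SupportTree":
        return SupportTree(
            tree=self.tree.clone(depth=1),
            supports=dict(self.supports),
            collapse_epsilon=self.collapse_epsilon,
            n_bootstrap=self.n_bootstrap,
        )


def _bipartition_key(tree: dendropy.Tree, edge: dendropy.Edge) -> frozenset[str]:
    """Canonical unrooted bipartition key for an internal edge."""
    below = {
        lf.taxon.label for lf in edge.head_node.leaf_iter()
    }
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    other = all_leaves - below
    # Smaller side; lexicographic tie-break for equal sizes.
    if (len(below), sorted(below)) <= (len(other), sorted(other)):
        return frozenset(below)
    return frozenset(other)


def internal_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions of a tree, as canonical keys."""
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    keys = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        key = _bipartition_key(tree, edge)
        if 1 < len(key) < n_leaves - 1:
            keys.add(key)
    return keys


def _nj_from_array(dist: np.ndarray, ids: list[str]) -> dendropy.Tree:
    """Saitou–Nei NJ on a full distance array; deterministic tie rule."""
    n = len(ids)
    taxa = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for sid in ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(nd)
    # Representative id per cluster = smallest contained leaf id.
    reps = list(ids)
    active = list(range(n))
    D = dist.astype(float).copy()

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                if (
                    best is None
                    or q < best - 1e-15
                    or (abs(q - best) <= 1e-15 and pair_key < best_pair)
                ):
                    best = q
                    best_pair = pair_key
                    bi, bj = i, j
        i, j = bi, bj
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        # Negative-length correction: clamp, move deficit to the sister.
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # Reuse slot i for the merged cluster.
        new_idx = i
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[new_idx] = parent
        reps[new_idx] = min(reps[i], reps[j])
        active.remove(j)

    # Join the last three clusters at an unrooted central node.
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(length, 0.0)
        center.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def nj(matrix: DistanceMatrix) -> SupportTree:
    """Neighbor-joining tree from a fully defined distance matrix."""
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("NJ requires at least 3 taxa")
    undefined = [
        (p.id_a, p.id_b) for p in matrix.iter_pairs() if not p.defined
    ]
    if undefined:
        raise ValueError(
            f"distance matrix has undefined entries (e.g. {undefined[0]}); "
            "restrict the dataset before tree building"
        )
    n = len(ids)
    arr = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = matrix.pair(ids[i], ids[j]).d
            arr[i, j] = arr[j, i] = d
    return SupportTree(tree=_nj_from_array(arr, ids))


def _pair_site_arrays(records: list[AlignedRecord]):
    """Per-pair, per-column indicator matrices for fast bootstrap counting."""
    enc = [_encode(r.seq) for r in records]
    masks = [_base_mask(a) for a in enc]
    purine = [(a == ord("A")) | (a == ord("G")) for a in enc]
    n = len(records)
    L = len(records[0].seq)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.zeros((len(pairs), L), dtype=np.float64)
    ts = np.zeros((len(pairs), L), dtype=np.float64)
    tv = np.zeros((len(pairs), L), dtype=np.float64)
    for p, (i, j) in enumerate(pairs):
        both = masks[i] & masks[j]
        diff = (enc[i] != enc[j]) & both
        valid[p] = both
        ts[p] = diff & (purine[i] == purine[j])
        tv[p] = diff & (purine[i] != purine[j])
    return pairs, valid, ts, tv


def _distances_from_counts(
    n_sites: np.ndarray, n_ts: np.ndarray, n_tv: np.ndarray, model: Model,
    min_overlap: int,
) -> np.ndarray | None:
    """Vector of pair distances, or None if any pair is undefined."""
    if np.any(n_sites < min_overlap):
        return None
    P = n_ts / n_sites
    Q = n_tv / n_sites
    if model == "uncorrected":
        return P + Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        return None
    return -0.5 * np.log(w1 * np.sqrt(w2))


def bootstrap_supports(
    records: list[AlignedRecord],
    model: Model = "k2p",
    B: int = 1000,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SupportTree:
    """NJ tree of the full alignment with column-bootstrap edge supports.

    Columns are resampled with replacement ``B`` times; a replicate whose
    resampled matrix contains an undefined pair (below the overlap floor or
    K2P-saturated) is redrawn, up to 100 attempts per replicate, so the
    replicate count is preserved.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids = [r.id for r in records]
    L = len(records[0].seq)
    pairs, valid, ts, tv = _pair_site_arrays(records)

    full_d = _distances_from_counts(
        valid.sum(axis=1), ts.sum(axis=1), tv.sum(axis=1), model, min_overlap
    )
    if full_d is None:
        raise ValueError("full alignment has undefined pairs; cannot bootstrap")
    n = len(ids)
    arr = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        arr[i, j] = arr[j, i] = full_d[p]
    base = _nj_from_array(arr, ids)
    base_tree = SupportTree(tree=base, n_bootstrap=B)
    targets = internal_bipartitions(base)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {key: 0 for key in targets}
    for _ in range(B):
        rep_d = None
        for _attempt in range(MAX_REPLICATE_REDRAWS):
            cols = rng.integers(0, L, size=L)
            w = np.bincount(cols, minlength=L).astype(np.float64)
            rep_d = _distances_from_counts(
                valid @ w, ts @ w, tv @ w, model, min_overlap
            )
            if rep_d is not None:
                break
        if rep_d is None:
            raise RuntimeError(
                "bootstrap replicate kept producing undefined pairs "
                f"after {MAX_REPLICATE_REDRAWS} redraws"
            )
        for p, (i, j) in enumerate(pairs):
            arr[i, j] = arr[j, i] = rep_d[p]
        rep_tree = _nj_from_array(arr, ids)
        rep_splits = internal_bipartitions(rep_tree)
        for key in targets:
            if key in rep_splits:
                counts[key] += 1

    supports = {key: round(100.0 * c / B) for key, c in counts.items()}
    base_tree.supports = supports
    _annotate_supports(base_tree)
    return base_tree


def _annotate_supports(stree: SupportTree) -> None:
    """Write supports onto internal node labels for newick output."""
    for edge in stree.tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        key = _bipartition_key(stree.tree, edge)
        if key in stree.supports:
            head.label = str(stree.supports[key])


def collapse(stree: SupportTree, epsilon: float = DEFAULT_COLLAPSE_EPSILON) -> SupportTree:
    """Contract internal edges with length <= epsilon into polytomies."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    out = stree.clone()
    out.collapse_epsilon = epsilon
    to_collapse = []
    for nd in out.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        if nd.edge.length is not None and nd.edge.length <= epsilon:
            to_collapse.append(nd.edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def root_tree(
    stree: SupportTree, outgroup: str | None = None
) -> SupportTree:
    """Rooted view for tree-based identification.

    Roots at the outgroup leaf's edge when given, else at the midpoint.
    """
    out = stree.clone()
    if outgroup is not None:
        node = out.tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        out.tree.reroot_at_edge(
            node.edge, length1=(node.edge.length or 0.0) / 2.0,
            length2=(node.edge.length or 0.0) / 2.0,
            update_bipartitions=False,
        )
    else:
        out.tree.reroot_at_midpoint(update_bipartitions=False)
    out.tree.is_rooted = True
    return out


def prune_leaves(stree: SupportTree, drop: list[str]) -> SupportTree:
    """Remove leaves (e.g. an outgroup) before identification scoring."""
    out = stree.clone()
    taxa = [
        out.tree.taxon_namespace.get_taxon(name)
        for name in drop
    ]
    taxa = [t for t in taxa if t is not None]
    if taxa:
        out.tree.prune_taxa(taxa)
    return out
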