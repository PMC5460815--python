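"""p-distance neighbor-joining phylogeny with column-bootstrap support.

The distance model is the p-distance: the proportion of differing sites over
compared sites, where gap-containing positions are excluded either per pair
(``pairwise-delete``) or across the whole alignment (``complete-delete``).
Trees are built with the Saitou-Nei neighbor-joining agglomeration (Q-matrix
minimization with the standard branch-length formulas). NJ is consistent on
additive matrices, so a tree whose path-length matrix is the input is
recovered exactly. Q-ties are broken by the smallest (i, j) index pair and
negative branch lengths are clamped to zero (the clamped deficit is kept on
the tree object), so output is deterministic.

Branch support is estimated by bootstrap: alignment columns are resampled
with replacement, an NJ tree is built per replicate, and each internal
bipartition of the full-data tree is scored by the percentage of replicate
trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DwdfamError, UndefinedDistanceError

_GAP_CHARS = frozenset("-.?")


@dataclass
class AlignedSet:
    """A protein multiple alignment: parallel id and row lists, equal lengths."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise DwdfamError("ids and rows differ in length")
        if len(self.ids) != len(set(self.ids)):
            raise DwdfamError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DwdfamError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subsample_columns(self, columns: np.ndarray) -> "AlignedSet":
        return AlignedSet(self.ids, ["".join(r[c] for c in columns) for r in self.rows])


def p_distance(aligned: AlignedSet, gap_policy: str = "pairwise-delete") -> np.ndarray:
    """Symmetric p-distance matrix (order = ``aligned.ids``).

    Raises :class:`UndefinedDistanceError` naming the first pair with zero
    comparable sites.
    """
    if gap_policy not in ("pairwise-delete", "complete-delete"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if len(aligned.ids) < 2:
        raise DwdfamError("p-distance needs at least 2 sequences")
    mat = np.array([list(r.upper()) for r in aligned.rows])
    is_gap = np.isin(mat, list(_GAP_CHARS))
    if gap_policy == "complete-delete":
        keep = ~is_gap.any(axis=0)
        mat, is_gap = mat[:, keep], is_gap[:, keep]
    n = len(aligned.ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise UndefinedDistanceError(aligned.ids[i], aligned.ids[j])
            diff = int((mat[i, ok] != mat[j, ok]).sum())
            dm[i, j] = dm[j, i] = diff / compared
    return dm


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted NJ tree: a degree-3 'root' joining three subtrees.

    ``clamped_deficit`` accumulates the absolute amount of negative branch
    length clamped to zero during construction.
    """

    root: _Node
    ids: list[str]
    clamped_deficit: float = 0.0

    def newick(self, support: bool = False) -> str:
        def fmt(node: _Node) -> str:
            if not node.children:
                return node.label
            inner = ",".join(f"{fmt(c)}:{l:.10g}" for c, l in node.children)
            label = ""
            if support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial internal bipartitions, each canonicalized as the side
        not containing the lexicographically smallest taxon."""
        ref = min(self.ids)
        all_ids = set(self.ids)
        out: set[frozenset] = set()
        for node in self._internal_nodes():
            side = set(node.leaves())
            if ref in side:
                side = all_ids - side
            if 1 < len(side) < len(all_ids) - 1:
                out.add(frozenset(side))
        return out

    def _internal_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, _ in node.children:
                if child.children:
                    yield child
                    stack.append(child)

    def annotate_support(self, supports: dict[frozenset, float]) -> None:
        ref = min(self.ids)
        all_ids = set(self.ids)
        for node in self._internal_nodes():
            side = set(node.leaves())
            if ref in side:
                side = all_ids - side
            key = frozenset(side)
            if key in supports:
                node.support = supports[key]


def nj_tree(dm: np.ndarray, ids: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Requires >= 3 taxa and a finite, symmetric, non-negative matrix with a
    zero diagonal. Q-minimization ties break to the smallest (i, j) pair;
    negative branch lengths are clamped to zero with the deficit recorded.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(ids)
    if n < 3:
        raise DwdfamError("neighbor joining needs at least 3 taxa")
    if dm.shape != (n, n):
        raise DwdfamError(f"distance matrix shape {dm.shape} does not match {n} ids")
    if not np.all(np.isfinite(dm)):
        raise DwdfamError("non-finite distances")
    if np.any(dm < 0) or not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise DwdfamError("matrix must be symmetric, non-negative, zero-diagonal")

    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    nodes: list[_Node] = [_Node(label=i) for i in ids]
    d = dm.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) on ties: flatten index order is row-major
        flat = int(np.argmin(q))
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining taxa
        new_d = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_d[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three nodes through a central degree-3 node
    a, b, c = active
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, ids=list(ids), clamped_deficit=deficit)


def resample_support(
    aligned: AlignedSet,
    replicates: int = 1000,
    seed: int | None = None,
    gap_policy: str = "pairwise-delete",
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column-bootstrap support for the full-data NJ tree.

    Resamples alignment columns with replacement ``replicates`` times,
    rebuilds an NJ tree per replicate, and scores each internal bipartition
    of the full-data tree by the percentage of replicate trees containing
    it. Returns the (support-annotated) tree and the bipartition->percent
    map. Seeded and reproducible.
    """
    if replicates < 1:
        raise DwdfamError("replicates must be >= 1")
    tree = nj_tree(p_distance(aligned, gap_policy), aligned.ids)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = aligned.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = aligned.subsample_columns(cols)
        rep_tree = nj_tree(p_distance(rep, gap_policy), rep.ids)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    tree.annotate_support(supports)
    return tree, supports


def midpoint_root(newick: str) -> str:
    """Midpoint-root a Newick tree (display convention) via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def cut_clades(newick: str, k: int) -> list[list[str]]:
    """Split a midpoint-rooted tree into ``k`` leaf groups by cutting the
    k - 1 internal edges closest to the root (deepest splits first).

    A reading aid for assigning coarse phylogenetic groups; group membership
    depends on the rooting and is not a calibrated clustering.
    """
    if k < 1:
        raise DwdfamError("k must be >= 1")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    try:
        tree.reroot_at_midpoint(update_bipartitions=True)
    except Exception:
        pass  # already rooted or degenerate; cut as-is
    groups: list = [tree.seed_node]
    while len(groups) < k:
        # expand the group whose root is closest to the tree root
        depths = {
            node: node.distance_from_root()
            for node in groups
            if node.child_nodes()
        }
        if not depths:
            break
        node = min(depths, key=lambda nd: (depths[nd], id(nd)))
        groups.remove(node)
        groups.extend(node.child_nodes())
    return sorted(
        [sorted(lf.taxon.label for lf in nd.leaf_iter()) for nd in groups]
    )
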