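"""Distance-based phylogeny: p-distance, neighbor joining, bootstrap,
and subfamily assignment from labeled reference domains.

Neighbor joining (Saitou & Nei) iteratively joins the pair minimizing

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

with branch lengths from the standard two-point formulas; the result is
an unrooted tree represented with a trifurcating root.  Bootstrap support
resamples alignment columns with replacement, rebuilds the tree, and
counts how many replicates contain each internal-edge bipartition of the
original tree.  Wheat query domains inherit the subfamily of their
nearest labeled reference leaf by patristic distance, with a distance
ceiling beyond which a query stays "unplaced" — subfamilies with no
nearby reference simply do not attract queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from bhlh_survey.domain_profile import GAP, DomainHit
from bhlh_survey.io_formats import ValidationError

logger = logging.getLogger("bhlh_survey")

MIN_COMPARABLE_COLUMNS = 20


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a list of low-overlap pairs."""

    ids: list[str]
    d: np.ndarray
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")


class TreeNode:
    """A node in a (possibly unrooted) tree; leaves carry names."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: int | None = None) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """An unrooted tree stored with a trifurcating root (for n >= 3 leaves)."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf labels")
        return names  # type: ignore[return-value]

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                if not node.name:
                    raise ValidationError("unlabeled leaf cannot be serialized")
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6f}"
        if len(self.leaves()) < 2:
            raise ValidationError("tree must have at least 2 leaves")
        return fmt(self.root) + ";"

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions keyed by the canonical leaf-name side.

        The canonical side is the one NOT containing the alphabetically
        smallest leaf, so keys are comparable across trees on the same
        taxon set regardless of rooting.
        """
        all_names = frozenset(self.leaf_names())
        anchor = min(all_names)
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.root.walk():
            if node.parent is None or node.is_leaf():
                continue
            side = frozenset(l.name for l in node.walk() if l.is_leaf())
            if anchor in side:
                side = all_names - side
            if len(side) >= 2 and len(all_names - side) >= 2:
                out[side] = node
        return out

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """All-pairs leaf distances as (names, matrix)."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        depth: dict[int, float] = {}

        def set_depth(node: TreeNode, d: float) -> None:
            depth[id(node)] = d
            for c in node.children:
                set_depth(c, d + c.length)

        set_depth(self.root, 0.0)

        def ancestors(node: TreeNode) -> list[TreeNode]:
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            return path

        n = len(leaves)
        mat = np.zeros((n, n))
        anc = [ancestors(l) for l in leaves]
        anc_sets = [{id(a) for a in path} for path in anc]
        for i in range(n):
            for j in range(i + 1, n):
                lca_depth = 0.0
                for a in anc[i]:
                    if id(a) in anc_sets[j]:
                        lca_depth = depth[id(a)]
                        break
                dij = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * lca_depth
                mat[i, j] = mat[j, i] = dij
        return names, mat


def aligned_from_hits(hits: Sequence[DomainHit]) -> dict[str, str]:
    """Profile-coordinate aligned domain strings keyed by protein id."""
    out = {}
    for h in hits:
        if h.protein_id in out:
            raise ValidationError(f"duplicate protein id {h.protein_id}")
        out[h.protein_id] = h.residues
    return out


def p_distance(
    aligned: Mapping[str, str] | Sequence[DomainHit],
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise distance over shared non-gap columns.

    p-distance = mismatches / comparable columns; ``model="poisson"``
    applies the Poisson correction -ln(1-p).  Pairs with fewer than
    20 comparable columns are flagged; zero comparable columns is an
    error naming the pair.
    """
    if not isinstance(aligned, Mapping):
        aligned = aligned_from_hits(aligned)
    ids = list(aligned)
    if len(ids) < 3:
        raise ValidationError("need at least 3 sequences for a distance matrix")
    ncol = len(next(iter(aligned.values())))
    if any(len(s) != ncol for s in aligned.values()):
        raise ValidationError("sequences must share the same aligned length")

    seqs = np.array([list(aligned[i]) for i in ids])
    valid = (seqs != GAP) & (seqs != "X")
    n = len(ids)
    d = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValidationError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            if comparable < MIN_COMPARABLE_COLUMNS:
                flagged.append((ids[i], ids[j]))
            p = float((seqs[i, both] != seqs[j, both]).mean())
            if model == "poisson":
                if p >= 1.0:
                    raise ValidationError(
                        f"Poisson correction undefined at p=1 for {ids[i]!r},{ids[j]!r}"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=ids, d=d, flagged_pairs=flagged)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in Q are broken by the lexicographically smallest (cluster
    representative) id pair, where a cluster is represented by its
    smallest member label.  Negative branch-length estimates are clamped
    to zero (original value logged).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    reps: list[str] = list(dm.ids)  # representative label per active cluster

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.info("NJ: negative branch length %.6g at %s clamped to 0",
                        length, context)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        pairs = {tuple(sorted((int(a), int(b)))) for a, b in cand}
        i, j = min(pairs, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        pair_label = f"({reps[i]},{reps[j]})"
        nodes[i].length = clamp(li, pair_label)
        nodes[j].length = clamp(lj, pair_label)
        new = TreeNode()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = clamp(length, "final trifurcation")
        root.add_child(node)
    return PhyloTree(root=root)


def bootstrap(
    aligned: Mapping[str, str] | Sequence[DomainHit],
    replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree with bootstrap support counts on internal nodes.

    Columns are resampled with replacement ``replicates`` times; the
    support of each internal edge of the tree built from the full
    alignment is the number of replicate trees containing the same leaf
    bipartition.
    """
    if not isinstance(aligned, Mapping):
        aligned = aligned_from_hits(aligned)
    if replicates < 1:
        raise ValidationError("bootstrap needs at least 1 replicate")
    tree = neighbor_joining(p_distance(aligned, model=model))
    target = tree.bipartitions()
    counts = {key: 0 for key in target}
    ncol = len(next(iter(aligned.values())))
    rng = np.random.default_rng(seed)
    ids = list(aligned)
    seq_arr = {i: np.array(list(aligned[i])) for i in ids}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {i: "".join(seq_arr[i][cols]) for i in ids}
        try:
            rep_tree = neighbor_joining(p_distance(resampled, model=model))
        except ValidationError:
            continue  # a replicate may lose all comparable columns for a pair
        rep_bips = set(rep_tree.bipartitions())
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    for key, node in target.items():
        node.support = counts[key]
    return tree


@dataclass
class SubfamilyAssignment:
    """Query -> (subfamily, supporting reference, patristic distance)."""

    assignments: dict[str, tuple[str, str, float]]   # placed queries
    unplaced: list[str]

    def subfamilies_used(self) -> set[str]:
        return {sf for sf, _, _ in self.assignments.values()}


def assign_subfamilies(
    tree: PhyloTree,
    labeled_ids: Mapping[str, str],
    distance_ceiling: float = 0.8,
) -> SubfamilyAssignment:
    """Assign each unlabeled leaf the subfamily of its nearest labeled leaf.

    Nearest by patristic distance; ties by majority subfamily among the
    tied references, then alphabetically.  Queries farther than
    ``distance_ceiling`` from every reference are reported "unplaced".
    """
    if not labeled_ids:
        raise ValidationError("no labeled reference leaves supplied")
    names, mat = tree.patristic_distances()
    index = {name: k for k, name in enumerate(names)}
    refs = [r for r in labeled_ids if r in index]
    if not refs:
        raise ValidationError("none of the labeled ids are in the tree")
    queries = [name for name in names if name not in labeled_ids]

    assignments: dict[str, tuple[str, str, float]] = {}
    unplaced: list[str] = []
    ref_idx = np.array([index[r] for r in refs])
    for q in queries:
        dists = mat[index[q], ref_idx]
        dmin = float(dists.min())
        if dmin > distance_ceiling:
            unplaced.append(q)
            continue
        tied = [refs[k] for k in np.flatnonzero(dists <= dmin + 1e-12)]
        label_votes: dict[str, int] = {}
        for r in tied:
            label_votes[labeled_ids[r]] = label_votes.get(labeled_ids[r], 0) + 1
        top = max(label_votes.values())
        subfamily = min(l for l, v in label_votes.items() if v == top)
        ref = min(r for r in tied if labeled_ids[r] == subfamily)
        assignments[q] = (subfamily, ref, dmin)
    return SubfamilyAssignment(assignments=assignments, unplaced=unplaced)
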