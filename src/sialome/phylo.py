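"""Protein distance matrices, neighbor-joining trees and bootstrap support.

The machinery behind family phylograms for small salivary-protein
paralog/ortholog sets: p-distance or Poisson-corrected distances from a
protein alignment, the Saitou-Nei neighbor-joining algorithm with
deterministic tie-breaking, and nonparametric bootstrap over alignment
columns with bipartition-based support values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Clade",
    "DistanceMatrix",
    "protein_distance",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
]

# characters ignored in pairwise-deletion distance computation
_MISSING = frozenset("-X.")


class Clade:
    """A node of an (un)rooted phylogenetic tree.

    Leaves carry ``name``; internal nodes may carry an integer bootstrap
    ``support`` (percent). ``branch_length`` is the length of the edge
    above this node (None at the root). An unrooted NJ tree is represented
    with a trifurcating root.
    """

    __slots__ = ("name", "children", "branch_length", "support")

    def __init__(self, name=None, children=None, branch_length=None, support=None):
        self.name = name
        self.children = list(children) if children else []
        self.branch_length = branch_length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def __eq__(self, other):
        if not isinstance(other, Clade):
            return NotImplemented
        if self.is_leaf != other.is_leaf:
            return False
        if self.is_leaf:
            return (self.name == other.name
                    and _bl_eq(self.branch_length, other.branch_length))
        if self.support != other.support:
            return False
        if len(self.children) != len(other.children):
            return False
        # children compared as unordered sets keyed by leaf content
        key = lambda c: tuple(sorted(c.leaf_names()))
        mine = sorted(self.children, key=key)
        theirs = sorted(other.children, key=key)
        return all(a == b for a, b in zip(mine, theirs)) and _bl_eq(
            self.branch_length, other.branch_length)

    def __repr__(self):  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Clade({self.name!r})"
        return f"Clade(<{len(self.leaves())} leaves>)"


def _bl_eq(a, b, tol=1e-9):
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    return abs(a - b) <= tol


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with unique labels."""

    labels: list[str]
    d: np.ndarray
    comment: str = ""

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")


def protein_distance(records, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances from an aligned protein set.

    Gap and X columns are deleted per pair (pairwise deletion). Under
    ``p_distance`` d = mismatches / compared columns; under ``poisson``
    d = -ln(1 - p).

    Raises ValueError for unequal lengths, a pair with zero comparable
    columns, or p = 1 under the Poisson correction (infinite distance).
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model: {model!r}")
    labels = [r.id for r in records]
    seqs = [r.seq.upper() for r in records]
    n = len(seqs)
    if n == 0:
        raise ValueError("no sequences")
    L = len(seqs[0])
    for r, s in zip(records, seqs):
        if len(s) != L:
            raise ValueError(f"sequence {r.id!r} has length {len(s)} != {L}; "
                             "input must be aligned")
    d = np.zeros((n, n))
    ok = np.array([[c not in _MISSING for c in s] for s in seqs], dtype=bool)
    arr = np.array([list(s) for s in seqs])
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        m = int(both.sum())
        if m == 0:
            raise ValueError(
                f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
        p = float(np.sum(arr[i, both] != arr[j, both])) / m
        if model == "poisson":
            if p >= 1.0:
                raise ValueError(
                    f"p-distance 1.0 between {labels[i]!r} and {labels[j]!r}: "
                    "Poisson distance is infinite")
            dist = -np.log(1.0 - p)
        else:
            dist = p
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def _min_leaf(node: Clade) -> str:
    return min(node.leaf_names())


def nj_tree(dm: DistanceMatrix) -> Clade:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of minimal leaf labels of the candidate nodes, so the
    result is invariant to input row order. Negative branch-length
    estimates are clamped to 0. Exact on additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[Clade] = [Clade(name=lab) for lab in dm.labels]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
                elif abs(q - best_q) <= 1e-12:
                    cand = tuple(sorted((_min_leaf(nodes[i]), _min_leaf(nodes[j]))))
                    cur = tuple(sorted((_min_leaf(nodes[best[0]]),
                                        _min_leaf(nodes[best[1]]))))
                    if cand < cur:
                        best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = nodes[i], nodes[j]
        a.branch_length, b.branch_length = li, lj
        new = Clade(children=[a, b])
        keep = [k for k in range(m) if k not in (i, j)]
        nd = np.zeros((len(keep) + 1, len(keep) + 1))
        for x, k in enumerate(keep):
            for y, l in enumerate(keep):
                nd[x, y] = d[k, l]
        for x, k in enumerate(keep):
            nd[x, -1] = nd[-1, x] = max((d[i, k] + d[j, k] - d[i, j]) / 2.0, 0.0)
        nodes = [nodes[k] for k in keep] + [new]
        d = nd

    # resolve the final three nodes around a trifurcating root
    a, b, c = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    return Clade(children=[a, b, c])


def bipartitions(tree: Clade) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set induced by internal edges.

    Each bipartition is a frozenset of the two frozenset sides, so it is
    insensitive to rooting and leaf order.
    """
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def walk(node):
        for child in node.children:
            side = frozenset(child.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(frozenset((side, all_leaves - side)))
            walk(child)

    walk(tree)
    return out


def bootstrap_support(records, n_replicates: int = 1000, seed: int = 0,
                      model: str = "p_distance") -> Clade:
    """NJ tree from the full alignment with column-bootstrap supports.

    Alignment columns are resampled with replacement ``n_replicates``
    times; the support of an internal edge is the percentage of replicate
    trees containing the same bipartition, attached to the corresponding
    internal node of the full-alignment tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    L = len(records[0].seq)
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(protein_distance(records, model=model))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}

    rng = np.random.default_rng(seed)
    cols = np.array([list(r.seq) for r in records])
    ids = [r.id for r in records]

    from .io import SequenceRecord  # local import to avoid a cycle

    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        boot = [SequenceRecord(id=i, seq="".join(row), alphabet="protein",
                               validate=False)
                for i, row in zip(ids, cols[:, idx])]
        try:
            bt = nj_tree(protein_distance(boot, model=model))
        except ValueError:
            continue  # e.g. zero comparable columns in a replicate
        for bp in bipartitions(bt):
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaf_names())

    def attach(node):
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaf_names())
                bp = frozenset((side, all_leaves - side))
                if bp in counts:
                    child.support = int(round(100.0 * counts[bp] / n_replicates))
            attach(child)

    attach(tree)
    return tree
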