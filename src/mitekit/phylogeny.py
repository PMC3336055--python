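"""Distance-based classification of elements into subfamilies.

Pairwise p-distances from global alignments feed a Saitou–Nei
neighbor-joining tree and a single-linkage subfamily clustering with
per-subfamily IUPAC consensus sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._seq import covering_code

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SubfamilyAssignment",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "assign_subfamilies",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix must be finite")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


@dataclass
class TreeNode:
    """Node of an unrooted phylogeny (stored with an arbitrary root whose
    degree is 3 for n >= 3 leaves). ``raw_length`` keeps any negative
    branch estimate that was clamped to zero."""

    name: str | None = None
    length: float = 0.0
    raw_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}
        # distances from every node down to its leaves, combined at ancestors
        def down(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, 0.0)]
            sub = []
            for child in node.children:
                below = [(n, d + child.length) for n, d in down(child)]
                for n1, d1 in below:
                    for other in sub:
                        for n2, d2 in other:
                            key = (n1, n2) if n1 < n2 else (n2, n1)
                            dists[key] = d1 + d2
                sub.append(below)
            return [x for b in sub for x in b]

        down(self)
        return dists


@dataclass(frozen=True)
class SubfamilyAssignment:
    assignment: dict[str, str | None]
    consensuses: dict[str, str]

    @property
    def n_subfamilies(self) -> int:
        return len(self.consensuses)


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=0,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def pairwise_distance(a: str, b: str) -> float:
    """p-distance from a global alignment of two sequences.

    The alignment minimises mismatch 1, gap open 2, gap extend 0.5
    (distance-mode scoring); the returned value is mismatched columns over
    aligned columns, columns containing a gap excluded.
    """
    if not a or not b:
        raise ValueError("pairwise_distance requires non-empty sequences")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    sa, sb = aln[0], aln[1]
    aligned = mismatch = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        aligned += 1
        if x != y:
            mismatch += 1
    return mismatch / aligned if aligned else 1.0


def distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    labels = tuple(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    At each step the pair minimising
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)
    is joined; branch lengths follow the standard formulas. Ties pick the
    lexicographically smallest label pair. Negative branch estimates are
    clamped to zero, the raw value retained on the node.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in dm.labels}
    labels = list(dm.labels)
    d = {a: {b: float(dm.d[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)}

    if n == 2:
        a, b = sorted(labels)
        half = d[a][b] / 2
        root = TreeNode()
        for lab in (a, b):
            child = nodes[lab]
            child.length = child.raw_length = half
            root.children.append(child)
        return root

    def set_length(node: TreeNode, raw: float) -> None:
        node.raw_length = raw
        node.length = max(raw, 0.0)

    next_id = 0
    while len(labels) > 3:
        m = len(labels)
        row = {a: sum(d[a][b] for b in labels) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (m - 2) * d[a][b] - row[a] - row[b]
                pair = tuple(sorted((a, b)))
                key = (q, pair)
                if best is None or key < best:
                    best = key
        a, b = best[1]
        la = 0.5 * d[a][b] + (row[a] - row[b]) / (2 * (m - 2))
        lb = d[a][b] - la
        new_label = f"__nj{next_id}"
        next_id += 1
        parent = TreeNode()
        set_length(nodes[a], la)
        set_length(nodes[b], lb)
        parent.children = [nodes[a], nodes[b]]
        nodes[new_label] = parent
        d[new_label] = {}
        for c in labels:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_label][c] = dc
            d[c][new_label] = dc
        d[new_label][new_label] = 0.0
        labels = [c for c in labels if c not in (a, b)] + [new_label]

    a, b, c = sorted(labels)
    root = TreeNode()
    set_length(nodes[a], 0.5 * (d[a][b] + d[a][c] - d[b][c]))
    set_length(nodes[b], 0.5 * (d[a][b] + d[b][c] - d[a][c]))
    set_length(nodes[c], 0.5 * (d[a][c] + d[b][c] - d[a][b]))
    root.children = [nodes[a], nodes[b], nodes[c]]
    return root


def _single_linkage(dm: DistanceMatrix, threshold: float) -> list[list[int]]:
    n = len(dm.labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _medoid_msa_consensus(seqs: list[str]) -> str:
    """Consensus via a medoid-anchored alignment.

    All members are globally aligned to the medoid (minimal summed
    p-distance); columns are indexed by medoid positions, insertions
    relative to the medoid are dropped, and each column takes the plain
    base when unanimous, otherwise the minimal covering IUPAC code. A
    member gap at a column is ignored for that column.
    """
    if len(seqs) == 1:
        return seqs[0].upper()
    sums = [sum(pairwise_distance(s, t) for t in seqs) for s in seqs]
    medoid = seqs[int(np.argmin(sums))].upper()
    columns: list[list[str]] = [[] for _ in medoid]
    for s in seqs:
        aln = _ALIGNER.align(medoid, s.upper())[0]
        mi = 0
        for x, y in zip(aln[0], aln[1]):
            if x == "-":
                continue
            if y != "-":
                columns[mi].append(y)
            mi += 1
    out = []
    for i, col in enumerate(columns):
        if not col:
            out.append(medoid[i])
        elif len(set(col)) == 1:
            out.append(col[0])
        else:
            out.append(covering_code(set(col)))
    return "".join(out)


def assign_subfamilies(
    dm: DistanceMatrix,
    seqs: dict[str, str] | None = None,
    max_within: float = 0.15,
    min_size: int = 3,
) -> SubfamilyAssignment:
    """Single-linkage subfamily clustering with IUPAC consensuses.

    Clusters smaller than ``min_size`` are left unassigned, mirroring
    elements that fall outside every named subfamily. Subfamilies are
    named by decreasing size (subfamily1 = largest; ties broken by the
    lexicographically smallest member label).
    """
    groups = _single_linkage(dm, max_within)
    big = [g for g in groups if len(g) >= min_size]
    big.sort(key=lambda g: (-len(g), min(dm.labels[i] for i in g)))
    assignment: dict[str, str | None] = {lab: None for lab in dm.labels}
    consensuses: dict[str, str] = {}
    for k, g in enumerate(big):
        name = f"subfamily{k + 1}"
        members = [dm.labels[i] for i in g]
        for lab in members:
            assignment[lab] = name
        if seqs is not None:
            consensuses[name] = _medoid_msa_consensus([seqs[lab] for lab in members])
        else:
            consensuses[name] = ""
    return SubfamilyAssignment(assignment=assignment, consensuses=consensuses)
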