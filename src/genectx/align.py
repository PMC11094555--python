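"""Gene-neighborhood comparison by local alignment of annotation vectors.

Each neighborhood is projected onto a *label vector*: the ordered list of
per-gene annotation label sets in one namespace.  Two neighborhoods are then
compared with a Smith–Waterman-style local alignment over gene positions,
where two positions match iff their label sets intersect.  The modifications
relative to residue-level Smith–Waterman are (a) the match predicate operates
on label sets rather than characters, and (b) the second vector is optionally
also aligned in reversed orientation so that inverted gene clusters still
score (``AlignParams.try_reverse``).

Pairwise similarity is the cross-alignment score normalized by the smaller
self-alignment score, giving a length-free value in [0, 1]; distance is
``1 - similarity``.  Sets of neighborhoods are ordered by average-linkage
hierarchical clustering on that distance, with a deterministic leaf order
(the subtree containing the lower original index is placed first at every
merge).

Unannotated genes (empty label sets) never match anything, including each
other — this prevents spurious similarity between hypothetical proteins.
Strand is ignored by the match predicate; orientation effects are handled by
``normalize_orientation`` and ``try_reverse``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import EmptyNeighborhoodError, NothingToClusterError
from .model import Neighborhood, NeighborhoodSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelVector:
    """A neighborhood's ordered per-gene label sets in one namespace."""

    entries: tuple[frozenset[str], ...]
    anchor_index: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", tuple(frozenset(e) for e in self.entries)
        )
        if self.entries and not (0 <= self.anchor_index < len(self.entries)):
            raise ValueError("anchor_index out of range")

    def __len__(self) -> int:
        return len(self.entries)

    def reversed(self) -> "LabelVector":
        n = len(self.entries)
        return LabelVector(
            entries=self.entries[::-1],
            anchor_index=(n - 1 - self.anchor_index) if n else 0,
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for the label-vector alignment.

    match_score : score for a pair of positions whose label sets intersect.
    mismatch_score : score for disjoint or unannotated pairs.
    gap_score : score per skipped position.
    try_reverse : also align against the reversed second vector and keep the
        better orientation (handles inverted clusters).
    anchored : require the two anchor positions to be aligned to each other.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -1.0
    try_reverse: bool = True
    anchored: bool = False

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.gap_score > 0:
            raise ValueError("gap_score must be <= 0")
        if self.mismatch_score > self.match_score:
            raise ValueError("mismatch_score must not exceed match_score")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a local alignment: non-negative score, the aligned position
    pairs (strictly increasing in both coordinates, in the orientation that
    won), and whether that orientation was the reversed one."""

    score: float
    aligned_pairs: tuple[tuple[int, int], ...]
    reversed: bool = False


@dataclass
class ClusterOrdering:
    """Leaf order and pairwise distances from hierarchical clustering."""

    order: list[int]
    distance_matrix: np.ndarray
    linkage_method: str = "average"


def label_vector(n: Neighborhood, namespace: str) -> LabelVector:
    """Project a neighborhood onto its label vector in ``namespace``.

    One entry per gene in display order; genes without annotation in the
    namespace contribute an empty set.  Switching namespace changes entries
    but never the length or the anchor index.
    """
    entries = tuple(g.labels_in(namespace) for g in n.genes)
    anchor_index = next(
        i for i, g in enumerate(n.genes) if g.gene_id == n.anchor_id
    )
    return LabelVector(entries, anchor_index, n.neighborhood_id)


def _pair_score(a: frozenset, b: frozenset, p: AlignParams) -> float:
    # empty sets never match, not even each other
    return p.match_score if (a and b and not a.isdisjoint(b)) else p.mismatch_score


def _sw_matrix(u, v, p: AlignParams) -> list[list[float]]:
    """Standard local-alignment DP matrix with a cell floor of zero.

    H[i][j] = best score of an alignment ending at positions (i-1, j-1)."""
    m, n = len(u), len(v)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        row, prev = H[i], H[i - 1]
        ui = u[i - 1]
        for j in range(1, n + 1):
            s = _pair_score(ui, v[j - 1], p)
            best = prev[j - 1] + s
            up = prev[j] + p.gap_score
            if up > best:
                best = up
            left = row[j - 1] + p.gap_score
            if left > best:
                best = left
            row[j] = best if best > 0 else 0.0
    return H


def _traceback(H, u, v, p: AlignParams, i: int, j: int):
    """Walk back from cell (i, j); ties prefer diagonal, then up, then left."""
    pairs = []
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        s = _pair_score(u[i - 1], v[j - 1], p)
        if h == H[i - 1][j - 1] + s:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + p.gap_score:
            i -= 1
        elif h == H[i][j - 1] + p.gap_score:
            j -= 1
        else:  # pragma: no cover - recurrence guarantees one branch
            break
    pairs.reverse()
    return tuple(pairs)


def _best_cell(H) -> tuple[float, int, int]:
    """Max cell; ties resolved to the smallest (i, j) lexicographically."""
    best, bi, bj = 0.0, 0, 0
    for i, row in enumerate(H):
        for j, h in enumerate(row):
            if h > best:
                best, bi, bj = h, i, j
    return best, bi, bj


def _align_oriented(u, v, p: AlignParams) -> tuple[float, tuple]:
    H = _sw_matrix(u, v, p)
    score, bi, bj = _best_cell(H)
    if score <= 0:
        return 0.0, ()
    return score, _traceback(H, u, v, p, bi, bj)


def _align_anchored(uvec: LabelVector, vvec: LabelVector, p: AlignParams):
    """Best local alignment constrained to pair the two anchors.

    Decomposes at the anchor column: best local alignment ending just before
    (au, av), plus the anchor pair itself, plus the best local alignment
    starting just after it (computed on the reversed suffixes)."""
    u, v = uvec.entries, vvec.entries
    au, av = uvec.anchor_index, vvec.anchor_index
    s_anchor = _pair_score(u[au], v[av], p)

    Hpre = _sw_matrix(u[:au], v[:av], p)
    pre_score = max(0.0, Hpre[au][av])
    pre_pairs = _traceback(Hpre, u[:au], v[:av], p, au, av) if pre_score > 0 else ()

    u_suf, v_suf = u[au + 1:][::-1], v[av + 1:][::-1]
    Hsuf = _sw_matrix(u_suf, v_suf, p)
    suf_score = max(0.0, Hsuf[len(u_suf)][len(v_suf)])
    suf_pairs = ()
    if suf_score > 0:
        rev = _traceback(Hsuf, u_suf, v_suf, p, len(u_suf), len(v_suf))
        suf_pairs = tuple(
            sorted((au + 1 + len(u_suf) - 1 - i, av + 1 + len(v_suf) - 1 - j)
                   for i, j in rev)
        )
    score = pre_score + s_anchor + suf_score
    if score <= 0:
        return 0.0, ()
    return score, pre_pairs + ((au, av),) + suf_pairs


def local_align(
    u: LabelVector, v: LabelVector, params: AlignParams = AlignParams()
) -> AlignmentResult:
    """Local alignment of two label vectors.

    Two positions match iff their label sets have a non-empty intersection;
    the cell floor is zero, so the score is never negative.  With
    ``try_reverse`` the alignment is also computed against the reversed
    second vector and the better orientation is reported (forward wins ties);
    the aligned pairs are then given in reversed-``v`` coordinates so they
    stay strictly increasing.
    """
    if len(u) == 0 or len(v) == 0:
        raise EmptyNeighborhoodError("empty neighborhood")
    aligner = _align_anchored if params.anchored else (
        lambda a, b, p: _align_oriented(a.entries, b.entries, p)
    )
    score_f, pairs_f = aligner(u, v, params)
    if params.try_reverse:
        score_r, pairs_r = aligner(u, v.reversed(), params)
        if score_r > score_f:
            return AlignmentResult(score_r, pairs_r, reversed=True)
    return AlignmentResult(score_f, pairs_f, reversed=False)


def similarity(
    u: LabelVector, v: LabelVector, params: AlignParams = AlignParams()
) -> float:
    """Normalized neighborhood similarity in [0, 1].

    The cross-alignment score divided by the smaller of the two forward
    self-alignment scores (``try_reverse`` off for self-scores), clipped to
    [0, 1].  Fully unannotated vectors have self-score 0; their similarity is
    defined as 0 with a logged warning.
    """
    self_params = replace(params, try_reverse=False, anchored=False)
    su = local_align(u, u, self_params).score
    sv = local_align(v, v, self_params).score
    denom = min(su, sv)
    if denom <= 0:
        logger.warning(
            "similarity undefined for unannotated vectors (%s, %s); using 0",
            u.source_id, v.source_id,
        )
        return 0.0
    raw = local_align(u, v, params).score / denom
    return min(1.0, max(0.0, raw))


def _leaf_order_min_index(Z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order with the lower-original-index subtree first at
    every merge — deterministic regardless of scipy internals."""
    children: dict[int, tuple[int, int]] = {
        n + t: (int(a), int(b)) for t, (a, b, _, _) in enumerate(Z)
    }
    min_leaf: dict[int, int] = {}

    def min_of(node: int) -> int:
        if node < n:
            return node
        if node not in min_leaf:
            a, b = children[node]
            min_leaf[node] = min(min_of(a), min_of(b))
        return min_leaf[node]

    order: list[int] = []
    stack = [n + len(Z) - 1] if len(Z) else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if min_of(a) <= min_of(b) else (b, a)
        stack.append(second)  # LIFO: first child is visited first
        stack.append(first)
    return order


def distance_matrix(
    s: NeighborhoodSet, params: AlignParams = AlignParams()
) -> np.ndarray:
    """Symmetric pairwise distance matrix, ``1 - similarity``, zero diagonal."""
    vecs = [label_vector(nb, s.active_namespace) for nb in s.neighborhoods]
    n = len(vecs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - similarity(vecs[i], vecs[j], params)
            D[i, j] = D[j, i] = min(1.0, max(0.0, d))
    return D


def cluster_neighborhoods(
    s: NeighborhoodSet,
    params: AlignParams = AlignParams(),
    linkage_method: str = "average",
) -> ClusterOrdering:
    """Hierarchical agglomerative clustering of a neighborhood set.

    Distances come from :func:`similarity` on the set's active namespace;
    linkage defaults to average.  The returned order is the dendrogram leaf
    order with deterministic tie-breaking, so identical label vectors are
    always adjacent and repeated runs give identical output.
    """
    n = len(s.neighborhoods)
    if n == 0:
        raise NothingToClusterError("nothing to cluster: empty neighborhood set")
    D = distance_matrix(s, params)
    if n == 1:
        return ClusterOrdering([0], D, linkage_method)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    return ClusterOrdering(_leaf_order_min_index(Z, n), D, linkage_method)
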