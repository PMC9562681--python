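"""Vietoris-Rips persistent homology of 2-D point clouds, dimensions 0 and 1.

The filtration scale is the pairwise *distance*: an edge (u, v) enters the
complex at t = d(u, v), a triangle at the length of its longest edge.  This
is the standard Rips convention; growing-disk narratives that parameterize
by radius differ only by a global factor of two, which the downstream
Pearson-correlation analysis is invariant to.

* H0 is computed by Kruskal's algorithm with union-find: the finite deaths
  are exactly the Euclidean minimum-spanning-tree edge lengths.
* H1 is computed by Z/2 column reduction of the anti-transposed boundary
  matrix (persistent cohomology): edge columns holding their cofacet
  triangles are reduced in decreasing filtration order, with clearing --
  edges already paired as H0 deaths (the MST edges) are skipped, which is
  what makes the reduction fast.  The pairing produced equals that of the
  textbook homology reduction.  The inner loop is numba-compiled.
* Simplices are ordered by filtration value with a fixed documented
  tie-break (below), so results are bit-reproducible.
* Classes still alive at ``max_scale`` are reported with death clamped to
  ``max_scale`` and counted in ``n_essential``.
* Zero-persistence bars (death == birth) are discarded everywhere.

Tie-break order.  Edges are ranked by (length, vertex pair); a triangle is
keyed by (rank of its longest edge, remaining vertex), which refines the
filtration order.  Any linear extension of the filtration yields the same
barcode, so this differs from a plain lexicographic tie-break only in which
of several simultaneous simplices is named in a pairing, never in the bars.

``naive_reduction_oracle`` is a deliberately unoptimized dense reduction of
the full boundary matrix with (filtration, dimension, lexicographic) order,
used only by the test suite as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from numba import njit, types
from numba.typed import Dict as NumbaDict

__all__ = [
    "PersistenceDiagram",
    "FiltrationSpec",
    "h0_diagram",
    "h1_diagram",
    "naive_reduction_oracle",
    "warm_up",
]

_KEY_BITS = 21  # triangle key = (max_edge_rank << _KEY_BITS) | third_vertex
_MAX_POINTS = 1 << _KEY_BITS


@dataclass
class PersistenceDiagram:
    """Birth/death pairs of one homology dimension.

    ``bars`` is an (n, 2) float array of (birth, death); bars whose class
    was still alive at the maximum filtration scale have death clamped to
    that scale and are counted in ``n_essential``.
    """

    dimension: int
    bars: np.ndarray
    n_essential: int = 0

    def __post_init__(self) -> None:
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)

    @property
    def births(self) -> np.ndarray:
        return self.bars[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.bars[:, 1]

    @property
    def persistences(self) -> np.ndarray:
        return self.bars[:, 1] - self.bars[:, 0]

    def __len__(self) -> int:
        return len(self.bars)


@dataclass(frozen=True)
class FiltrationSpec:
    """Filtration parameters: Euclidean metric, distance-scale convention,
    and the maximum scale at which simplices may enter."""

    max_scale: float
    metric: str = "euclidean"
    scale_is_distance: bool = True

    def __post_init__(self) -> None:
        if self.max_scale <= 0:
            raise ValueError("max_scale must be positive")
        if self.metric != "euclidean":
            raise ValueError("only the Euclidean metric is supported")


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return pts


def _sorted_edges(dist: np.ndarray, max_scale: float | None = None):
    """All pairs (i, j), i < j, ordered by (distance, i, j); optionally
    restricted to distance <= max_scale.  Returns (ei, ej, ed) arrays."""
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ed = dist[iu, ju]
    if max_scale is not None:
        keep = ed <= max_scale
        iu, ju, ed = iu[keep], ju[keep], ed[keep]
    order = np.lexsort((ju, iu, ed))
    return iu[order].astype(np.int64), ju[order].astype(np.int64), ed[order]


def _kruskal(n: int, ei: np.ndarray, ej: np.ndarray):
    """Union-find over edges already sorted by filtration.

    Returns (mst_mask, n_components): mst_mask[k] is True when edge k merges
    two components (a *negative* edge, an H0 death); False marks a cycle
    edge (*positive*, a potential H1 birth).
    """
    parent = np.arange(n, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    mst = np.zeros(len(ei), dtype=bool)
    n_comp = n
    for k in range(len(ei)):
        ra, rb = find(int(ei[k])), find(int(ej[k]))
        if ra != rb:
            parent[rb] = ra
            mst[k] = True
            n_comp -= 1
    return mst, n_comp


def h0_diagram(points, spec: FiltrationSpec | None = None) -> PersistenceDiagram:
    """Zeroth persistent homology (connected components).

    All births are 0; the finite deaths are the Euclidean MST edge lengths
    (duplicate points would give death-0 bars, which are discarded as
    zero-persistence).  Without a ``spec`` the filtration is uncapped and
    exactly one essential class survives (not listed in ``bars``, its death
    is infinite).  With a ``spec``, edges longer than ``max_scale`` never
    enter: each component still alive at the cap is reported as a clamped
    bar (0, ``max_scale``) and counted in ``n_essential``, mirroring the H1
    convention.
    """
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        return PersistenceDiagram(0, np.empty((0, 2)), n_essential=0)
    cap = None if spec is None else float(spec.max_scale)
    if n == 1:
        if cap is None:
            return PersistenceDiagram(0, np.empty((0, 2)), n_essential=1)
        return PersistenceDiagram(0, [[0.0, cap]], n_essential=1)
    dist = squareform(pdist(pts))
    ei, ej, ed = _sorted_edges(dist, max_scale=cap)
    mst, n_comp = _kruskal(n, ei, ej)
    deaths = ed[mst]
    deaths = deaths[deaths > 0.0]
    bars = np.column_stack([np.zeros_like(deaths), deaths]).tolist()
    if cap is None:
        return PersistenceDiagram(0, bars, n_essential=1)
    bars.extend([[0.0, cap]] * n_comp)
    arr = np.asarray(bars, dtype=float).reshape(-1, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    return PersistenceDiagram(0, arr, n_essential=n_comp)


@njit(cache=True)
def _coreduce_d1(n, ei, ej, ed, edge_rank, dist, max_scale, skip):  # pragma: no cover - numba
    """Cohomology-style reduction yielding the dimension-1 pairing.

    Edge columns (rows: cofacet triangles keyed by (max-edge rank, third
    vertex)) are processed in decreasing filtration order; ``skip`` marks
    MST edges, cleared because they are already paired as H0 deaths.  The
    pivot is the *minimum* triangle key (the maximal row of the
    anti-transposed matrix).  Returns per-edge paired triangle key, -1 when
    the column reduced to zero or was skipped.
    """
    n_edges = len(ed)
    pair_key = np.full(n_edges, -1, np.int64)
    registry = NumbaDict.empty(types.int64, types.int64)
    cap = 8 * n_edges + 16
    data = np.empty(cap, np.int64)
    col_start = np.empty(n_edges + 1, np.int64)
    col_len = np.empty(n_edges + 1, np.int64)
    n_cols = 0
    used = 0
    buf = 4 * n + 16
    work = np.empty(buf, np.int64)
    work2 = np.empty(buf, np.int64)
    for e in range(n_edges - 1, -1, -1):
        if skip[e]:
            continue
        u = ei[e]
        v = ej[e]
        wlen = 0
        for w in range(n):
            if w == u or w == v:
                continue
            if dist[u, w] <= max_scale and dist[v, w] <= max_scale:
                ruw = edge_rank[u, w]
                rvw = edge_rank[v, w]
                if ruw > rvw:
                    rmax = ruw
                    k3 = v
                else:
                    rmax = rvw
                    k3 = u
                if e > rmax:
                    rmax = e
                    k3 = w
                work[wlen] = (rmax << _KEY_BITS) | k3
                wlen += 1
        if wlen > 1:
            work[:wlen] = np.sort(work[:wlen])
        while wlen > 0:
            piv = work[0]
            if piv not in registry:
                break
            c = registry[piv]
            s = col_start[c]
            l2 = col_len[c]
            if wlen + l2 > len(work2):
                newlen = 2 * (wlen + l2)
                nw = np.empty(newlen, np.int64)
                nw[:wlen] = work[:wlen]
                work = nw
                work2 = np.empty(newlen, np.int64)
            a = 0
            b = 0
            w2 = 0
            while a < wlen and b < l2:
                va = work[a]
                vb = data[s + b]
                if va < vb:
                    work2[w2] = va
                    w2 += 1
                    a += 1
                elif vb < va:
                    work2[w2] = vb
                    w2 += 1
                    b += 1
                else:
                    a += 1
                    b += 1
            while a < wlen:
                work2[w2] = work[a]
                w2 += 1
                a += 1
            while b < l2:
                work2[w2] = data[s + b]
                w2 += 1
                b += 1
            tmp = work
            work = work2
            work2 = tmp
            wlen = w2
        if wlen > 0:
            piv = work[0]
            if used + wlen > cap:
                newcap = max(2 * cap, used + wlen)
                newdata = np.empty(newcap, np.int64)
                newdata[:used] = data[:used]
                data = newdata
                cap = newcap
            col_start[n_cols] = used
            col_len[n_cols] = wlen
            for q in range(wlen):
                data[used + q] = work[q]
            used += wlen
            registry[piv] = n_cols
            n_cols += 1
            pair_key[e] = piv
    return pair_key


def h1_diagram(points, spec: FiltrationSpec) -> PersistenceDiagram:
    """First persistent homology (loops) of the Rips filtration capped at
    ``spec.max_scale``.

    Bars are (length of the longest edge closing the loop, length of the
    longest edge of the triangle filling it); classes unfilled at
    ``max_scale`` get death = ``max_scale`` and are counted essential.
    """
    pts = _as_points(points)
    n = len(pts)
    if n >= _MAX_POINTS:
        raise ValueError(f"point clouds above {_MAX_POINTS - 1} points are not supported")
    if n < 3:
        return PersistenceDiagram(1, np.empty((0, 2)), n_essential=0)
    dist = squareform(pdist(pts))
    ei, ej, ed = _sorted_edges(dist, max_scale=spec.max_scale)
    n_edges = len(ed)
    mst_mask, _ = _kruskal(n, ei, ej)
    positive = ~mst_mask  # cycle-creating edges: candidate H1 births

    edge_rank = np.full((n, n), -1, dtype=np.int64)
    edge_rank[ei, ej] = np.arange(n_edges)
    edge_rank[ej, ei] = np.arange(n_edges)

    pair_key = _coreduce_d1(n, ei, ej, ed, edge_rank, dist,
                            float(spec.max_scale), mst_mask)

    bars: list[tuple[float, float]] = []
    paired = pair_key >= 0
    for e in np.nonzero(paired)[0]:
        birth = ed[e]
        death = ed[pair_key[e] >> _KEY_BITS]
        if death > birth:
            bars.append((float(birth), float(death)))
    # positive edges never filled within max_scale: essential classes
    n_essential = 0
    for e in np.nonzero(positive & ~paired)[0]:
        birth = ed[e]
        if spec.max_scale > birth:
            bars.append((float(birth), float(spec.max_scale)))
            n_essential += 1
    bars_arr = np.asarray(bars, dtype=float).reshape(-1, 2)
    if len(bars_arr):
        bars_arr = bars_arr[np.lexsort((bars_arr[:, 1], bars_arr[:, 0]))]
    return PersistenceDiagram(1, bars_arr, n_essential=n_essential)


# ---------------------------------------------------------------------------
# independent test oracle: dense textbook reduction, no optimizations
# ---------------------------------------------------------------------------

_ORACLE_MAX_POINTS = 15


def naive_reduction_oracle(points, spec: FiltrationSpec) -> dict[int, PersistenceDiagram]:
    """Full dense boundary-matrix reduction of the Rips 2-skeleton.

    Textbook left-to-right column reduction with no optimizations, refusing
    clouds above 15 points.  Returns {0: H0 diagram, 1: H1 diagram}; used
    only in tests as an independent cross-check of :func:`h0_diagram` and
    :func:`h1_diagram`.
    """
    pts = _as_points(points)
    n = len(pts)
    if n > _ORACLE_MAX_POINTS:
        raise ValueError(f"oracle refuses clouds with more than {_ORACLE_MAX_POINTS} points")
    if n == 0:
        return {
            0: PersistenceDiagram(0, np.empty((0, 2)), 0),
            1: PersistenceDiagram(1, np.empty((0, 2)), 0),
        }
    dist = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))

    # simplex list: (filtration, dimension, vertices)
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= spec.max_scale:
                simplices.append((float(dist[i, j]), 1, (i, j)))
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                diam = max(dist[i, j], dist[i, k], dist[j, k])
                if diam <= spec.max_scale:
                    simplices.append((float(diam), 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: idx for idx, s in enumerate(simplices)}
    n_simp = len(simplices)

    # dense Z/2 boundary matrix, columns reduced left to right
    cols: list[set[int]] = []
    for _filt, dim, verts in simplices:
        if dim == 0:
            cols.append(set())
        else:
            faces = [verts[:q] + verts[q + 1:] for q in range(len(verts))]
            cols.append({index[f] for f in faces})
    low_of: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j in range(n_simp):
        col = cols[j]
        while col:
            low = max(col)
            if low not in low_of:
                break
            col = col ^ cols[low_of[low]]
        if col:
            low = max(col)
            low_of[low] = j
            pairs.append((low, j))
        cols[j] = col

    paired_simplices = {i for i, _ in pairs} | {j for _, j in pairs}
    bars: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    n_essential = {0: 0, 1: 0}
    for i, j in pairs:
        dim = simplices[i][1]
        birth, death = simplices[i][0], simplices[j][0]
        if dim in bars and death > birth:
            bars[dim].append((birth, death))
    for idx, (filt, dim, _verts) in enumerate(simplices):
        if idx in paired_simplices:
            continue
        # positive simplex never killed: essential class, clamped at the cap
        if dim == 0:
            bars[0].append((0.0, spec.max_scale))
            n_essential[0] += 1
        elif dim == 1 and spec.max_scale > filt:
            bars[1].append((filt, spec.max_scale))
            n_essential[1] += 1
    out = {}
    for dim in (0, 1):
        arr = np.asarray(bars[dim], dtype=float).reshape(-1, 2)
        if len(arr):
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        out[dim] = PersistenceDiagram(dim, arr, n_essential=n_essential[dim])
    return out


def warm_up() -> None:
    """Trigger numba compilation on a tiny input so later calls are fast."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    h0_diagram(pts)
    h1_diagram(pts, FiltrationSpec(max_scale=2.0))
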