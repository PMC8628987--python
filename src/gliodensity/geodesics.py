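"""Geodesic distance (traveling-time) maps to the tumor core.

The distance map d(r) is the first-arrival cost from the tumor core through
a permitted tissue mask (white matter by default, optionally the whole
brain) on the 26-connected voxel graph.  An edge between adjacent voxels
with world offset v costs sqrt(v^T M v), where M is the mean of the two
endpoint metric tensors — the unit metric gives Euclidean edge lengths in
mm, an anisotropic metric gives a traveling time.  Core voxels are sources
with d = 0; voxels not connected to the core within the domain are +inf.

The production solver delegates the shortest-path computation to
scipy.sparse.csgraph.  Two stencils are available: the 26-connected
neighborhood (``graph26``), which is the declared reference semantics, and
an extended 5x5x5 coprime-offset neighborhood (``extended``, the default)
whose chamfer error against true Euclidean distance is about 2% in the
worst direction versus about 8% for the 26-neighborhood.  Long offsets are
only admitted when the voxels straddling their midpoint are inside the
domain, so paths cannot tunnel through thin obstacles.
:func:`dijkstra_oracle` is a deliberately independent pure-Python
re-implementation of the 26-connected reference, kept as the oracle the
solver is tested against.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .grids import ScalarVolume, TissueLabelVolume, VoxelGrid
from .phantom import MetricTensorField, make_metric_field

__all__ = [
    "neighbor_offsets",
    "geodesic_distance",
    "dijkstra_oracle",
    "anisotropic_speedup_check",
    "SpeedupReport",
]


def neighbor_offsets() -> np.ndarray:
    """The 26 neighbor offsets of the voxel graph, as (26, 3) ints."""
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return np.asarray(offs, dtype=int)


def extended_offsets() -> np.ndarray:
    """Coprime offsets of the 5x5x5 neighborhood (98 directions)."""
    from math import gcd

    offs = [
        (i, j, k)
        for i in range(-2, 3)
        for j in range(-2, 3)
        for k in range(-2, 3)
        if (i, j, k) != (0, 0, 0) and gcd(gcd(abs(i), abs(j)), abs(k)) == 1
    ]
    return np.asarray(offs, dtype=int)


def _edge_cost_vec(offset_mm: np.ndarray, M_mean: np.ndarray) -> np.ndarray:
    """sqrt(v^T M v) for a fixed offset v against (N, 3, 3) mean tensors."""
    v = offset_mm
    return np.sqrt(np.einsum("i,nij,j->n", v, M_mean, v))


def _validate(core_mask: np.ndarray, domain_mask: np.ndarray, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    core = np.asarray(core_mask, bool)
    dom = np.asarray(domain_mask, bool) | core
    if core.shape != grid.shape or dom.shape != grid.shape:
        raise ValueError("mask shapes must match the grid")
    if not core.any():
        raise ValueError("core mask is empty")
    return core, dom


def geodesic_distance(
    core_mask: np.ndarray,
    domain_mask: np.ndarray,
    metric: MetricTensorField | None = None,
    grid: VoxelGrid | None = None,
    method: str = "extended",
) -> ScalarVolume:
    """First-arrival distance from the core through the domain mask.

    ``metric=None`` means the unit isotropic metric (distances in mm).  The
    propagation domain is ``domain_mask | core_mask``; everything else is
    +inf in the returned map.  ``method`` selects the stencil: ``extended``
    (default, ~2% worst-direction chamfer error) or ``graph26`` (the
    26-connected reference semantics).
    """
    if grid is None:
        if metric is None:
            raise ValueError("provide a grid or a metric field carrying one")
        grid = metric.grid
    if method not in ("extended", "graph26"):
        raise ValueError(f"unknown method {method!r}")
    core, dom = _validate(core_mask, domain_mask, grid)

    flat_dom = dom.ravel()
    node_of_voxel = np.full(flat_dom.size, -1, dtype=np.int64)
    dom_flat_idx = np.flatnonzero(flat_dom)
    node_of_voxel[dom_flat_idx] = np.arange(dom_flat_idx.size)
    n_nodes = dom_flat_idx.size
    shape = grid.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    spacing = grid.spacing

    if metric is not None:
        tensors = metric.tensor.reshape(-1, 3, 3)

    offsets = neighbor_offsets() if method == "graph26" else extended_offsets()
    rows, cols, costs = [], [], []
    # half the offsets (lexicographically positive); csgraph treats the
    # matrix as undirected so each edge is stored once
    for off in offsets:
        if tuple(off) <= (0, 0, 0):
            continue
        src = dom_flat_idx
        ijk = np.stack(np.unravel_index(src, shape), axis=1)
        tgt_ijk = ijk + off[None, :]
        ok = np.all((tgt_ijk >= 0) & (tgt_ijk < np.asarray(shape)[None, :]), axis=1)
        src = src[ok]
        tgt = src + int(off @ strides)
        ok2 = flat_dom[tgt]
        src, tgt = src[ok2], tgt[ok2]
        if np.max(np.abs(off)) > 1 and src.size:
            # no tunneling: both voxels straddling the midpoint must be in
            # the domain
            half = off / 2.0
            for mid in {tuple(np.floor(half).astype(int)), tuple(np.ceil(half).astype(int))}:
                keep = flat_dom[src + int(np.asarray(mid) @ strides)]
                src, tgt = src[keep], tgt[keep]
        if src.size == 0:
            continue
        v_mm = off * spacing
        if metric is None:
            w = np.full(src.size, float(np.linalg.norm(v_mm)))
        else:
            M_mean = 0.5 * (tensors[src] + tensors[tgt])
            w = _edge_cost_vec(v_mm, M_mean)
        rows.append(node_of_voxel[src])
        cols.append(node_of_voxel[tgt])
        costs.append(w)

    d_nodes = np.full(n_nodes, np.inf)
    src_nodes = node_of_voxel[np.flatnonzero(core.ravel())]
    if rows:
        graph = coo_matrix(
            (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_nodes, n_nodes),
        ).tocsr()
        d_nodes = _csgraph_dijkstra(
            graph, directed=False, indices=src_nodes, min_only=True
        )
    else:
        d_nodes[src_nodes] = 0.0
    d_nodes[src_nodes] = 0.0

    d = np.full(flat_dom.size, np.inf)
    d[dom_flat_idx] = d_nodes
    units = "mm" if metric is None else "traveling time"
    return ScalarVolume(grid, d.reshape(shape), units=units)


def dijkstra_oracle(
    core_mask: np.ndarray,
    domain_mask: np.ndarray,
    metric: MetricTensorField | None = None,
    grid: VoxelGrid | None = None,
) -> ScalarVolume:
    """Exact shortest path on the 26-connected voxel graph, written from
    scratch (binary heap, explicit loops).  Reference semantics for
    :func:`geodesic_distance`; intended for small instances."""
    if grid is None:
        if metric is None:
            raise ValueError("provide a grid or a metric field carrying one")
        grid = metric.grid
    core, dom = _validate(core_mask, domain_mask, grid)
    shape = grid.shape
    spacing = grid.spacing

    dist = {}
    heap = []
    for ijk in map(tuple, np.argwhere(core)):
        dist[ijk] = 0.0
        heapq.heappush(heap, (0.0, ijk))
    offs = [tuple(o) for o in neighbor_offsets()]

    while heap:
        du, u = heapq.heappop(heap)
        if du > dist.get(u, np.inf):
            continue
        for off in offs:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            if not dom[v]:
                continue
            step = np.array(off, dtype=float) * spacing
            if metric is None:
                w = float(np.sqrt(step @ step))
            else:
                M = 0.5 * (metric.tensor[u] + metric.tensor[v])
                w = float(np.sqrt(step @ M @ step))
            alt = du + w
            if alt < dist.get(v, np.inf):
                dist[v] = alt
                heapq.heappush(heap, (alt, v))

    d = np.full(shape, np.inf)
    for ijk, val in dist.items():
        d[ijk] = val
    units = "mm" if metric is None else "traveling time"
    return ScalarVolume(grid, d, units=units)


@dataclass
class SpeedupReport:
    """Mean arrival times in the contralateral hemisphere under the
    anisotropic metric versus the unit metric."""

    mean_time_metric: float
    mean_time_unit: float
    n_voxels: int

    @property
    def speedup(self) -> float:
        return self.mean_time_unit / self.mean_time_metric


def contralateral_mask(labels: TissueLabelVolume) -> np.ndarray:
    """White voxels in the hemisphere opposite the tumor core."""
    core = labels.core_mask
    if not core.any():
        raise ValueError("labels carry no tumor core")
    mid = labels.grid.shape[0] / 2.0
    core_side = np.mean(np.argwhere(core)[:, 0]) < mid
    x = np.arange(labels.grid.shape[0])
    far = (x >= mid) if core_side else (x < mid)
    return labels.white_mask & far[:, None, None]


def anisotropic_speedup_check(
    labels: TissueLabelVolume,
    metric: MetricTensorField,
) -> SpeedupReport:
    """Compare contralateral arrival times under ``metric`` and the unit
    metric.  A fiber metric fast along the bridge must strictly reduce the
    mean arrival time beyond the bridge."""
    unit = make_metric_field(labels, "unit")
    target = contralateral_mask(labels)
    core = labels.core_mask
    white = labels.white_mask
    t_metric = geodesic_distance(core, white, metric).values
    t_unit = geodesic_distance(core, white, unit).values
    ok = target & np.isfinite(t_metric) & np.isfinite(t_unit)
    if not ok.any():
        raise ValueError("no contralateral white voxel is reachable from the core")
    return SpeedupReport(
        mean_time_metric=float(t_metric[ok].mean()),
        mean_time_unit=float(t_unit[ok].mean()),
        n_voxels=int(ok.sum()),
    )
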