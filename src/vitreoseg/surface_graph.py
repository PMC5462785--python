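"""Optimal surface extraction from region probability maps.

The four boundary surfaces are recovered with the minimum-cost closed-set
formulation of multi-surface graph search: one node per (surface, A-scan,
axial position), infinite intra-column arcs enforcing monotonicity, shifted
inter-column arcs encoding hard smoothness constraints, and inter-surface
arcs encoding minimum separations. A single min-cut then yields the global
optimum of the region-cost objective.

Objective
---------
For one surface ``z(c)`` over columns ``c`` with per-voxel "above-cost"
``a(v)`` (the probability that voxel ``v`` lies exterior to the surface),

    F(z) = sum_c [ sum_{k <  z(c)} (1 - a(k, c))  +  sum_{k >= z(c)} a(k, c) ]

i.e. the total probability mass misassigned by the induced exterior/interior
partition; the voxel at ``z(c)`` itself belongs to the interior side. Above
costs derive directly from the 5-class region probability maps: the cost for
a surface is the summed probability of all region classes exterior to it.

Ties are broken towards smaller axial index (the maximal min-cut source set),
so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .types import (
    ABOVE_VITREOUS,
    VMI,
    VMI_ILM,
    ILM_RPE,
    SURFACE_NAMES,
    SurfaceSet,
)

__all__ = [
    "SurfaceConfig",
    "region_cost",
    "surface_objective",
    "extract_surface",
    "extract_surfaces",
    "vitreous_presence_test",
]

# classes exterior to each surface, in region-class indices
_EXTERIOR = {
    "vit_top": (ABOVE_VITREOUS,),
    "vit_bottom": (ABOVE_VITREOUS, VMI),
    "ilm": (ABOVE_VITREOUS, VMI, VMI_ILM),
    "rpe": (ABOVE_VITREOUS, VMI, VMI_ILM, ILM_RPE),
}

_SCALE = float(2**38)   # float->int capacity scale
_BIG = 2**50            # forces / forbids node selection
_ARC_INF = 2**60        # hard-constraint arc capacity


@dataclass(frozen=True)
class SurfaceConfig:
    """Hard constraints of the surface search.

    ``delta_ascan`` / ``delta_bscan``: maximum axial jump (voxels) between
    4-neighbour A-scans within / across B-scans. The inter-B-scan allowance
    is larger because B-scans are much farther apart than neighbouring
    A-scans; the defaults admit the same physical surface slope (~0.1 µm/µm)
    in both lateral directions on the default phantom grid. ``min_ilm_rpe``: minimum ILM-to-RPE separation.
    ``min_cortex`` / ``max_cortex``: bounds on the thickness of the vitreous
    cortex band ``[vit_top, vit_bottom)``; the cortex is a thin membrane, so
    a hard upper bound keeps the exterior surface anchored to the interior
    one where the image evidence above the cortex is weak. ``tau_vmi``: presence
    threshold on the per-column maximum cortex-class probability below which
    the vitreous boundary is declared out of range.
    """

    delta_ascan: int = 3
    delta_bscan: int = 9
    min_ilm_rpe: int = 10
    min_cortex: int = 3
    max_cortex: int = 6
    tau_vmi: float = 0.3


def region_cost(prob_map, surface_id: str) -> np.ndarray:
    """Above-cost volume for one surface: summed exterior-class probability."""
    if surface_id not in _EXTERIOR:
        raise ValueError(f"unknown surface {surface_id!r}; expected one of {SURFACE_NAMES}")
    probs = prob_map.probs if hasattr(prob_map, "probs") else np.asarray(prob_map)
    if probs.ndim != 4 or probs.shape[-1] != 5:
        raise ValueError("probability map must have shape (bscan, ascan, axial, 5)")
    return probs[..., list(_EXTERIOR[surface_id])].sum(axis=-1)


def surface_objective(cost: np.ndarray, z: np.ndarray) -> float:
    """Evaluate the above/below misassignment objective of a surface."""
    cost = np.asarray(cost, dtype=np.float64)
    nb, na, nz = cost.shape
    above = np.cumsum(1.0 - cost, axis=2)         # above[..., k] = sum_{j<=k}(1-a)
    total_below = cost.sum(axis=2)
    zc = np.asarray(z, dtype=np.int64)
    below_from = total_below - np.take_along_axis(
        np.cumsum(cost, axis=2), np.maximum(zc, 1)[..., None] - 1, axis=2
    )[..., 0]
    below_from = np.where(zc == 0, total_below, below_from)
    above_sum = np.where(
        zc == 0, 0.0, np.take_along_axis(above, np.maximum(zc, 1)[..., None] - 1, axis=2)[..., 0]
    )
    return float(np.sum(above_sum + below_from))


# ---------------------------------------------------------------------------
# Dinic max-flow (int64 capacities)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dinic(n_nodes, adj_start, adj_edges, eto, cap, source, sink):  # pragma: no cover
    """Max flow on an edge-paired residual graph; ``cap`` is mutated in place.

    Edges come in pairs ``(e, e ^ 1)``; ``cap[e ^ 1]`` is the reverse
    residual. Returns the flow value.
    """
    INF = np.int64(2**62)
    level = np.empty(n_nodes, dtype=np.int32)
    it = np.empty(n_nodes, dtype=np.int64)
    queue = np.empty(n_nodes, dtype=np.int64)
    path_edges = np.empty(n_nodes + 1, dtype=np.int64)
    flow = np.int64(0)
    while True:
        # BFS level graph
        level[:] = -1
        level[source] = 0
        queue[0] = source
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            for a in range(adj_start[u], adj_start[u + 1]):
                e = adj_edges[a]
                v = eto[e]
                if cap[e] > 0 and level[v] < 0:
                    level[v] = level[u] + 1
                    queue[tail] = v
                    tail += 1
        if level[sink] < 0:
            return flow
        # blocking flow with iterative DFS
        it[:] = adj_start[:-1]
        v = source
        depth = 0
        while True:
            if v == sink:
                bottleneck = INF
                for d in range(depth):
                    e = path_edges[d]
                    if cap[e] < bottleneck:
                        bottleneck = cap[e]
                flow += bottleneck
                retreat_to = 0
                for d in range(depth):
                    e = path_edges[d]
                    cap[e] -= bottleneck
                    cap[e ^ 1] += bottleneck
                # retreat to the first saturated edge on the path
                for d in range(depth):
                    if cap[path_edges[d]] == 0:
                        retreat_to = d
                        break
                depth = retreat_to
                v = source
                for d in range(depth):
                    v = eto[path_edges[d]]
                continue
            advanced = False
            while it[v] < adj_start[v + 1]:
                e = adj_edges[it[v]]
                w = eto[e]
                if cap[e] > 0 and level[w] == level[v] + 1:
                    path_edges[depth] = e
                    depth += 1
                    v = w
                    advanced = True
                    break
                it[v] += 1
            if not advanced:
                level[v] = -1  # dead end
                if depth == 0:
                    break
                depth -= 1
                v = source
                for d in range(depth):
                    v = eto[path_edges[d]]
                it[v] += 1


@njit(cache=True)
def _reaches_sink(n_nodes, adj_start, adj_edges, eto, cap, sink):  # pragma: no cover
    """Mark nodes that can reach the sink in the residual graph."""
    seen = np.zeros(n_nodes, dtype=np.bool_)
    queue = np.empty(n_nodes, dtype=np.int64)
    seen[sink] = True
    queue[0] = sink
    head, tail = 0, 1
    while head < tail:
        v = queue[head]
        head += 1
        for a in range(adj_start[v], adj_start[v + 1]):
            e = adj_edges[a]            # v -> u edge; residual of u -> v is cap[e ^ 1]
            u = eto[e]
            if not seen[u] and cap[e ^ 1] > 0:
                seen[u] = True
                queue[tail] = u
                tail += 1
    return seen


def _min_closure(weights: np.ndarray, req_from: np.ndarray, req_to: np.ndarray) -> np.ndarray:
    """Minimum-weight closed set: selecting ``u`` requires selecting ``v``.

    ``weights`` are int64 node costs (negative = attractive). Among minimum
    solutions the maximal closed set is returned (ties favour selection).
    """
    n = weights.shape[0]
    source, sink = n, n + 1
    neg = np.flatnonzero(weights < 0)
    pos = np.flatnonzero(weights > 0)
    # arcs: source->neg(-w), pos->sink(w), u->v INF for each requirement
    u_all = np.concatenate([np.full(len(neg), source, dtype=np.int64), pos.astype(np.int64), req_from.astype(np.int64)])
    v_all = np.concatenate([neg.astype(np.int64), np.full(len(pos), sink, dtype=np.int64), req_to.astype(np.int64)])
    c_all = np.concatenate([-weights[neg], weights[pos], np.full(len(req_from), _ARC_INF, dtype=np.int64)])
    m = len(u_all)
    eto = np.empty(2 * m, dtype=np.int64)
    efrom = np.empty(2 * m, dtype=np.int64)
    cap = np.empty(2 * m, dtype=np.int64)
    eto[0::2] = v_all
    eto[1::2] = u_all
    efrom[0::2] = u_all
    efrom[1::2] = v_all
    cap[0::2] = c_all
    cap[1::2] = 0
    order = np.argsort(efrom, kind="stable")
    counts = np.bincount(efrom, minlength=n + 2)
    adj_start = np.zeros(n + 3, dtype=np.int64)
    np.cumsum(counts, out=adj_start[1:])
    _dinic(n + 2, adj_start, order, eto, cap, source, sink)
    reach = _reaches_sink(n + 2, adj_start, order, eto, cap, sink)
    return ~reach[:n]  # maximal source side = cannot reach sink


# ---------------------------------------------------------------------------
# Surface solving
# ---------------------------------------------------------------------------


def _build_requirements(
    n_surf: int,
    nb: int,
    na: int,
    nz: int,
    deltas: Sequence[tuple[int, int]],
    separations: Sequence[tuple[int, int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Implication arcs for monotonicity, smoothness and separation.

    Node id layout: ``((s * nb + b) * na + a) * nz + k``; selecting node
    ``(s, c, k)`` means surface ``s`` passes at or above ``k`` in column
    ``c`` (``z_s(c) <= k``).
    """
    def nid(s, b, a, k):
        return ((s * nb + b) * na + a) * nz + k

    froms, tos = [], []
    bb, aa, kk = np.meshgrid(np.arange(nb), np.arange(na), np.arange(nz), indexing="ij")

    for s in range(n_surf):
        # monotone: x(c, k) => x(c, k + 1)
        sel = kk < nz - 1
        froms.append(nid(s, bb[sel], aa[sel], kk[sel]))
        tos.append(nid(s, bb[sel], aa[sel], kk[sel] + 1))
        d_a, d_b = deltas[s]
        # smoothness: x(c', k) => x(c, min(k + delta, nz - 1)); arcs to the
        # forced top node are tautologies and skipped
        for (db, da, delta) in ((0, 1, d_a), (0, -1, d_a), (1, 0, d_b), (-1, 0, d_b)):
            if not np.isfinite(delta):
                continue
            delta = int(delta)
            sel = (
                (bb + db >= 0) & (bb + db < nb)
                & (aa + da >= 0) & (aa + da < na)
                & (kk + delta < nz - 1)
            )
            froms.append(nid(s, bb[sel], aa[sel], kk[sel]))
            tos.append(nid(s, bb[sel] + db, aa[sel] + da, kk[sel] + delta))
    for (s_up, s_low, sep) in separations:
        # z_up <= z_low - sep:  x_low(c, k) => x_up(c, k - sep); k - sep < 0
        # is handled by forbidding those x_low nodes in the weights. A
        # negative sep encodes a maximum separation the other way round;
        # arcs into the forced top node are tautologies and skipped.
        sel = (kk - sep >= 0) & (kk - sep <= nz - 1)
        froms.append(nid(s_low, bb[sel], aa[sel], kk[sel]))
        tos.append(nid(s_up, bb[sel], aa[sel], kk[sel] - sep))
    return (
        np.concatenate(froms).astype(np.int64),
        np.concatenate(tos).astype(np.int64),
    )


def _solve_surfaces(
    costs: Sequence[np.ndarray],
    deltas: Sequence[tuple[int, int]],
    separations: Sequence[tuple[int, int, int]] = (),
    upper_bounds: Optional[Sequence[Optional[np.ndarray]]] = None,
) -> list[np.ndarray]:
    """Jointly optimal surfaces for the given above-cost volumes.

    ``deltas[s] = (delta_ascan, delta_bscan)``; ``separations`` entries are
    ``(upper_surface, lower_surface, min_sep)``; ``upper_bounds[s]`` is an
    optional per-column cap ``z_s(c) <= bound``.
    """
    n_surf = len(costs)
    nb, na, nz = costs[0].shape
    if nz < 1 or nb < 1 or na < 1:
        raise ValueError("empty cost volume")
    for c in costs:
        if c.shape != (nb, na, nz):
            raise ValueError("cost volumes must share one shape")
        if not np.all(np.isfinite(c)):
            raise ValueError("cost volume contains non-finite values")

    # fully unconstrained single surface: per-column search, ties to smaller z
    if n_surf == 1 and not separations and all(not np.isfinite(d) for d in deltas[0]) and (
        upper_bounds is None or upper_bounds[0] is None
    ):
        cost = np.asarray(costs[0], dtype=np.float64)
        f = np.zeros((nb, na, nz))
        f[..., 1:] = np.cumsum(1.0 - cost, axis=2)[..., :-1]
        f += cost.sum(axis=2, keepdims=True) - np.concatenate(
            [np.zeros((nb, na, 1)), np.cumsum(cost, axis=2)[..., :-1]], axis=2
        )
        return [np.argmin(f, axis=2).astype(np.int64)]

    weights = np.empty((n_surf, nb, na, nz), dtype=np.int64)
    for s, cost in enumerate(costs):
        d = np.rint((2.0 * np.asarray(cost, dtype=np.float64) - 1.0) * _SCALE).astype(np.int64)
        d[..., nz - 1] = -_BIG  # top node forced: z <= nz - 1 always holds
        weights[s] = d
    for (s_up, s_low, sep) in separations:
        if sep > 0:
            weights[s_low, :, :, : min(sep, nz)] = _BIG  # z_low >= sep
    if upper_bounds is not None:
        for s, bound in enumerate(upper_bounds):
            if bound is None:
                continue
            b_idx = np.clip(np.asarray(bound, dtype=np.int64), 0, nz - 1)
            flat = weights[s].reshape(nb * na, nz)
            flat[np.arange(nb * na), b_idx.ravel()] = np.minimum(
                flat[np.arange(nb * na), b_idx.ravel()], -_BIG
            )

    req_from, req_to = _build_requirements(n_surf, nb, na, nz, deltas, separations)
    selected = _min_closure(weights.ravel(), req_from, req_to)
    selected = selected.reshape(n_surf, nb, na, nz)
    return [np.argmax(sel, axis=2).astype(np.int64) for sel in selected]


def extract_surface(
    cost: np.ndarray, smoothness: tuple[float, float] = (3, 9)
) -> np.ndarray:
    """Globally optimal single surface under hard smoothness constraints.

    ``smoothness = (delta_ascan, delta_bscan)`` in voxels (``np.inf``
    decouples the columns). Returns axial positions of shape
    ``(n_bscans, n_ascans)``.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 3 or cost.size == 0:
        raise ValueError("cost must be a non-empty (bscan, ascan, axial) volume")
    d_a, d_b = smoothness
    if d_a < 0 or d_b < 0:
        raise ValueError("smoothness constraints must be non-negative")
    return _solve_surfaces([cost], deltas=[(d_a, d_b)])[0]


def vitreous_presence_test(prob_map, tau_vmi: float = 0.3) -> np.ndarray:
    """Columns whose peak cortex-class probability reaches ``tau_vmi``.

    Returns a boolean ``(n_bscans, n_ascans)`` mask; ``False`` marks columns
    where the posterior vitreous boundary is considered out of the axial
    range (complete PVD locally or globally).
    """
    probs = prob_map.probs if hasattr(prob_map, "probs") else np.asarray(prob_map)
    return probs[..., VMI].max(axis=2) >= tau_vmi


def extract_surfaces(prob_map, config: SurfaceConfig = SurfaceConfig()) -> SurfaceSet:
    """Extract the four ordered boundary surfaces from a probability map.

    The retinal pair (ILM, RPE) is solved jointly with its minimum
    separation; the vitreous pair (vit_top, vit_bottom) is then solved
    jointly, constrained to lie at or above the extracted ILM. Columns
    failing the vitreous presence test get neutral vitreous costs (so they
    do not drag neighbouring in-range columns through the smoothness
    constraints) and are reported as NaN.
    """
    probs = prob_map.probs if hasattr(prob_map, "probs") else np.asarray(prob_map)
    deltas = (config.delta_ascan, config.delta_bscan)

    ilm_z, rpe_z = _solve_surfaces(
        [region_cost(probs, "ilm"), region_cost(probs, "rpe")],
        deltas=[deltas, deltas],
        separations=[(0, 1, config.min_ilm_rpe)],
    )
    present = vitreous_presence_test(probs, config.tau_vmi)
    vt_cost = region_cost(probs, "vit_top")
    vb_cost = region_cost(probs, "vit_bottom")
    vt_cost[~present] = 0.5
    vb_cost[~present] = 0.5
    vt_z, vb_z = _solve_surfaces(
        [vt_cost, vb_cost],
        deltas=[deltas, deltas],
        separations=[(0, 1, config.min_cortex)],
        upper_bounds=[None, ilm_z],
    )
    # The 20-voxel training-exclusion band above the annotated boundary leaves
    # the classifier least reliable right above the cortex, letting vit_top
    # drift into the vitreous; project it into the physical cortex-thickness
    # band around the well-anchored interior surface.
    vt_z = np.clip(vt_z, vb_z - config.max_cortex, vb_z - config.min_cortex)
    vit_top = np.where(present, vt_z.astype(np.float64), np.nan)
    vit_bottom = np.where(present, vb_z.astype(np.float64), np.nan)
    return SurfaceSet(vit_top, vit_bottom, ilm_z.astype(np.float64), rpe_z.astype(np.float64))
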