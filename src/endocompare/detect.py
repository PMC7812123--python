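"""Sulcus detection as curvature-extremal (ravine) lines on a triangle mesh.

Sulcal imprints are concave furrows, so on both the brain hull and the
endocast they are detected as *ravine* lines: curves where the minimal
principal curvature kmin attains a negative extremum along its own principal
direction.  At each vertex a cubic height field is fitted over the geodesic
neighbourhood in the local tangent frame; its quadratic part gives the
principal curvatures and directions, its cubic part the extremality
coefficients (the derivative of each principal curvature along its own
direction).  Ravine points are the zero crossings of the minimal-curvature
extremality on mesh edges where kmin is below a (negative) threshold; they
are linked across triangles into ordered polylines.

Sign convention: curvature is positive where the surface is convex with
respect to the outward normal, so ravines have kmin strongly negative.  A
symmetric ridge mode (zero crossings of the maximal-curvature extremality
where kmax is above +threshold) is available via ``mode="ridge"``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import trimesh

from .curves import CurveSet, LabeledCurve


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures, directions and extremalities."""

    kmax: np.ndarray  # 1/mm
    kmin: np.ndarray
    dmax: np.ndarray  # (n, 3) unit tangent vectors
    dmin: np.ndarray
    emax: np.ndarray  # 1/mm^2, derivative of kmax along dmax
    emin: np.ndarray

    def __post_init__(self):
        if np.any(self.kmax < self.kmin - 1e-9):
            raise ValueError("kmax must dominate kmin at every vertex")


def _geodesic_neighborhoods(
    vertices: np.ndarray, faces: np.ndarray, radius: float
) -> list[list[int]]:
    """Per-vertex lists of vertices within graph-geodesic distance ``radius``."""
    n = len(vertices)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    lens = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    for (a, b), l in zip(edges, lens):
        adj[a].append((b, l))
        adj[b].append((a, l))
    out = []
    for s in range(n):
        dist = {s: 0.0}
        hp = [(0.0, s)]
        while hp:
            d, u = heapq.heappop(hp)
            if d > dist.get(u, np.inf):
                continue
            for v, l in adj[u]:
                nd = d + l
                if nd <= radius and nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(hp, (nd, v))
        del dist[s]
        out.append(list(dist))
    return out


def estimate_curvature(mesh: trimesh.Trimesh, neighborhood_radius: float) -> CurvatureField:
    """Principal curvatures/directions and extremality by local cubic fits.

    ``neighborhood_radius`` should be at least ~2 mean edge lengths so the
    cubic fit is well conditioned.  Vertices whose neighbourhood has fewer
    than 9 points fall back to a quadratic fit (extremality 0); fewer than 6
    points is an error.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    mean_edge = float(np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1).mean())
    if neighborhood_radius < 2.0 * mean_edge:
        raise ValueError(
            f"neighborhood_radius {neighborhood_radius:.2f} below 2x mean edge "
            f"length ({2 * mean_edge:.2f})"
        )
    hoods = _geodesic_neighborhoods(v, f, neighborhood_radius)

    # fall back to the topological 2-ring where the metric ball is too sparse
    one_ring: list[set[int]] = [set() for _ in range(len(v))]
    for a, b, c in f:
        one_ring[a].update((b, c))
        one_ring[b].update((a, c))
        one_ring[c].update((a, b))
    for i, hood in enumerate(hoods):
        if len(hood) < 9:
            two_ring = set(one_ring[i])
            for j in one_ring[i]:
                two_ring |= one_ring[j]
            two_ring.discard(i)
            hoods[i] = sorted(set(hood) | two_ring)

    n_v = len(v)
    kmax = np.zeros(n_v)
    kmin = np.zeros(n_v)
    dmax = np.zeros((n_v, 3))
    dmin = np.zeros((n_v, 3))
    emax = np.zeros(n_v)
    emin = np.zeros(n_v)

    for i in range(n_v):
        idx = hoods[i]
        if len(idx) < 6:
            raise ValueError(f"vertex {i}: neighborhood has {len(idx)} points (< 6)")
        n = normals[i]
        # tangent frame
        t1 = np.cross(n, [1.0, 0.0, 0.0])
        if (t1 @ t1) < 1e-12:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)

        rel = v[idx] - v[i]
        u = rel @ t1
        w = rel @ t2
        h = rel @ n

        cubic = len(idx) >= 9
        cols = [u, w, u * u, u * w, w * w]
        if cubic:
            cols += [u**3, u * u * w, u * w * w, w**3]
        A = np.stack(cols, axis=1)
        # Gaussian distance weights localise the fit, suppressing the bias
        # that 4th-order surface terms would otherwise leak into the quadric
        r2 = np.einsum("ij,ij->i", rel, rel)
        wgt = np.exp(-r2 / (0.5 * neighborhood_radius) ** 2)
        beta, *_ = np.linalg.lstsq(A * wgt[:, None], h * wgt, rcond=None)
        b1, b2, b3, b4, b5 = beta[:5]

        # shape operator with first-fundamental-form correction
        W2 = 1.0 + b1 * b1 + b2 * b2
        Wn = np.sqrt(W2)
        I = np.array([[1 + b1 * b1, b1 * b2], [b1 * b2, 1 + b2 * b2]])
        II = np.array([[2 * b3, b4], [b4, 2 * b5]]) / Wn
        S = np.linalg.solve(I, II)
        S = 0.5 * (S + S.T)
        vals, vecs = np.linalg.eigh(-S)  # negate: convex w.r.t. outward normal -> +
        k_small, k_large = vals  # ascending
        d_small2, d_large2 = vecs[:, 0], vecs[:, 1]

        def to3d(d2):
            d3 = d2[0] * (t1 + b1 * n) + d2[1] * (t2 + b2 * n)
            d3 -= (d3 @ n) * n  # exactly tangent to the vertex normal
            return d3 / np.linalg.norm(d3)

        kmax[i], kmin[i] = k_large, k_small
        dmax[i] = to3d(d_large2)
        dmin[i] = to3d(d_small2)

        if cubic:
            b6, b7, b8, b9 = beta[5:]

            def extremality(d2):
                a, b = d2
                return -(6 * b6 * a**3 + 6 * b7 * a * a * b + 6 * b8 * a * b * b + 6 * b9 * b**3)

            emax[i] = extremality(d_large2)
            emin[i] = extremality(d_small2)

    return CurvatureField(kmax=kmax, kmin=kmin, dmax=dmax, dmin=dmin, emax=emax, emin=emin)


def smooth_curvature_field(
    mesh: trimesh.Trimesh, field: CurvatureField, iterations: int = 2
) -> CurvatureField:
    """Regularize a curvature field for tracing on voxel-derived meshes.

    Principal curvatures are relaxed by ``iterations`` steps of 0.5-weighted
    neighbour averaging, and the extremalities are recomputed as the tangent-
    plane gradient of the smoothed curvature projected on the (unchanged)
    principal directions.  On meshes extracted from voxel data this is far
    more stable than the raw cubic-term extremality, whose sign flips with
    voxel-scale surface ripple; on clean analytic meshes the two agree.
    """
    from scipy import sparse

    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    adj = sparse.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(v),) * 2)
    adj = ((adj + adj.T) > 0).astype(float).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()

    kmin = field.kmin.copy()
    kmax = field.kmax.copy()
    for _ in range(iterations):
        kmin = 0.5 * kmin + 0.5 * (adj @ kmin) / deg
        kmax = 0.5 * kmax + 0.5 * (adj @ kmax) / deg
    kmax = np.maximum(kmax, kmin)

    normals = np.asarray(mesh.vertex_normals, dtype=float)
    emin = np.zeros(len(v))
    emax = np.zeros(len(v))
    indptr, indices = adj.indptr, adj.indices
    for i in range(len(v)):
        nb = indices[indptr[i]:indptr[i + 1]]
        rel = v[nb] - v[i]
        rel = rel - np.outer(rel @ normals[i], normals[i])
        g_min, *_ = np.linalg.lstsq(rel, kmin[nb] - kmin[i], rcond=None)
        g_max, *_ = np.linalg.lstsq(rel, kmax[nb] - kmax[i], rcond=None)
        emin[i] = g_min @ field.dmin[i]
        emax[i] = g_max @ field.dmax[i]
    return CurvatureField(kmax=kmax, kmin=kmin, dmax=field.dmax.copy(),
                          dmin=field.dmin.copy(), emax=emax, emin=emin)


def _edge_crossings(
    v: np.ndarray, eligible: np.ndarray, e_val: np.ndarray, d_vec: np.ndarray,
    k_val: np.ndarray, edges: np.ndarray,
) -> dict[tuple[int, int], tuple[np.ndarray, float]]:
    """Zero crossings of the extremality on eligible edges.

    The principal direction field has a per-vertex sign ambiguity; for each
    edge the second endpoint's direction (and hence extremality, which is
    odd under the flip) is aligned to the first before the sign test.
    """
    out = {}
    for a, b in edges:
        if not (eligible[a] and eligible[b]):
            continue
        ea = e_val[a]
        eb = e_val[b] if (d_vec[a] @ d_vec[b]) >= 0 else -e_val[b]
        if ea == 0.0 and eb == 0.0:
            continue
        if ea * eb < 0:
            t = ea / (ea - eb)
            pt = v[a] + t * (v[b] - v[a])
            kk = abs(k_val[a] + t * (k_val[b] - k_val[a]))
            out[(a, b)] = (pt, kk)
    return out


def _merge_chains(polys: list[tuple[np.ndarray, float]], gap: float) -> list[tuple[np.ndarray, float]]:
    """Join polylines whose endpoints nearly continue one another.

    Two chains are merged when an endpoint pair is closer than ``gap`` and
    the joint roughly continues both tangents (no hairpins).  Strengths are
    merged length-weighted.  Repeats until stable.
    """

    def out_tangent(pts, at_end):
        t = pts[-1] - pts[-2] if at_end else pts[0] - pts[1]
        return t / max(np.linalg.norm(t), 1e-12)

    from scipy.spatial import cKDTree

    changed = True
    while changed and len(polys) > 1:
        changed = False
        ends = np.array([p[0] for p, _ in polys] + [p[-1] for p, _ in polys])
        n = len(polys)
        tree = cKDTree(ends)
        best = None  # (dist, i, j, i_end, j_end)
        for ia, ib in tree.query_pairs(gap):
            i, i_end = ia % n, ia >= n
            j, j_end = ib % n, ib >= n
            if i == j:
                continue
            if i > j:
                i, j, i_end, j_end = j, i, j_end, i_end
            pi, pj = polys[i][0], polys[j][0]
            a = pi[-1] if i_end else pi[0]
            b = pj[-1] if j_end else pj[0]
            d = float(np.linalg.norm(b - a))
            if d >= gap or d < 1e-12:
                continue
            link = (b - a) / d
            if (out_tangent(pi, i_end) @ link) < 0.3 or (out_tangent(pj, j_end) @ -link) < 0.3:
                continue
            if best is None or d < best[0]:
                best = (d, i, j, i_end, j_end)
        if best is not None:
            _, i, j, i_end, j_end = best
            pi, si = polys[i]
            pj, sj = polys[j]
            a_part = pi if i_end else pi[::-1]
            b_part = pj if not j_end else pj[::-1]
            merged = np.vstack([a_part, b_part])
            li = polyline_len(pi)
            lj = polyline_len(pj)
            strength = (si * li + sj * lj) / max(li + lj, 1e-12)
            polys = [p for k, p in enumerate(polys) if k not in (i, j)]
            polys.append((merged, strength))
            changed = True
    return polys


def polyline_len(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def trace_ravines(
    mesh: trimesh.Trimesh,
    field: CurvatureField,
    k_threshold: float,
    min_length: float,
    mode: str = "ravine",
    merge_gap: float | None = None,
) -> CurveSet:
    """Link extremality zero crossings into ordered ravine (or ridge) lines.

    Ravine mode keeps edges where kmin < -k_threshold and crosses the zero
    of the minimal-curvature extremality; ridge mode mirrors it with kmax >
    +k_threshold.  Crossings on two edges of a triangle are joined; at
    branch triangles (3 crossings) the two strongest-|curvature| crossings
    are joined and the third is left to other triangles, so the output
    decomposes into simple polylines.  Chains whose endpoints nearly
    continue one another (gap below ``merge_gap``, default 3 mean edge
    lengths) are merged, then polylines shorter than ``min_length`` are
    discarded.  An empty result is a valid outcome.
    """
    if mode not in ("ravine", "ridge"):
        raise ValueError("mode must be 'ravine' or 'ridge'")
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if mode == "ravine":
        eligible = field.kmin < -k_threshold
        e_val, d_vec, k_val = field.emin, field.dmin, field.kmin
    else:
        eligible = field.kmax > k_threshold
        e_val, d_vec, k_val = field.emax, field.dmax, field.kmax

    edges = np.unique(
        np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0
    )
    crossings = _edge_crossings(v, eligible, e_val, d_vec, k_val, edges)
    if not crossings:
        return CurveSet(curves=[], source="")

    # per-face linkage between edge crossings
    links: dict[tuple[int, int], list[tuple[int, int]]] = {k: [] for k in crossings}
    for tri in f:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            k = (a, b) if a < b else (b, a)
            if k in crossings:
                keys.append(k)
        if len(keys) == 2:
            pair = keys
        elif len(keys) == 3:
            keys = sorted(keys, key=lambda k: -crossings[k][1])  # strongest first
            pair = keys[:2]
        else:
            continue
        a_k, b_k = pair
        if len(links[a_k]) < 2 and len(links[b_k]) < 2 and a_k not in links[b_k]:
            links[a_k].append(b_k)
            links[b_k].append(a_k)

    # walk chains (endpoints first, then leftover cycles)
    visited: set[tuple[int, int]] = set()
    chains: list[list[tuple[int, int]]] = []

    def walk(start):
        chain = [start]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxt = [k for k in links[cur] if k != prev and k not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited.add(cur)
            chain.append(cur)
        return chain

    endpoints = sorted(k for k, ls in links.items() if len(ls) <= 1)
    for k in endpoints:
        if k not in visited:
            chains.append(walk(k))
    for k in sorted(links):
        if k not in visited:
            chains.append(walk(k))  # cycles

    polys: list[tuple[np.ndarray, float]] = []
    for chain in chains:
        if len(chain) < 2:
            continue
        pts = np.array([crossings[k][0] for k in chain])
        keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
        pts = pts[keep]
        if len(pts) < 2:
            continue
        polys.append((pts, float(np.mean([crossings[k][1] for k in chain]))))

    if merge_gap is None:
        mean_edge = float(np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1).mean())
        merge_gap = 3.0 * mean_edge
    if merge_gap > 0:
        polys = _merge_chains(polys, merge_gap)

    curves = [
        LabeledCurve(points=pts, strength=strength)
        for pts, strength in polys
        if polyline_len(pts) >= min_length
    ]
    return CurveSet(curves=curves, source="")


def default_k_threshold(field: CurvatureField, mode: str = "ravine", percentile: float = 75.0) -> float:
    """Scale-adaptive threshold: a percentile of |kmin| (or |kmax|) over the mesh."""
    vals = np.abs(field.kmin if mode == "ravine" else field.kmax)
    return float(np.percentile(vals, percentile))


def detect_sulci(
    mesh: trimesh.Trimesh,
    neighborhood_radius: float | None = None,
    k_percentile: float = 75.0,
    min_length: float = 12.0,
    smooth_iterations: int = 2,
    mode: str = "ravine",
    source: str = "",
    min_strength: float = 0.0,
) -> CurveSet:
    """Standard detection path: curvature -> smoothing -> ravine tracing.

    ``neighborhood_radius`` defaults to max(2.5 mm, 2.1 mean edge lengths);
    the curvature threshold is the ``k_percentile`` percentile of |kmin|
    over the mesh (scale-adaptive).  ``min_strength`` (1/mm) optionally
    discards weak lines (tessellation-scale ripple); by default everything
    is returned and weak lines are left for downstream labeling to reject.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    mean_edge = float(np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1).mean())
    if neighborhood_radius is None:
        neighborhood_radius = max(2.5, 2.1 * mean_edge)
    field = estimate_curvature(mesh, neighborhood_radius)
    if smooth_iterations > 0:
        field = smooth_curvature_field(mesh, field, iterations=smooth_iterations)
    thr = default_k_threshold(field, mode=mode, percentile=k_percentile)
    out = trace_ravines(mesh, field, k_threshold=thr, min_length=min_length, mode=mode)
    if min_strength > 0:
        out = filter_curves(out, min_strength=min_strength)
    out.source = source
    return out


def filter_curves(curves: CurveSet, min_length: float = 0.0, min_strength: float = 0.0) -> CurveSet:
    """Keep curves meeting both thresholds; order preserved, geometry untouched."""
    kept = [c for c in curves if c.length >= min_length and c.strength >= min_strength]
    return CurveSet(curves=kept, source=curves.source)
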