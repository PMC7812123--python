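"""Shrink-wrap surface extraction and mesh resampling.

The brain hull and the endocast are both extracted by deforming a seed
sphere toward an isosurface of the volume: a sphere *enclosing* the brain is
shrunk onto it (the hull bridges narrow folds while keeping groove-scale
depressions), and a sphere placed *inside* the braincase is inflated onto
the inner table (the endocast).  Each iteration displaces every vertex along
its normal, by the (clamped) signed distance to the target isosurface, with
the sign chosen so the vertex descends |distance|; the displacement is
blended with uniform Laplacian smoothing.  The seed sphere is a subdivided
icosahedron, so the output is watertight and genus 0 by construction.

``resample_mesh`` brings any watertight mesh to an exact face budget:
uniform subdivision while below the target, then shortest-edge midpoint
collapses (with link-condition and normal-flip guards, so watertightness
and orientation survive) down to exactly the requested count.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .volume import VolumeImage


@dataclass
class ShrinkWrapSettings:
    direction: str = "inward"  # "inward" | "outward"
    step_size: float = 1.0  # mm, max displacement per iteration
    smoothing_weight: float = 0.3
    max_iterations: int = 400
    convergence_tol: float = 0.01  # mm
    target_isovalue: float = 0.5

    def __post_init__(self):
        if self.direction not in ("inward", "outward"):
            raise ValueError("direction must be 'inward' or 'outward'")
        if self.step_size <= 0 or self.convergence_tol <= 0:
            raise ValueError("step_size and convergence_tol must be positive")
        if not (0 <= self.smoothing_weight < 1):
            raise ValueError("smoothing_weight must be in [0, 1)")


@dataclass
class ConvergenceLog:
    iterations: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = False


def _signed_distance_grid(volume: VolumeImage, isovalue: float) -> np.ndarray:
    """Signed distance (mm) to the isovalue surface: positive outside."""
    fg = np.asarray(volume.values, dtype=float) >= isovalue
    if not fg.any():
        raise ValueError("no voxels at or above the target isovalue")
    d_out = ndimage.distance_transform_edt(~fg, sampling=volume.spacing)
    d_in = ndimage.distance_transform_edt(fg, sampling=volume.spacing)
    d = (d_out - d_in).astype(float)
    # the EDT measures to voxel *centres*, overstating the distance to the
    # binary boundary by half a voxel on each side; soft-shrink so the zero
    # level sits on the boundary with unit slope across it
    h = 0.5 * float(volume.spacing.min())
    d = np.sign(d) * np.maximum(np.abs(d) - h, 0.0)
    # a sub-voxel Gaussian blur removes the voxel staircase from the zero
    # level set (it would otherwise imprint spurious curvature ripple on the
    # wrapped surface); the level-set bias this adds is ~sigma^2 * curvature / 2,
    # far below a voxel for any structure the grid can resolve
    return ndimage.gaussian_filter(d, sigma=0.6)


def _sample(grid: np.ndarray, volume: VolumeImage, points: np.ndarray) -> np.ndarray:
    idx = volume.world_to_index(points)
    return ndimage.map_coordinates(grid, idx.T, order=1, mode="nearest")


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    vn = np.zeros_like(vertices)
    np.add.at(vn, faces[:, 0], fn)
    np.add.at(vn, faces[:, 1], fn)
    np.add.at(vn, faces[:, 2], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(norm, 1e-12)


def _neighbor_matrix(n_vertices: int, faces: np.ndarray):
    from scipy import sparse

    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    data = np.ones(len(e))
    adj = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices))
    adj = ((adj + adj.T) > 0).astype(float).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return adj, deg


def pad_volume(volume: VolumeImage, pad_mm: float, value: float = 0.0) -> VolumeImage:
    """Extend the grid by ``pad_mm`` on every side, filling with ``value``."""
    n = np.ceil(pad_mm / volume.spacing).astype(int)
    vals = np.pad(volume.values, [(k, k) for k in n], constant_values=value)
    origin = volume.origin - volume.orientation @ (n * volume.spacing)
    return VolumeImage(values=vals, spacing=volume.spacing.copy(), origin=origin,
                       orientation=volume.orientation.copy())


def icosphere_for_volume(
    center: np.ndarray, radius: float, edge_length_mm: float
) -> trimesh.Trimesh:
    """Subdivided icosahedron whose edge length is close to the request."""
    subdivisions = 0
    edge = 1.05 * radius  # icosahedron edge for circumscribed radius r
    while edge > edge_length_mm and subdivisions < 8:
        subdivisions += 1
        edge /= 2.0
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(center)
    return mesh


def shrink_wrap(
    volume: VolumeImage,
    seed_center: np.ndarray,
    seed_radius: float,
    settings: ShrinkWrapSettings | None = None,
    return_log: bool = False,
):
    """Deform a seed sphere onto the isosurface of ``volume``.

    ``direction='inward'`` expects the sphere to enclose the target surface;
    ``'outward'`` expects it strictly inside (e.g. in the endocranial
    cavity).  Containment is checked at the start.  Terminates when the
    maximum vertex displacement of an iteration falls below
    ``convergence_tol`` or after ``max_iterations``.
    """
    settings = settings or ShrinkWrapSettings()
    seed_center = np.asarray(seed_center, dtype=float)
    sdf = _signed_distance_grid(volume, settings.target_isovalue)

    lo, hi = volume.index_to_world([0, 0, 0])[0], volume.index_to_world(np.array(volume.shape) - 1)[0]
    if np.any(seed_center - seed_radius < lo) or np.any(seed_center + seed_radius > hi):
        raise ValueError("seed sphere escapes the volume bounds")

    edge_target = 2.0 * float(volume.spacing.min())
    mesh = icosphere_for_volume(seed_center, seed_radius, edge_target)
    v = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)

    d0 = _sample(sdf, volume, v)
    if settings.direction == "inward" and np.any(d0 < 0):
        raise ValueError("inward mode: seed sphere does not enclose the target surface")
    if settings.direction == "outward" and np.any(d0 < 0):
        raise ValueError("outward mode: seed sphere is not strictly inside the cavity")

    adj, deg = _neighbor_matrix(len(v), faces)
    w = settings.smoothing_weight
    log = ConvergenceLog()
    # inward mode: sphere normals point away from the target, so descending
    # the distance means stepping against the normal; outward mode is the
    # mirror case (normals point toward the target surface).
    sign = -1.0 if settings.direction == "inward" else 1.0
    grad = np.stack(np.gradient(sdf, *volume.spacing), axis=-1)

    for it in range(settings.max_iterations):
        n = _vertex_normals(v, faces)
        d = _sample(sdf, volume, v)
        step = np.clip(d, -settings.step_size, settings.step_size)
        moved = v + sign * step[:, None] * n
        if w > 0:
            lap = (adj @ v) / deg[:, None]
            new_v = (1 - w) * (moved) + w * lap
        else:
            new_v = moved
        # non-penetration: smoothing may drag vertices inside the target
        # solid; project those back onto the zero level along the distance
        # gradient so the wrap stays an enclosing (resp. inscribed) surface
        d_new = _sample(sdf, volume, new_v)
        inside = d_new < 0
        if inside.any():
            g = np.stack([_sample(grad[..., k], volume, new_v[inside]) for k in range(3)], axis=1)
            g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 0.25)
            new_v[inside] -= d_new[inside, None] * g
        disp = np.linalg.norm(new_v - v, axis=1).max()
        v = new_v
        log.iterations.append((it, float(disp)))
        if disp < settings.convergence_tol:
            log.converged = True
            break

    out = trimesh.Trimesh(vertices=v, faces=faces, process=False)
    if return_log:
        return out, log
    return out


def brain_hull(
    mri_volume: VolumeImage,
    brain_mask: VolumeImage,
    settings: ShrinkWrapSettings | None = None,
) -> trimesh.Trimesh:
    """Inward shrink-wrap of the (cleaned) binary brain mask.

    The mask is reduced to its largest connected component with holes
    filled, then wrapped from an enclosing sphere.  Default smoothing keeps
    groove-scale depressions visible while bridging sub-groove detail.
    """
    mask = np.asarray(brain_mask.values) > 0.5
    if not mask.any():
        raise ValueError("empty brain mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    clean = brain_mask.copy_with(mask.astype(np.float32))

    idx = np.argwhere(mask)
    world = clean.index_to_world(idx)
    center = world.mean(axis=0)
    radius = float(np.linalg.norm(world - center, axis=1).max()) + 3.0 * float(clean.spacing.max())
    # make sure the enclosing seed sphere fits inside the grid
    lo = clean.index_to_world([0, 0, 0])[0]
    hi = clean.index_to_world(np.array(clean.shape) - 1)[0]
    overhang = max(np.max(center + radius - hi), np.max(lo - (center - radius)), 0.0)
    if overhang > 0:
        clean = pad_volume(clean, overhang + 2.0 * float(clean.spacing.max()))
    # light smoothing: enough to bridge voxel-scale detail, light enough that
    # groove-scale depressions stay visible to the curvature detector
    settings = settings or ShrinkWrapSettings(direction="inward")
    return shrink_wrap(clean, center, radius, settings)


def endocast_surface(
    ct_volume: VolumeImage,
    settings: ShrinkWrapSettings | None = None,
    shell_threshold: float = 0.5,
) -> trimesh.Trimesh:
    """Outward shrink-wrap of the endocranial cavity of a CT-like volume.

    The cavity is the interior of the cranial shell (holes of the
    thresholded shell); the wrap inflates a small sphere from the cavity
    centroid onto the inner table.
    """
    shell = np.asarray(ct_volume.values) > shell_threshold
    lab, n = ndimage.label(shell)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        shell = lab == (1 + int(np.argmax(sizes)))
    cavity = ndimage.binary_fill_holes(shell) & ~shell
    if not cavity.any():
        raise ValueError("no endocranial cavity found inside the shell")
    lab, n = ndimage.label(cavity)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    cavity = lab == (1 + int(np.argmax(sizes)))

    idx = np.argwhere(cavity)
    world = ct_volume.index_to_world(idx)
    center = world.mean(axis=0)
    # target surface = boundary of the cavity; wrap outward from the centre
    cavity_img = ct_volume.copy_with((~cavity).astype(np.float32))  # foreground outside cavity
    settings = settings or ShrinkWrapSettings(direction="outward")
    d_in = ndimage.distance_transform_edt(cavity, sampling=ct_volume.spacing)
    r0 = min(0.5 * float(d_in.max()), 10.0)
    return shrink_wrap(cavity_img, center, r0, settings)


# ---------------------------------------------------------------------------
# exact-count resampling


def _mesh_checks(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        raise ValueError("mesh must be watertight")


def resample_mesh(mesh: trimesh.Trimesh, target_faces: int = 100_000) -> trimesh.Trimesh:
    """Resample a watertight mesh to exactly ``target_faces`` faces.

    If the mesh is below the budget it is uniformly subdivided first, then
    shortest-edge midpoint collapses reduce it to the exact count.  A closed
    manifold triangulation always has an even face count, so ``target_faces``
    must be even.  Geometry is preserved to well within twice the mean input
    edge length (symmetric Hausdorff).
    """
    _mesh_checks(mesh)
    if target_faces < 4:
        raise ValueError("target_faces below the topological minimum (4)")
    if target_faces % 2:
        raise ValueError("a closed triangulation has an even face count")
    if len(mesh.faces) == target_faces:
        return trimesh.Trimesh(
            vertices=np.asarray(mesh.vertices).copy(),
            faces=np.asarray(mesh.faces).copy(),
            process=False,
        )
    work = mesh
    while len(work.faces) < target_faces:
        v, f = trimesh.remesh.subdivide(work.vertices, work.faces)
        work = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if len(work.faces) == target_faces:
        return work
    v, f = _collapse_to_count(
        np.asarray(work.vertices, dtype=float), np.asarray(work.faces, dtype=np.int64), target_faces
    )
    out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    return out


def _collapse_to_count(vertices: np.ndarray, faces: np.ndarray, target: int):
    """Shortest-edge midpoint collapse until exactly ``target`` faces remain."""
    nv = len(vertices)
    pos: list[tuple[float, float, float]] = [tuple(p) for p in vertices]
    alive_v = np.ones(nv, dtype=bool)
    face_list = [tuple(f) for f in faces]
    alive_f = np.ones(len(face_list), dtype=bool)
    v_faces: list[set[int]] = [set() for _ in range(nv)]
    for fi, f in enumerate(face_list):
        for vi in f:
            v_faces[vi].add(fi)

    def neighbors(u):
        out = set()
        for fi in v_faces[u]:
            out.update(face_list[fi])
        out.discard(u)
        return out

    version = np.zeros(nv, dtype=np.int64)
    heap: list[tuple[float, int, int, int, int]] = []

    def edge_len(a, b):
        pa, pb = pos[a], pos[b]
        return ((pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2 + (pa[2] - pb[2]) ** 2) ** 0.5

    def push_edges_of(u):
        for w_ in neighbors(u):
            a, b = (u, w_) if u < w_ else (w_, u)
            heapq.heappush(heap, (edge_len(a, b), a, b, int(version[a]), int(version[b])))

    for u in range(nv):
        for w_ in neighbors(u):
            if u < w_:
                heapq.heappush(heap, (edge_len(u, w_), u, w_, 0, 0))

    n_faces = int(alive_f.sum())
    while n_faces > target:
        if not heap:
            raise RuntimeError("ran out of collapsible edges before reaching the target")
        d, u, v, vu, vv = heapq.heappop(heap)
        if not (alive_v[u] and alive_v[v]):
            continue
        if version[u] != vu or version[v] != vv:
            continue
        shared = v_faces[u] & v_faces[v]
        if len(shared) != 2:
            continue
        # link condition: common neighbours must be exactly the two apex vertices
        apex = set()
        for fi in shared:
            apex.update(face_list[fi])
        apex -= {u, v}
        if neighbors(u) & neighbors(v) != apex:
            continue

        pu, pv = pos[u], pos[v]
        mid = (0.5 * (pu[0] + pv[0]), 0.5 * (pu[1] + pv[1]), 0.5 * (pu[2] + pv[2]))
        # normal-flip guard on surviving faces around u and v (plain floats:
        # this loop dominates the runtime of a 100k-face resample)
        flip = False
        for fi in (v_faces[u] | v_faces[v]) - shared:
            f = face_list[fi]
            p0 = mid if f[0] == u or f[0] == v else pos[f[0]]
            p1 = mid if f[1] == u or f[1] == v else pos[f[1]]
            p2 = mid if f[2] == u or f[2] == v else pos[f[2]]
            q0, q1, q2 = pos[f[0]], pos[f[1]], pos[f[2]]
            ax, ay, az = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
            bx, by, bz = p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2]
            nx, ny, nz = ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx
            cx, cy, cz = q1[0] - q0[0], q1[1] - q0[1], q1[2] - q0[2]
            dx2, dy2, dz2 = q2[0] - q0[0], q2[1] - q0[1], q2[2] - q0[2]
            ox, oy, oz = cy * dz2 - cz * dy2, cz * dx2 - cx * dz2, cx * dy2 - cy * dx2
            if nx * nx + ny * ny + nz * nz < 1e-28 or nx * ox + ny * oy + nz * oz <= 0:
                flip = True
                break
        if flip:
            continue

        # perform the collapse: v merges into u at the midpoint
        pos[u] = mid
        for fi in shared:
            alive_f[fi] = False
            for x in face_list[fi]:
                v_faces[x].discard(fi)
        n_faces -= 2
        for fi in list(v_faces[v]):
            f = face_list[fi]
            face_list[fi] = tuple(u if x == v else x for x in f)
            v_faces[v].discard(fi)
            v_faces[u].add(fi)
        alive_v[v] = False
        version[u] += 1  # stale heap entries for u are skipped on pop
        push_edges_of(u)

    keep = np.flatnonzero(alive_f)
    new_faces = np.array([face_list[fi] for fi in keep], dtype=np.int64)
    used = np.unique(new_faces)
    remap = -np.ones(nv, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return np.array([pos[i] for i in used], dtype=float), remap[new_faces]
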