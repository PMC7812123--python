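"""Paired synthetic brain-hull / endocast phantoms with exact ground truth.

The phantom stands in for paired clinical MRI (brain) and CT (cranium) scans
of one individual.  The brain is a flattened-base ellipsoid with grooves
("sulci") carved along well-separated geodesic-like arcs; the endocast is the
same shape offset outward by a dura/CSF shell thickness, with grooves
attenuated in depth, a configurable fraction of them absent, the superior cap
optionally smoothed, and a midline sagittal-sinus ridge added — the known
ways a real endocast under-represents the brain surface.  The "CT" volume is
a cranial shell whose inner surface is the endocast, posed under a known
rigid(+scale) offset relative to the "MRI" frame, with its own intensity
profile and noise so multimodal registration is exercised non-trivially.

Everything downstream is geometry-agnostic, so an ellipsoid rather than an
anatomical template keeps the ground truth exact: every groove centre path,
the dropped labels, and the true inter-modality transform are recorded in
:class:`PhantomTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .curves import CurveSet, LabeledCurve, load_vocabulary
from .geometry import resample_polyline
from .volume import RigidSimilarityTransform, VolumeImage, resample_volume, save_nifti

SKULL_THICKNESS_MM = 4.0  # outer table of the phantom cranial shell


@dataclass
class PhantomParams:
    """Parameters of the paired phantom.  All lengths in mm."""

    semi_axes: tuple[float, float, float] = (48.0, 38.0, 33.0)
    n_sulci: int = 10
    groove_depth: float = 3.0
    groove_width: float = 4.0
    shell_thickness: float = 2.0
    depth_attenuation: float = 0.3
    drop_fraction: float = 0.2
    superior_smoothing: float = 3.0
    sinus_ridge_height: float = 2.5
    superior_cap_angle_deg: float = 40.0
    modality_transform: RigidSimilarityTransform = field(
        default_factory=lambda: RigidSimilarityTransform.from_params([0.0, 0.0, 5.0], [4.0, -3.0, 2.0])
    )
    voxel_size: float = 1.0
    noise_sd: float = 0.03
    seed: int = 0
    base_cut: float = 0.55  # flat base at z = -base_cut * c

    def validate(self) -> None:
        lengths = (*self.semi_axes, self.groove_depth, self.groove_width,
                   self.shell_thickness, self.voxel_size)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if not (0 <= self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in [0, 1)")
        if not (0 <= self.depth_attenuation <= 1):
            raise ValueError("depth_attenuation must be in [0, 1]")
        if self.voxel_size > self.groove_width / 2:
            raise ValueError(
                f"grooves are sub-voxel: voxel_size {self.voxel_size} > groove_width/2 "
                f"= {self.groove_width / 2}"
            )
        if self.n_sulci < 0:
            raise ValueError("n_sulci must be non-negative")

    @property
    def n_dropped(self) -> int:
        return int(round(self.drop_fraction * self.n_sulci))


@dataclass
class PhantomTruth:
    """Exact ground truth of one phantom (all geometry in the MRI frame)."""

    brain_mesh: trimesh.Trimesh
    endocast_mesh: trimesh.Trimesh
    brain_curves: CurveSet
    endocast_curves: CurveSet
    dropped_labels: list[str]
    modality_transform: RigidSimilarityTransform
    brain_mask: VolumeImage | None = None
    endocast_mask: VolumeImage | None = None


# ---------------------------------------------------------------------------
# grid / implicit-shape helpers


def _make_grid(params: PhantomParams) -> VolumeImage:
    margin = params.shell_thickness + SKULL_THICKNESS_MM + params.sinus_ridge_height + 6.0
    extent = np.asarray(params.semi_axes) + margin
    shape = np.ceil(2 * extent / params.voxel_size).astype(int) + 1
    origin = -extent
    return VolumeImage(values=np.zeros(shape, dtype=np.float32),
                       spacing=np.full(3, params.voxel_size), origin=origin)


def _grid_world(grid: VolumeImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [grid.origin[k] + np.arange(grid.shape[k]) * grid.spacing[k] for k in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _signed_distance(params: PhantomParams, grid: VolumeImage) -> np.ndarray:
    """Approximate signed distance (mm) to the flattened ellipsoid surface.

    Uses the first-order estimate (phi - 1) / |grad phi| for the ellipsoid
    combined with the exact distance to the base cut plane; negative inside.
    Building both the brain (level 0) and the endocast (level
    ``shell_thickness``) from this one field makes their offset exact up to
    voxel dithering.
    """
    a, b, c = params.semi_axes
    x, y, z = _grid_world(grid)
    phi = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    gnorm = 2.0 * np.sqrt((x / a**2) ** 2 + (y / b**2) ** 2 + (z / c**2) ** 2)
    sdf_ell = (phi - 1.0) / np.maximum(gnorm, 1e-9)
    sdf_plane = (-params.base_cut * c) - z  # positive below the cut plane
    return np.maximum(sdf_ell, sdf_plane)


def _brain_solid_mask(params: PhantomParams, grid: VolumeImage) -> np.ndarray:
    return _signed_distance(params, grid) <= 0.0


def _surface_normal(params: PhantomParams, pts: np.ndarray) -> np.ndarray:
    """Outward ellipsoid normal at points on/near the ellipsoid surface."""
    a, b, c = params.semi_axes
    g = pts / np.array([a**2, b**2, c**2])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# groove catalogue


def _arc_catalogue(params: PhantomParams, rng: np.random.Generator) -> list[np.ndarray]:
    """Well-separated geodesic-like arcs on the ellipsoid surface.

    Arcs are great-circle segments of the unit sphere mapped through the
    ellipsoid's axis scaling; they avoid the flattened base and the superior
    cap, and any two arcs stay at least 2 x groove_width apart so a 10 mm
    matching threshold remains meaningful between neighbouring grooves.
    """
    a, b, c = params.semi_axes
    min_sep = 2.0 * params.groove_width
    cap_limit = np.radians(params.superior_cap_angle_deg + 12.0)
    arcs: list[np.ndarray] = []
    attempts = 0
    while len(arcs) < params.n_sulci:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place {params.n_sulci} grooves with {min_sep} mm separation"
            )
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        e1 = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(n, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        theta0 = rng.uniform(0, 2 * np.pi)
        span = np.radians(rng.uniform(45.0, 75.0))
        theta = theta0 + np.linspace(0.0, span, 48)
        p = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
        polar = np.arccos(np.clip(p[:, 2], -1, 1))
        if np.any(polar < cap_limit):
            continue
        q = p * np.array([a, b, c])
        if np.any(q[:, 2] < -0.30 * c):
            continue
        ok = True
        for other in arcs:
            d = np.linalg.norm(q[:, None, :] - other[None, :, :], axis=2)
            if d.min() < min_sep:
                ok = False
                break
        if ok:
            arcs.append(q)
    return arcs


def _arc_labels(params: PhantomParams, arcs: list[np.ndarray]) -> list[tuple[str, str]]:
    vocab = load_vocabulary()
    out = []
    for i, arc in enumerate(arcs):
        name = vocab[i % len(vocab)] if i < len(vocab) else f"{vocab[i % len(vocab)]} {i // len(vocab) + 1}"
        my = float(np.mean(arc[:, 1]))
        side = "midline" if abs(my) < 2.0 else ("left" if my < 0 else "right")
        out.append((name, side))
    return out


# ---------------------------------------------------------------------------
# carving


def carve_groove(
    volume: VolumeImage, path: np.ndarray, depth: float, width: float,
    background: float = 0.0,
) -> VolumeImage:
    """Erode the volume's foreground along a groove following ``path``.

    The groove has an elliptical cross-section: at lateral offset ``l`` from
    the path the carve depth is ``depth * sqrt(1 - (2 l / width)^2)``, so the
    floor is a single curved furrow (one concave minimum, as a sulcal
    imprint) rather than a flat-bottomed channel.  The local inward
    direction is the gradient of the smoothed foreground.  ``depth = 0``
    returns the input unchanged; disjoint grooves commute.  The path must
    lie inside the volume bounds.
    """
    path = np.asarray(path, dtype=float)
    if depth < 0 or width <= 0:
        raise ValueError("depth must be >= 0 and width > 0")
    idx = volume.world_to_index(path)
    if np.any(idx < -0.5) or np.any(idx > np.array(volume.shape) - 0.5):
        raise ValueError("groove path lies outside the volume bounds")
    if depth == 0:
        return volume.copy_with(volume.values.copy())

    vals = np.asarray(volume.values, dtype=float)
    lo, hi = vals.min(), vals.max()
    fg = vals > (lo + hi) / 2.0
    smooth = ndimage.gaussian_filter(fg.astype(float), sigma=1.0)
    grad = np.stack(np.gradient(smooth, *volume.spacing), axis=-1)

    step = volume.spacing.min() / 2.0
    dense = resample_polyline(path, step)
    didx = volume.world_to_index(dense)
    g = np.stack(
        [ndimage.map_coordinates(grad[..., k], didx.T, order=1) for k in range(3)], axis=1
    )
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    inward = np.where(norm > 1e-9, g / np.maximum(norm, 1e-12), 0.0)

    # candidate voxels: everything within reach of the carved pocket
    bidx = np.round(didx).astype(int)
    bidx = np.clip(bidx, 0, np.array(volume.shape) - 1)
    seeds = np.zeros(volume.shape, dtype=bool)
    seeds[bidx[:, 0], bidx[:, 1], bidx[:, 2]] = True
    reach = float(np.hypot(width / 2.0, depth)) + float(volume.spacing.max())
    dist = ndimage.distance_transform_edt(~seeds, sampling=volume.spacing)
    cand = np.argwhere((dist <= reach) & fg)
    if len(cand) == 0:
        return volume.copy_with(vals.copy().astype(volume.values.dtype))

    from scipy.spatial import cKDTree

    world = volume.index_to_world(cand)
    tree = cKDTree(dense)
    _, nearest = tree.query(world)
    w_vec = world - dense[nearest]
    n_hat = inward[nearest]
    s = np.einsum("ij,ij->i", w_vec, n_hat)  # depth below the surface path
    lat = np.linalg.norm(w_vec - s[:, None] * n_hat, axis=1)
    frac = 1.0 - (2.0 * lat / width) ** 2
    local_depth = depth * np.sqrt(np.maximum(frac, 0.0))
    carve = (frac > 0.0) & (s >= -volume.spacing.max()) & (s <= local_depth)

    out = vals.copy()
    ci = cand[carve]
    out[ci[:, 0], ci[:, 1], ci[:, 2]] = background
    return volume.copy_with(out.astype(volume.values.dtype))


# ---------------------------------------------------------------------------
# phantom assembly


def _mask_to_mesh(mask: np.ndarray, grid: VolumeImage, smooth_sigma: float = 0.7) -> trimesh.Trimesh:
    f = ndimage.gaussian_filter(mask.astype(float), sigma=smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5)
    verts = verts * grid.spacing + grid.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh


def _cap_weight(grid: VolumeImage, cap_angle_deg: float) -> np.ndarray:
    """1 inside the superior polar cap, 0 outside, smooth 10-degree ramp."""
    x, y, z = _grid_world(grid)
    r = np.sqrt(x**2 + y**2 + z**2) + 1e-9
    polar = np.degrees(np.arccos(np.clip(z / r, -1, 1)))
    return np.clip((cap_angle_deg + 10.0 - polar) / 10.0, 0.0, 1.0)


def make_phantom(
    params: PhantomParams,
) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Generate the paired MRI-like and CT-like volumes plus ground truth.

    Deterministic given ``params.seed``.  The MRI volume holds the grooved
    brain as bright foreground in the MRI frame; the CT volume holds the
    cranial shell (inner surface = endocast) posed under
    ``params.modality_transform``; all truth geometry is in the MRI frame.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    grid = _make_grid(params)
    vox = params.voxel_size
    a, b, c = params.semi_axes

    arcs = _arc_catalogue(params, rng)
    labels = _arc_labels(params, arcs)
    n_drop = params.n_dropped
    drop_idx = sorted(rng.choice(params.n_sulci, size=n_drop, replace=False)) if n_drop else []
    dropped_labels = [labels[i][0] for i in drop_idx]

    # --- brain (MRI frame)
    sdf = _signed_distance(params, grid)
    brain_solid = sdf <= 0.0
    brain_img = grid.copy_with(brain_solid.astype(np.float32))
    for arc in arcs:
        brain_img = carve_groove(brain_img, arc, params.groove_depth, params.groove_width)
    brain_mask = brain_img.values > 0.5

    # --- endocast (MRI frame): exact outward offset of the ungrooved brain
    endo_solid = sdf <= params.shell_thickness
    endo_img = grid.copy_with(endo_solid.astype(np.float32))
    endo_depth = params.groove_depth * (1.0 - params.depth_attenuation)
    kept = [i for i in range(params.n_sulci) if i not in drop_idx]
    if endo_depth > 0:
        nrm = [_surface_normal(params, arc) for arc in arcs]
        for i in kept:
            endo_arc = arcs[i] + params.shell_thickness * nrm[i]
            endo_img = carve_groove(endo_img, endo_arc, endo_depth, params.groove_width)
    endo_mask = endo_img.values > 0.5

    if params.superior_smoothing > 0:
        w = _cap_weight(grid, params.superior_cap_angle_deg)
        f = ndimage.gaussian_filter(endo_mask.astype(float), sigma=params.superior_smoothing / vox)
        endo_mask = (w * f + (1 - w) * endo_mask) > 0.5

    if params.sinus_ridge_height > 0:
        theta = np.radians(np.linspace(-(params.superior_cap_angle_deg + 8.0),
                                       params.superior_cap_angle_deg + 8.0, 64))
        mid = np.stack([np.zeros_like(theta), b * np.sin(theta), c * np.cos(theta)], axis=1)
        mid = mid + params.shell_thickness * _surface_normal(params, mid)
        midx = np.round(grid.world_to_index(mid)).astype(int)
        seeds = np.zeros(grid.shape, dtype=bool)
        seeds[midx[:, 0], midx[:, 1], midx[:, 2]] = True
        dist = ndimage.distance_transform_edt(~seeds, sampling=grid.spacing)
        endo_mask = endo_mask | (dist <= params.sinus_ridge_height)

    # --- tissue regions shared by both modalities (MRI frame)
    dist_endo = ndimage.distance_transform_edt(~endo_mask, sampling=grid.spacing)
    skull = (dist_endo <= SKULL_THICKNESS_MM) & ~endo_mask
    scalp = (dist_endo <= SKULL_THICKNESS_MM + 3.0) & ~skull & ~endo_mask
    gap = endo_mask & ~brain_mask  # dura/CSF between brain and inner table

    # MRI: bright brain with a mild internal gradient, dark CSF and bone,
    # mid-grey scalp (T1-like contrast)
    x, y, z = _grid_world(grid)
    phi = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    mri = np.zeros(grid.shape)
    mri[brain_mask] = (0.85 - 0.25 * phi)[brain_mask]
    mri[gap] = 0.2
    mri[skull] = 0.05
    mri[scalp] = 0.5
    mri = ndimage.gaussian_filter(mri, sigma=0.5)
    mri = mri + rng.normal(0.0, params.noise_sd, size=mri.shape)
    mri_volume = grid.copy_with(mri.astype(np.float32))

    # CT: bright bone, faint soft tissue; posed under the modality transform
    ct_field = np.zeros(grid.shape)
    ct_field[brain_mask] = 0.2
    ct_field[gap] = 0.2
    ct_field[skull] = 1.0
    ct_field[scalp] = 0.35
    ct_field = ndimage.gaussian_filter(ct_field, sigma=0.5)
    ct = resample_volume(grid.copy_with(ct_field.astype(np.float32)),
                         params.modality_transform, grid)
    ct_vals = ct.values + rng.normal(0.0, params.noise_sd, size=ct.values.shape)
    ct_volume = ct.copy_with(ct_vals.astype(np.float32))

    # --- ground truth
    brain_mesh = _mask_to_mesh(brain_mask, grid)
    endocast_mesh = _mask_to_mesh(endo_mask, grid)

    brain_curves, endo_curves = [], []
    for i, arc in enumerate(arcs):
        name, side = labels[i]
        n_hat = _surface_normal(params, arc)
        bottom = arc - params.groove_depth * n_hat
        brain_curves.append(LabeledCurve(points=resample_polyline(bottom, 1.0),
                                         label=name, side=side))
        if i in drop_idx:
            continue
        e_base = arc + params.shell_thickness * n_hat
        e_bottom = e_base - endo_depth * n_hat
        endo_curves.append(LabeledCurve(points=resample_polyline(e_bottom, 1.0),
                                        label=name, side=side))

    truth = PhantomTruth(
        brain_mesh=brain_mesh,
        endocast_mesh=endocast_mesh,
        brain_curves=CurveSet(curves=brain_curves, source="brain-hull"),
        endocast_curves=CurveSet(curves=endo_curves, source="endocast"),
        dropped_labels=dropped_labels,
        modality_transform=params.modality_transform,
        brain_mask=grid.copy_with(brain_mask.astype(np.float32)),
        endocast_mask=grid.copy_with(endo_mask.astype(np.float32)),
    )
    return mri_volume, ct_volume, truth


def save_phantom(outdir: str | Path, mri: VolumeImage, ct: VolumeImage, truth: PhantomTruth) -> None:
    """Write a phantom to disk (NIfTI volumes, PLY meshes, curve JSON)."""
    from .curves import write_curves

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_nifti(mri, outdir / "mri.nii.gz")
    save_nifti(ct, outdir / "ct.nii.gz")
    truth.brain_mesh.export(outdir / "truth_brain_mesh.ply")
    truth.endocast_mesh.export(outdir / "truth_endocast_mesh.ply")
    write_curves(truth.brain_curves, outdir / "truth_brain_curves.json")
    write_curves(truth.endocast_curves, outdir / "truth_endocast_curves.json")
    truth.modality_transform.save(outdir / "truth_modality_transform.txt")
    (outdir / "dropped_labels.txt").write_text("\n".join(truth.dropped_labels) + "\n")
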