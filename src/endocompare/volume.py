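"""Volume images, rigid/similarity transforms, and NMI rigid registration.

Conventions (used everywhere in the package): world coordinates in mm, RAS
axes, voxel centres at ``origin + orientation @ (index * spacing)``, indices
0-based.  Transforms map *moving-frame* world points into the *fixed* frame;
to resample the moving image onto the fixed grid we pull values from the
moving image at the inverse-transformed fixed voxel centres.

Normalized mutual information is the bounded Studholme variant
NMI = (H(A) + H(B)) / H(A, B) computed from a joint histogram over the
overlap region (64 bins per channel by default, intensities min-max scaled
over the overlap).  It is 2 for identical images and tends to 1 for
independent ones, and is robust to the partial overlap typical of multimodal
head images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

DEFAULT_NMI_BINS = 64


@dataclass
class VolumeImage:
    """A 3D scalar grid with world geometry (mm)."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive per axis")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be orthonormal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = self.orientation @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm points (n, 3) to fractional voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return ((points - self.origin) @ self.orientation) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx * self.spacing) @ self.orientation.T + self.origin

    def sample(self, points: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Trilinear sample at world points; out-of-field -> ``background``."""
        idx = self.world_to_index(points)
        return ndimage.map_coordinates(
            self.values.astype(float), idx.T, order=1, mode="constant", cval=background
        )

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        return replace(self, values=values)


@dataclass
class RigidSimilarityTransform:
    """x_fixed = scale * R @ x_moving + t   (scale fixed to 1 for volumes)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidSimilarityTransform":
        return cls()

    @classmethod
    def from_params(cls, rotvec_deg: np.ndarray, translation: np.ndarray, scale: float = 1.0):
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rotation=rot.as_matrix(), translation=np.asarray(translation, float), scale=scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, other: "RigidSimilarityTransform") -> "RigidSimilarityTransform":
        """self o other: apply ``other`` first."""
        return RigidSimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "RigidSimilarityTransform":
        rinv = self.rotation.T
        return RigidSimilarityTransform(
            rotation=rinv,
            translation=-rinv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidSimilarityTransform":
        m = np.asarray(m, dtype=float)
        lin = m[:3, :3]
        scale = float(np.cbrt(np.linalg.det(lin)))
        return cls(rotation=lin / scale, translation=m[:3, 3].copy(), scale=scale)

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, header="4x4 world-mm transform, row-major")

    @classmethod
    def load(cls, path: str | Path) -> "RigidSimilarityTransform":
        return cls.from_matrix(np.loadtxt(path))

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_nifti(image: VolumeImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), image.affine), str(path))


def load_nifti(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return VolumeImage(
        values=np.asarray(img.get_fdata(), dtype=np.float32),
        spacing=spacing,
        origin=aff[:3, 3].copy(),
        orientation=lin / spacing,
    )


# ---------------------------------------------------------------------------
# NMI and rigid registration


def _overlap_samples(
    fixed: VolumeImage,
    moving: VolumeImage,
    transform: RigidSimilarityTransform,
    fixed_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired intensity samples over the overlap of fixed and warped moving."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in fixed.shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    vals = fixed.values.ravel()
    if fixed_mask is not None:
        keep = np.asarray(fixed_mask).ravel()
        idx = idx[keep]
        vals = vals[keep]
    world = fixed.index_to_world(idx)
    midx = moving.world_to_index(transform.inverse().apply(world))
    inside = np.all((midx >= 0) & (midx <= np.array(moving.shape) - 1), axis=1)
    if not inside.any():
        raise ValueError("empty overlap between fixed and transformed moving image")
    a = vals[inside].astype(float)
    b = ndimage.map_coordinates(moving.values.astype(float), midx[inside].T, order=1)
    return a, b


def nmi(
    fixed: VolumeImage,
    moving: VolumeImage,
    transform: RigidSimilarityTransform | None = None,
    n_bins: int = DEFAULT_NMI_BINS,
    fixed_mask: np.ndarray | None = None,
) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) over the overlap.

    ``fixed_mask`` optionally restricts the histogram to a region of
    interest of the fixed image (e.g. head voxels), which sharpens the
    metric when large empty backgrounds would otherwise dominate it.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    transform = transform or RigidSimilarityTransform.identity()
    a, b = _overlap_samples(fixed, moving, transform, fixed_mask)

    def _scaled(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    ha, _, _ = np.histogram2d(_scaled(a), _scaled(b), bins=n_bins, range=[[0, 1], [0, 1]])
    p = ha / ha.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = _entropy(p.ravel())
    if h_ab == 0.0:  # both images constant over the overlap
        return 2.0
    return (_entropy(pa) + _entropy(pb)) / h_ab


@dataclass
class RegistrationSettings:
    """Optimizer settings for NMI rigid registration.

    The coarse stage scans a translation grid (±``coarse_range_mm`` in steps
    of ``coarse_step_mm``) at the initial rotation; the best start is refined
    by Nelder-Mead over all 6 rigid DOF.  The capture range is therefore
    about ±``coarse_range_mm`` in translation and ~10° in rotation.
    """

    n_bins: int = DEFAULT_NMI_BINS
    coarse_range_mm: float = 8.0
    coarse_step_mm: float = 4.0
    max_iters: int = 400
    xatol: float = 0.01
    fatol: float = 1e-7
    stride: int = 1  # fixed-grid subsampling during optimization (speed)


@dataclass
class RigidRegistrationResult:
    transform: RigidSimilarityTransform
    nmi_init: float
    nmi_final: float
    converged: bool


def register_rigid_nmi(
    fixed: VolumeImage,
    moving: VolumeImage,
    init: RigidSimilarityTransform | None = None,
    settings: RegistrationSettings | None = None,
) -> RigidRegistrationResult:
    """Maximize NMI over rigid transforms (rotation + translation, scale 1).

    Guarantees NMI(final) >= NMI(init): if the optimizer fails to improve,
    the initial transform is returned with ``converged=False``.
    """
    init = init or RigidSimilarityTransform.identity()
    settings = settings or RegistrationSettings()
    init_rotvec = Rotation.from_matrix(init.rotation).as_rotvec(degrees=True)

    s = max(1, int(settings.stride))
    fixed_opt = fixed if s == 1 else VolumeImage(
        values=fixed.values[::s, ::s, ::s],
        spacing=fixed.spacing * s,
        origin=fixed.origin.copy(),
        orientation=fixed.orientation.copy(),
    )
    # focus the metric on the fixed image's foreground (head) so empty
    # background noise cannot flatten or displace the NMI peak
    from skimage.filters import threshold_otsu

    try:
        mask = fixed_opt.values > threshold_otsu(np.asarray(fixed_opt.values))
        mask = ndimage.binary_dilation(mask, iterations=2)
        if mask.mean() > 0.9 or not mask.any():
            mask = None  # no meaningful background to exclude
    except ValueError:  # constant image
        mask = None

    def params_to_transform(p):
        return RigidSimilarityTransform.from_params(p[:3], p[3:6])

    def neg_nmi(p):
        try:
            return -nmi(fixed_opt, moving, params_to_transform(p), settings.n_bins, fixed_mask=mask)
        except ValueError:  # empty overlap
            return 0.0

    score_init = nmi(fixed_opt, moving, init, settings.n_bins, fixed_mask=mask)

    # coarse translation scan around the initial translation
    steps = np.arange(-settings.coarse_range_mm, settings.coarse_range_mm + 1e-9, settings.coarse_step_mm)
    best_p = np.concatenate([init_rotvec, init.translation])
    best_score = -neg_nmi(best_p)
    for dx in steps:
        for dy in steps:
            for dz in steps:
                p = np.concatenate([init_rotvec, init.translation + [dx, dy, dz]])
                s = -neg_nmi(p)
                if s > best_score:
                    best_score, best_p = s, p

    # explicit initial simplex: Nelder-Mead's default steps are proportional
    # to the parameter values, which are ~0 here; seed it at 2 deg / 2 mm
    simplex = [best_p.copy()]
    for k, delta in enumerate([2.0, 2.0, 2.0, 2.0, 2.0, 2.0]):
        q = best_p.copy()
        q[k] += delta
        simplex.append(q)
    res = optimize.minimize(
        neg_nmi,
        best_p,
        method="Nelder-Mead",
        options={
            "maxiter": settings.max_iters,
            "xatol": settings.xatol,
            "fatol": settings.fatol,
            "initial_simplex": np.array(simplex),
        },
    )
    final_p = res.x if -res.fun >= best_score else best_p
    final_score = max(-res.fun, best_score)

    # second refinement pass with a tighter simplex (0.5 deg / 0.5 mm)
    simplex2 = [final_p.copy()]
    for k in range(6):
        q = final_p.copy()
        q[k] += 0.5
        simplex2.append(q)
    res2 = optimize.minimize(
        neg_nmi, final_p, method="Nelder-Mead",
        options={"maxiter": settings.max_iters, "xatol": settings.xatol / 2,
                 "fatol": settings.fatol, "initial_simplex": np.array(simplex2)},
    )
    if -res2.fun > final_score:
        final_p, final_score = res2.x, -res2.fun
        res = res2
    if final_score >= score_init:
        return RigidRegistrationResult(
            transform=params_to_transform(final_p),
            nmi_init=score_init,
            nmi_final=final_score,
            converged=bool(res.success),
        )
    return RigidRegistrationResult(
        transform=init, nmi_init=score_init, nmi_final=score_init, converged=False
    )


def resample_volume(
    image: VolumeImage,
    transform: RigidSimilarityTransform,
    reference: VolumeImage,
    background: float = 0.0,
) -> VolumeImage:
    """Resample ``image`` through ``transform`` onto the grid of ``reference``.

    ``transform`` maps image-frame world points into the reference frame;
    values are pulled by trilinear interpolation, out-of-field voxels are
    filled with ``background``.
    """
    if min(reference.shape) < 2:
        raise ValueError("degenerate reference grid")
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in reference.shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = reference.index_to_world(idx)
    midx = image.world_to_index(transform.inverse().apply(world))
    vals = ndimage.map_coordinates(
        image.values.astype(float), midx.T, order=1, mode="constant", cval=background
    )
    return VolumeImage(
        values=vals.reshape(reference.shape),
        spacing=reference.spacing.copy(),
        origin=reference.origin.copy(),
        orientation=reference.orientation.copy(),
    )
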