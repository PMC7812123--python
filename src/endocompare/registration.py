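"""Brain-hull to endocast surface registration and curve transport.

Two stages mirror how surface comparisons are normally set up:

1. :func:`align_rigid_scale` — iterative closest point over rotation,
   translation and one uniform scale (Umeyama solve per iteration), to
   remove pose and global size.
2. :func:`register_diffeo` — a smooth, one-to-one deformation parameterized
   by control points carrying momentum vectors.  The velocity field is a sum
   of Gaussian kernels K(x, c) = exp(-|x - c|^2 / sigma^2) weighted by the
   momenta; mesh vertices and control points are advected through an
   explicit Euler integration of this flow.  Momenta are held constant in
   time (a one-parameter subfamily of the usual geodesic flows), which keeps
   the transport a genuine flow of a smooth velocity field — hence
   invertible — while making the objective gradient exactly computable by
   reverse-mode accumulation through the Euler steps.

The data term is a varifold distance: surfaces are compared through their
face centroids and (area-weighted) normals with a Gaussian spatial kernel
and an orientation-insensitive squared-cosine weighting, so inconsistent
mesh orientations cannot corrupt the match.  The regularizer is the kinetic
energy of the momenta in the kernel metric at the initial control points.
Optimization is gradient descent with backtracking line search: the energy
trace is non-increasing by construction.

Any point set can be transported through a fitted deformation — in
particular sulcal curves detected on the brain hull, which is how they are
carried into the endocast frame for matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .curves import CurveSet, LabeledCurve
from .volume import RigidSimilarityTransform


# ---------------------------------------------------------------------------
# rigid + uniform scale (ICP / Umeyama)


def _umeyama(src: np.ndarray, dst: np.ndarray) -> RigidSimilarityTransform:
    """Least-squares similarity transform mapping src points onto dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (sc**2).sum() / len(src)
    scale = float(np.trace(np.diag(S) @ D) / var_s)
    t = mu_d - scale * R @ mu_s
    return RigidSimilarityTransform(rotation=R, translation=t, scale=scale)


def align_rigid_scale(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    max_iterations: int = 200,
    tol: float = 1e-6,
    n_samples: int = 2000,
) -> RigidSimilarityTransform:
    """ICP over rotation, translation and uniform scale (source -> target).

    Correspondences are exact closest points on the target *surface* (not
    nearest vertices), which avoids the vertex-locking minima of plain
    nearest-neighbour ICP; each iteration solves the similarity transform in
    closed form (Umeyama), so the RMS closest-point distance is
    non-increasing.  Initialized by centroid alignment and RMS-radius
    scaling, restarted from a small catalogue of initial rotations (identity
    and +/-20 degrees about each axis); the restart with the lowest mean
    distance wins, giving a capture range of roughly +/-30 degrees.
    Degenerate (flat or collinear) sources are rejected.
    """
    from scipy.spatial.transform import Rotation

    from .geometry import SurfaceDistanceQuery

    src_all = np.asarray(source.vertices, dtype=float)
    tgt_v = np.asarray(target.vertices, dtype=float)
    if np.linalg.matrix_rank(src_all - src_all.mean(axis=0), tol=1e-9) < 3:
        raise ValueError("degenerate source mesh (flat or collinear)")
    step = max(1, len(src_all) // n_samples)
    src = src_all[::step]
    query = SurfaceDistanceQuery(tgt_v, np.asarray(target.faces, dtype=np.int64))

    mu_s, mu_t = src.mean(axis=0), tgt_v.mean(axis=0)
    rms_s = np.sqrt(((src - mu_s) ** 2).sum(axis=1).mean())
    rms_t = np.sqrt(((tgt_v - mu_t) ** 2).sum(axis=1).mean())
    s0 = rms_t / rms_s

    def run_icp(start):
        best, best_d = start, np.inf
        prev = np.inf
        cur = start
        for _ in range(max_iterations):
            cp, d = query.query(cur.apply(src))
            d_mean = float(d.mean())
            if d_mean < best_d:
                best, best_d = cur, d_mean
            if prev - d_mean < tol:
                break
            prev = d_mean
            cur = _umeyama(src, cp)
        return best, best_d

    starts = [np.eye(3)]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            rv = np.zeros(3)
            rv[axis] = sign * 20.0
            starts.append(Rotation.from_rotvec(rv, degrees=True).as_matrix())

    overall, overall_d = None, np.inf
    for R0 in starts:
        init = RigidSimilarityTransform(
            rotation=R0, translation=mu_t - s0 * R0 @ mu_s, scale=s0
        )
        tf, d = run_icp(init)
        if d < overall_d:
            overall, overall_d = tf, d
    return overall


# ---------------------------------------------------------------------------
# varifold data term


def _face_geometry(vertices: np.ndarray, faces: np.ndarray):
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    centroids = (a + b + c) / 3.0
    normals = 0.5 * np.cross(b - a, c - a)  # length = face area
    return centroids, normals


def _gauss_kernel_matrix(c1: np.ndarray, c2: np.ndarray, sigma: float) -> np.ndarray:
    """exp(-|c1_i - c2_j|^2 / sigma^2) without materializing the (i, j, 3) tensor."""
    sq1 = np.einsum("ij,ij->i", c1, c1)
    sq2 = np.einsum("ij,ij->i", c2, c2)
    d2 = sq1[:, None] + sq2[None, :] - 2.0 * (c1 @ c2.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / sigma**2)


def _varifold_product(c1, n1, c2, n2, sigma):
    k = _gauss_kernel_matrix(c1, c2, sigma)
    dot = n1 @ n2.T
    a1 = np.linalg.norm(n1, axis=1)
    a2 = np.linalg.norm(n2, axis=1)
    denom = np.maximum(a1[:, None] * a2[None, :], 1e-14)
    return float((k * dot**2 / denom).sum())


def varifold_distance(
    source: trimesh.Trimesh | tuple, target: trimesh.Trimesh | tuple, sigma: float
) -> float:
    """Squared varifold distance |S - T|^2 between two surfaces."""

    def geom(m):
        if isinstance(m, tuple):
            return _face_geometry(np.asarray(m[0], float), np.asarray(m[1], np.int64))
        return _face_geometry(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))

    cs, ns = geom(source)
    ct, nt = geom(target)
    return (
        _varifold_product(cs, ns, cs, ns, sigma)
        - 2.0 * _varifold_product(cs, ns, ct, nt, sigma)
        + _varifold_product(ct, nt, ct, nt, sigma)
    )


def _varifold_loss_and_grad(
    verts: np.ndarray, faces: np.ndarray, ct: np.ndarray, nt: np.ndarray, sigma: float,
    target_self: float,
):
    """Varifold distance to a fixed target and its gradient w.r.t. vertices."""
    cs, ns = _face_geometry(verts, faces)

    def term_and_grads(c2, n2, factor):
        k = _gauss_kernel_matrix(cs, c2, sigma)
        dot = ns @ n2.T
        a1 = np.linalg.norm(ns, axis=1)
        a2 = np.linalg.norm(n2, axis=1)
        denom = np.maximum(a1[:, None] * a2[None, :], 1e-14)
        w = dot**2 / denom
        val = factor * float((k * w).sum())
        # d/d centroid: sum_j kw (-2/sigma^2)(cs_i - c2_j), all as matrix products
        kw = k * w * (-2.0 / sigma**2)
        g_c = factor * (kw.sum(axis=1)[:, None] * cs - kw @ c2)
        # d/d normal via the quotient rule on dot^2 / (|ns| |n2|)
        g_n = factor * (
            (k * 2.0 * dot / denom) @ n2
            - ns * ((k * dot**2 / (np.maximum(a1, 1e-14) ** 3)[:, None] / np.maximum(a2, 1e-14)[None, :]).sum(axis=1))[:, None]
        )
        return val, g_c, g_n

    v_ss, gc_ss, gn_ss = term_and_grads(cs, ns, 1.0)
    v_st, gc_st, gn_st = term_and_grads(ct, nt, -2.0)
    loss = v_ss + v_st + target_self
    g_c = 2.0 * gc_ss + gc_st  # self term: cs appears on both sides
    g_n = 2.0 * gn_ss + gn_st

    # chain to vertices: centroid is the face mean; normal = 0.5 (b-a)x(c-a)
    grad = np.zeros_like(verts)
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    pa, pb, pc = verts[a], verts[b], verts[c]
    np.add.at(grad, a, g_c / 3.0)
    np.add.at(grad, b, g_c / 3.0)
    np.add.at(grad, c, g_c / 3.0)
    np.add.at(grad, a, 0.5 * np.cross(pb - pc, g_n))
    np.add.at(grad, b, 0.5 * np.cross(pc - pa, g_n))
    np.add.at(grad, c, 0.5 * np.cross(pa - pb, g_n))
    return loss, grad


# ---------------------------------------------------------------------------
# deformation model


@dataclass
class DeformationModel:
    """Control points + momenta defining a Gaussian-kernel velocity flow."""

    control_points: np.ndarray
    momenta: np.ndarray
    kernel_width: float
    n_timesteps: int = 10

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.momenta = np.asarray(self.momenta, dtype=float)
        if self.control_points.shape != self.momenta.shape:
            raise ValueError("control_points and momenta must have equal shape")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "endocompare-deformation",
            "version": 1,
            "kernel_width": self.kernel_width,
            "n_timesteps": self.n_timesteps,
            "control_points": self.control_points.tolist(),
            "momenta": self.momenta.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "DeformationModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "endocompare-deformation":
            raise ValueError(f"{path}: not a deformation model file")
        return cls(
            control_points=np.asarray(doc["control_points"], float),
            momenta=np.asarray(doc["momenta"], float),
            kernel_width=float(doc["kernel_width"]),
            n_timesteps=int(doc["n_timesteps"]),
        )


def _kernel(x: np.ndarray, c: np.ndarray, sigma: float) -> np.ndarray:
    return _gauss_kernel_matrix(x, c, sigma)


def _flow_forward(model: DeformationModel, points: np.ndarray, keep_path: bool = False):
    """Advect ``points`` (and the control points) through the Euler flow."""
    dt = 1.0 / model.n_timesteps
    x = points.astype(float).copy()
    c = model.control_points.copy()
    al = model.momenta
    sig = model.kernel_width
    xs, cs = [x.copy()], [c.copy()]
    for _ in range(model.n_timesteps):
        kxc = _kernel(x, c, sig)
        kcc = _kernel(c, c, sig)
        x = x + dt * kxc @ al
        c = c + dt * kcc @ al
        if keep_path:
            xs.append(x.copy())
            cs.append(c.copy())
    if keep_path:
        return x, c, xs, cs
    return x, c


def transport_points(model: DeformationModel, points: np.ndarray) -> np.ndarray:
    """Apply the fitted flow to arbitrary points (identity for zero momenta)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.any(model.momenta):
        return points.copy()
    x, _ = _flow_forward(model, points)
    return x


def transport_curves(model: DeformationModel, curves: CurveSet) -> CurveSet:
    """Transport every polyline point; labels/sides/strengths unchanged."""
    out = [
        LabeledCurve(
            points=transport_points(model, c.points),
            label=c.label,
            side=c.side,
            strength=c.strength,
        )
        for c in curves
    ]
    return CurveSet(curves=out, source=curves.source)


def _control_grid(points: np.ndarray, n_target: int) -> np.ndarray:
    """Regular grid over the bounding box with about ``n_target`` nodes."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    h = (span.prod() / n_target) ** (1.0 / 3.0)
    ns = np.maximum(2, np.round(span / h).astype(int) + 1)
    axes = [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return g


@dataclass
class RegistrationResult:
    model: DeformationModel
    deformed_source: trimesh.Trimesh
    energy_trace: list[float]
    final_data_term: float
    initial_data_term: float
    rigid_prealign: RigidSimilarityTransform | None = None

    def __post_init__(self):
        if any(b > a + 1e-9 for a, b in zip(self.energy_trace, self.energy_trace[1:])):
            raise ValueError("energy trace must be non-increasing")


def register_diffeo(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    kernel_width: float = 15.0,
    data_kernel_width: float = 5.0,
    n_control_points: int = 1000,
    regularization_weight: float = 1e-4,
    n_timesteps: int = 10,
    max_iters: int = 80,
    seed: int = 0,
    grad_tol: float = 1e-8,
) -> RegistrationResult:
    """Fit the kernel flow deforming ``source`` onto ``target``.

    Minimizes ``varifold(phi(S), T) + w * alpha' K alpha`` by gradient
    descent on the momenta with backtracking line search, starting from zero
    momenta (deterministic; ``seed`` is kept for API stability and any
    stochastic initialization variants).  The energy trace is non-increasing
    by construction.  Sources are expected to be pre-aligned
    (``align_rigid_scale``) so the deformation only carries shape change.
    """
    if kernel_width <= 0 or data_kernel_width <= 0:
        raise ValueError("kernel widths must be positive")
    del seed  # deterministic zero-momenta start
    verts = np.asarray(source.vertices, dtype=float)
    faces = np.asarray(source.faces, dtype=np.int64)
    ct, nt = _face_geometry(np.asarray(target.vertices, float), np.asarray(target.faces, np.int64))
    target_self = _varifold_product(ct, nt, ct, nt, data_kernel_width)

    control = _control_grid(verts, n_control_points)
    alpha = np.zeros_like(control)
    sig = kernel_width
    dt = 1.0 / n_timesteps
    k0 = _kernel(control, control, sig)

    def forward(al):
        x = verts.copy()
        c = control.copy()
        xs, cs = [x.copy()], [c.copy()]
        for _ in range(n_timesteps):
            kxc = _kernel(x, c, sig)
            kcc = _kernel(c, c, sig)
            x = x + dt * kxc @ al
            c = c + dt * kcc @ al
            xs.append(x.copy())
            cs.append(c.copy())
        return xs, cs

    def energy_and_grad(al, need_grad=True):
        xs, cs = forward(al)
        data, gx_final = _varifold_loss_and_grad(
            xs[-1], faces, ct, nt, data_kernel_width, target_self
        )
        reg = float(np.einsum("ia,ij,ja->", al, k0, al))
        e = data + regularization_weight * reg
        if not need_grad:
            return e, data, None
        # reverse-mode through the Euler steps
        xbar = gx_final
        cbar = np.zeros_like(control)
        abar = 2.0 * regularization_weight * (k0 @ al)
        for t in range(n_timesteps - 1, -1, -1):
            x, c = xs[t], cs[t]
            kxc = _kernel(x, c, sig)
            kcc = _kernel(c, c, sig)

            # alpha gradient from both updates
            abar += dt * (kxc.T @ xbar + kcc.T @ cbar)

            # w_ij = xbar_i . alpha_j  (x-update), u_kj = cbar_k . alpha_j;
            # all (i, j, 3) contractions reduce to matrix products since
            # dx_ijk = x_ik - c_jk
            w = xbar @ al.T  # (nx, nc)
            u = cbar @ al.T  # (nc, nc)
            coef_x = kxc * w * (-2.0 / sig**2)
            xbar_new = xbar + dt * (coef_x.sum(axis=1)[:, None] * x - coef_x @ c)
            cbar_new = cbar - dt * (coef_x.T @ x - coef_x.sum(axis=0)[:, None] * c)
            coef_c = kcc * u * (-2.0 / sig**2)
            cbar_new = cbar_new + dt * (coef_c.sum(axis=1)[:, None] * c - coef_c @ c)
            cbar_new = cbar_new - dt * (coef_c.T @ c - coef_c.sum(axis=0)[:, None] * c)
            xbar, cbar = xbar_new, cbar_new
        return e, data, abar

    e0, data0, _ = energy_and_grad(alpha, need_grad=False)
    trace = [e0]
    step = None
    for _ in range(max_iters):
        e, data, g = energy_and_grad(alpha)
        gnorm2 = float((g**2).sum())
        if gnorm2 < grad_tol:
            break
        if step is None:
            step = 0.1 * max(np.abs(alpha).max(), 1.0) / max(np.abs(g).max(), 1e-12)
        improved = False
        for _try in range(25):
            cand = alpha - step * g
            e_new, data_new, _ = energy_and_grad(cand, need_grad=False)
            if e_new < e:
                alpha = cand
                trace.append(e_new)
                data = data_new
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if len(trace) > 2 and trace[-2] - trace[-1] < 1e-10 * max(abs(trace[0]), 1.0):
            break

    model = DeformationModel(
        control_points=control, momenta=alpha, kernel_width=sig, n_timesteps=n_timesteps
    )
    deformed, _ = _flow_forward(model, verts)
    final_data, _ = _varifold_loss_and_grad(deformed, faces, ct, nt, data_kernel_width, target_self)
    return RegistrationResult(
        model=model,
        deformed_source=trimesh.Trimesh(vertices=deformed, faces=faces.copy(), process=False),
        energy_trace=trace,
        final_data_term=float(final_data),
        initial_data_term=float(data0),
    )
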