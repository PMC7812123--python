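"""End-to-end pipeline: phantom -> segment -> detect -> register -> match.

Each stage is an ordinary function that reads its inputs from the run
directory and writes its outputs back there, so any stage can be rerun from
disk alone; :func:`run_pipeline` simply chains them and records a manifest
(parameters, per-stage seeds and timings).  Reruns with the same config are
bit-identical for all deterministic outputs.

The base seed fans out to per-stage seeds through a fixed counter scheme so
a stage rerun in isolation sees the same randomness as in a full run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .curves import CurveSet, label_by_reference, read_curves, write_curves
from .detect import detect_sulci
from .io_utils import dump_flat_toml, write_vtk_mesh_scalar, write_vtk_polylines
from .matching import (MatchReport, distance_field, displacement_map, match_curves,
                       summarize)
from .phantom import PhantomParams, make_phantom, save_phantom
from .registration import (DeformationModel, align_rigid_scale, register_diffeo,
                           transport_curves)
from .surface import (ShrinkWrapSettings, brain_hull, endocast_surface, resample_mesh)
from .volume import (RegistrationSettings, RigidSimilarityTransform, load_nifti,
                     register_rigid_nmi)

logger = logging.getLogger(__name__)

STAGES = ("phantom", "segment", "detect", "register", "match")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are left in the run directory."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SegmentationConfig:
    brain_threshold: float = 0.3  # MRI foreground threshold (intensity units)
    ct_threshold: float = 0.5  # CT shell threshold
    smoothing_weight: float = 0.3
    step_size: float = 1.0
    max_iterations: int = 400
    convergence_tol: float = 0.01
    target_faces: int = 100_000  # the study's face budget per surface


@dataclass
class DetectionConfig:
    k_percentile: float = 75.0
    min_length_mm: float = 12.0
    smooth_iterations: int = 2
    max_assign_dist_mm: float = 5.0  # reference-labeling acceptance radius


@dataclass
class RegistrationConfig:
    registration_faces: int = 2000  # meshes are decimated to this for fitting
    kernel_width_mm: float = 15.0
    data_kernel_width_mm: float = 5.0
    n_control_points: int = 600
    regularization_weight: float = 1e-4
    n_timesteps: int = 10
    max_iters: int = 40
    nmi_bins: int = 64
    nmi_stride: int = 2  # fixed-grid subsampling during NMI optimization


@dataclass
class MatchingConfig:
    tau_mm: float = 10.0
    influence_radius_mm: float = 10.0
    render_clip_mm: float = 5.0


@dataclass
class PipelineConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    seed: int = 0
    name: str = "phantom-run"

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * len(STAGES) + STAGES.index(stage)) % (2**31 - 1)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "run": {"seed": self.seed, "name": self.name},
            "phantom": dataclasses.asdict(self.phantom),
            "segmentation": dataclasses.asdict(self.segmentation),
            "detection": dataclasses.asdict(self.detection),
            "registration": dataclasses.asdict(self.registration),
            "matching": dataclasses.asdict(self.matching),
        }
        tf = d["phantom"].pop("modality_transform")
        d["phantom"]["modality_matrix"] = [float(x) for x in np.asarray(tf["scale"]) * np.asarray(tf["rotation"]).flatten()] + [
            float(x) for x in tf["translation"]
        ]
        d["phantom"]["semi_axes"] = list(d["phantom"]["semi_axes"])
        return d

    def save(self, path: str | Path) -> None:
        dump_flat_toml(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        run = d.pop("run", {})
        ph = dict(d.pop("phantom", {}))
        if "modality_matrix" in ph:
            m = np.asarray(ph.pop("modality_matrix"), dtype=float)
            lin = m[:9].reshape(3, 3)
            scale = float(np.cbrt(np.linalg.det(lin)))
            ph["modality_transform"] = RigidSimilarityTransform(
                rotation=lin / scale, translation=m[9:12], scale=scale
            )
        if "semi_axes" in ph:
            ph["semi_axes"] = tuple(ph["semi_axes"])
        return cls(
            phantom=PhantomParams(**ph),
            segmentation=SegmentationConfig(**d.pop("segmentation", {})),
            detection=DetectionConfig(**d.pop("detection", {})),
            registration=RegistrationConfig(**d.pop("registration", {})),
            matching=MatchingConfig(**d.pop("matching", {})),
            seed=int(run.get("seed", 0)),
            name=str(run.get("name", "phantom-run")),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing required input '{path.name}' in {path.parent} "
            f"(produced by stage '{produced_by}')"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_phantom(config: PipelineConfig, outdir: Path) -> None:
    params = dataclasses.replace(config.phantom, seed=config.stage_seed("phantom"))
    mri, ct, truth = make_phantom(params)
    save_phantom(outdir, mri, ct, truth)


def stage_segment(config: PipelineConfig, outdir: Path) -> None:
    seg = config.segmentation
    mri = load_nifti(_require(outdir / "mri.nii.gz", "phantom"))
    ct = load_nifti(_require(outdir / "ct.nii.gz", "phantom"))

    brain_mask = mri.copy_with((mri.values > seg.brain_threshold).astype(np.float32))
    wrap = ShrinkWrapSettings(
        direction="inward",
        smoothing_weight=seg.smoothing_weight,
        step_size=seg.step_size,
        max_iterations=seg.max_iterations,
        convergence_tol=seg.convergence_tol,
    )
    hull = brain_hull(mri, brain_mask, wrap)

    reg = register_rigid_nmi(
        mri, ct,
        settings=RegistrationSettings(
            n_bins=config.registration.nmi_bins,
            stride=config.registration.nmi_stride,
        ),
    )
    ct_to_mri = reg.transform
    ct_to_mri.save(outdir / "ct_to_mri_transform.txt")

    wrap_out = dataclasses.replace(wrap, direction="outward")
    endo_ct = endocast_surface(ct, wrap_out, shell_threshold=seg.ct_threshold)
    endo = trimesh.Trimesh(
        vertices=ct_to_mri.apply(endo_ct.vertices), faces=endo_ct.faces, process=False
    )

    hull = resample_mesh(hull, seg.target_faces)
    endo = resample_mesh(endo, seg.target_faces)
    hull.export(outdir / "brain_hull.ply")
    endo.export(outdir / "endocast.ply")


def stage_detect(config: PipelineConfig, outdir: Path) -> None:
    det = config.detection
    hull = trimesh.load(_require(outdir / "brain_hull.ply", "segment"), process=False)
    endo = trimesh.load(_require(outdir / "endocast.ply", "segment"), process=False)

    found = {}
    for name, mesh, src in (("brain", hull, "brain-hull"), ("endocast", endo, "endocast")):
        curves = detect_sulci(
            mesh,
            k_percentile=det.k_percentile,
            min_length=det.min_length_mm,
            smooth_iterations=det.smooth_iterations,
            source=src,
        )
        ref = read_curves(_require(outdir / f"truth_{name}_curves.json", "phantom"))
        labeled = label_by_reference(curves, ref, max_assign_dist=det.max_assign_dist_mm)
        # unidentified fragments are excluded from the comparison, mirroring
        # how only identified sulci enter the count statistics
        labeled = CurveSet(
            curves=[c for c in labeled if c.label != "unlabeled"], source=src
        )
        found[name] = labeled
        write_curves(labeled, outdir / f"detected_{name}_curves.json")
        write_vtk_polylines(labeled, outdir / f"detected_{name}_curves.vtk")
    logger.info(
        "detected %d brain / %d endocast labeled curves",
        len(found["brain"]), len(found["endocast"]),
    )


def stage_register(config: PipelineConfig, outdir: Path) -> None:
    reg = config.registration
    hull = trimesh.load(_require(outdir / "brain_hull.ply", "segment"), process=False)
    endo = trimesh.load(_require(outdir / "endocast.ply", "segment"), process=False)
    brain_curves = read_curves(_require(outdir / "detected_brain_curves.json", "detect"))

    src = resample_mesh(hull, reg.registration_faces)
    tgt = resample_mesh(endo, reg.registration_faces)
    prealign = align_rigid_scale(src, tgt)
    src_al = trimesh.Trimesh(vertices=prealign.apply(src.vertices), faces=src.faces, process=False)

    result = register_diffeo(
        src_al, tgt,
        kernel_width=reg.kernel_width_mm,
        data_kernel_width=reg.data_kernel_width_mm,
        n_control_points=reg.n_control_points,
        regularization_weight=reg.regularization_weight,
        n_timesteps=reg.n_timesteps,
        max_iters=reg.max_iters,
        seed=config.stage_seed("register"),
    )
    prealign.save(outdir / "hull_to_endocast_prealign.txt")
    result.model.save(outdir / "deformation_model.json")
    result.deformed_source.export(outdir / "deformed_brain_hull.ply")
    pd.DataFrame({"iteration": range(len(result.energy_trace)),
                  "energy": result.energy_trace}).to_csv(outdir / "energy_trace.csv", index=False)

    prealigned = CurveSet(
        curves=[dataclasses.replace(c, points=prealign.apply(c.points)) for c in brain_curves],
        source=brain_curves.source,
    )
    transported = transport_curves(result.model, prealigned)
    write_curves(transported, outdir / "transported_brain_curves.json")
    write_vtk_polylines(transported, outdir / "transported_brain_curves.vtk")


def stage_match(config: PipelineConfig, outdir: Path) -> None:
    m = config.matching
    endo_curves = read_curves(_require(outdir / "detected_endocast_curves.json", "detect"))
    brain_curves = read_curves(_require(outdir / "transported_brain_curves.json", "register"))
    endo_mesh = trimesh.load(_require(outdir / "endocast.ply", "segment"), process=False)
    deformed = trimesh.load(_require(outdir / "deformed_brain_hull.ply", "register"), process=False)

    report = match_curves(endo_curves, brain_curves, tau=m.tau_mm)
    report.name = config.name
    with open(outdir / "match_report.json", "w") as fh:
        json.dump(
            {
                "counts": report.counts,
                "tau_mm": report.tau,
                "matched_fraction": report.matched_fraction,
                "per_curve": [
                    {"curve_id": pc.curve_id, "label": pc.label,
                     "mean_distance_mm": pc.mean_distance, "matched": pc.matched}
                    for pc in report.per_curve
                ],
            },
            fh, indent=1,
        )
    summarize([report]).to_csv(outdir / "summary.csv", index=False)

    dfield = distance_field(endo_mesh, report, endo_curves, influence_radius=m.influence_radius_mm)
    write_vtk_mesh_scalar(endo_mesh, dfield, "curve_distance_mm", outdir / "distance_map.vtk")
    raw, clipped = displacement_map(deformed, endo_mesh, render_clip=m.render_clip_mm)
    write_vtk_mesh_scalar(endo_mesh, raw, "displacement_mm", outdir / "displacement_map.vtk")
    np.savetxt(outdir / "displacement_raw_mm.txt", raw.values)


_STAGE_FUNCS = {
    "phantom": stage_phantom,
    "segment": stage_segment,
    "detect": stage_detect,
    "register": stage_register,
    "match": stage_match,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages in order; returns the run directory.

    A failing stage raises :class:`PipelineError` naming the stage; outputs
    of completed stages are preserved.  The manifest records the package
    version, config, per-stage seeds and wall times.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.toml")
    timings = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as e:  # noqa: BLE001 - report the failing stage
            raise PipelineError(stage, e) from e
        timings[stage] = round(time.perf_counter() - t0, 2)
    manifest = {
        "package": "endocompare",
        "version": __version__,
        "name": config.name,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
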