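"""Shared fixtures: phantoms, analytic volumes and pipeline runs.

Heavy artefacts (phantom volumes, full pipeline runs) are session-scoped so
several tests can share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
import trimesh

from endocompare.phantom import PhantomParams, make_phantom
from endocompare.pipeline import PipelineConfig, run_pipeline
from endocompare.volume import VolumeImage


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom (drop 0.2, superior mismatch on)."""
    return make_phantom(PhantomParams(seed=42))


@pytest.fixture(scope="session")
def clean_phantom():
    """Phantom with no dropped sulci and no superior mismatch."""
    params = PhantomParams(
        drop_fraction=0.0, superior_smoothing=0.0, sinus_ridge_height=0.0, seed=42
    )
    return make_phantom(params)


@pytest.fixture(scope="session")
def ball_volume():
    """Binary ball of radius 30 mm on a 1 mm grid."""
    ax = -40.0 + np.arange(81) * 1.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return VolumeImage((r <= 30).astype(np.float32), np.ones(3), np.full(3, -40.0))


@pytest.fixture(scope="session")
def shell_volume():
    """Hollow spherical shell, inner radius 25 mm, outer 30 mm."""
    ax = -40.0 + np.arange(81) * 1.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return VolumeImage(((r >= 25) & (r <= 30)).astype(np.float32), np.ones(3), np.full(3, -40.0))


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    """A non-symmetric closed mesh for rigid/similarity recovery tests."""
    m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    m.apply_scale([30.0, 22.0, 18.0])
    return m


def _fast_config(**overrides) -> PipelineConfig:
    """Small, quick pipeline configuration for determinism-style tests."""
    cfg = PipelineConfig(
        phantom=PhantomParams(
            semi_axes=(34.0, 28.0, 24.0), n_sulci=6, seed=0,
            drop_fraction=0.0, superior_smoothing=0.0, sinus_ridge_height=0.0,
        ),
        seed=3,
        name="fast",
    )
    cfg.segmentation.target_faces = 20000
    cfg.registration.registration_faces = 1500
    cfg.registration.n_control_points = 400
    cfg.registration.max_iters = 25
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def fast_config():
    return _fast_config()


@pytest.fixture(scope="session")
def clean_pipeline_run(tmp_path_factory):
    """Full default-size pipeline on the clean phantom (no mismatch)."""
    cfg = PipelineConfig(
        phantom=PhantomParams(
            drop_fraction=0.0, superior_smoothing=0.0, sinus_ridge_height=0.0
        ),
        seed=7,
        name="clean",
    )
    out = tmp_path_factory.mktemp("run_clean")
    return cfg, run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def dropped_pipeline_run(tmp_path_factory):
    """Full pipeline on the default phantom (dropped sulci + mismatch)."""
    cfg = PipelineConfig(phantom=PhantomParams(), seed=7, name="default")
    out = tmp_path_factory.mktemp("run_default")
    return cfg, run_pipeline(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
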