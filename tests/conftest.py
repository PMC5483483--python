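"""Shared phantom fixtures.

Everything is generated at test time from the synthetic-phantom module;
expensive chains (geometry + sections on a tube) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortaflow import geometry, sections
from aortaflow.phantom import PhantomSpec, make_phantom
from aortaflow.pipeline_io import StudyConfig, run_pipeline
from aortaflow.preprocess import VelocityField

TUBE_RADIUS = 10.0       # mm
TUBE_VBAR = 0.5          # m/s
TUBE_WSS = 0.74          # Pa = 4 μ V̄ / R for μ = 3.7 cP
VOXEL = 1.6              # mm


@pytest.fixture(scope="session")
def steady_tube():
    """Steady Poiseuille tube phantom: R = 10 mm, V̄ = 0.5 m/s, 1.6 mm voxels."""
    spec = PhantomSpec(
        geometry_kind="straight_tube", radius=TUBE_RADIUS,
        length_or_arc=48.0, grid_shape=(25, 25, 36), n_frames=3,
        waveform=np.ones(3), mean_velocity=TUBE_VBAR, noise_sd=0.0, seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def tube_chain(steady_tube):
    """Full geometry + sections chain on the steady tube."""
    dataset, truth = steady_tube
    field_ = VelocityField.from_dataset(dataset)
    roi = geometry.ROIMask(mask=truth.lumen_mask, spacing=dataset.spacing,
                           origin=dataset.origin)
    surface = geometry.extract_surface(roi)
    skeleton = geometry.skeletonize_and_order(
        roi, truth.centerline[0], truth.centerline[-1])
    centerline = geometry.fit_centerline(skeleton, voxel_size=VOXEL)
    secs = sections.build_sections(field_, roi, surface, centerline)
    return {
        "dataset": dataset, "truth": truth, "field": field_, "roi": roi,
        "surface": surface, "skeleton": skeleton, "centerline": centerline,
        "sections": secs,
    }


@pytest.fixture(scope="session")
def torus_chain():
    """Torus-arc phantom (centerline = circle of radius 32 mm) with its
    skeleton-derived centerline."""
    spec = PhantomSpec(
        geometry_kind="torus_arc", radius=8.0, length_or_arc=180.0,
        torus_center_radius=32.0, grid_shape=(57, 13, 57), n_frames=3,
        waveform=np.ones(3), mean_velocity=0.4, noise_sd=0.0, seed=7)
    dataset, truth = make_phantom(spec)
    roi = geometry.ROIMask(mask=truth.lumen_mask, spacing=dataset.spacing,
                           origin=dataset.origin)
    skeleton = geometry.skeletonize_and_order(
        roi, truth.centerline[0], truth.centerline[-1])
    centerline = geometry.fit_centerline(skeleton, voxel_size=VOXEL)
    return {"dataset": dataset, "truth": truth, "roi": roi,
            "skeleton": skeleton, "centerline": centerline}


def pulsatile_config(seed: int = 3, **phantom_overrides) -> StudyConfig:
    phantom = dict(geometry_kind="straight_tube", radius=TUBE_RADIUS,
                   length_or_arc=48.0, grid_shape=(25, 25, 36), n_frames=10,
                   mean_velocity=TUBE_VBAR, noise_sd=0.0)
    phantom.update(phantom_overrides)
    return StudyConfig(phantom=phantom, seed=seed, apply_preprocess=False,
                       subject_id=f"phantom{seed}")


@pytest.fixture(scope="session")
def pulsatile_run():
    """Full pipeline on a pulsatile tube phantom (flow quantification on the
    clean decoded field)."""
    return run_pipeline(pulsatile_config(), write_outputs=False)
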