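"""Step 1 of the pipeline: phase decoding and velocity-field correction.

Encoded phase volumes are scaled by VENC into Cartesian velocity components,
then corrected for eddy-current offsets (first-order polynomial fitted to
static voxels), residual velocity aliasing (neighbourhood-median unwrapping),
and MR noise (3×3×3 componentwise median filter).  The stages must run in
that order; each records a provenance flag on the field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import FourDFlowDataset, decode_phase, voxel_centers

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityField",
    "decode_velocity",
    "correct_eddy_currents",
    "unwrap_aliasing",
    "median_filter",
    "speed",
    "preprocess",
]

_STAGE_ORDER = ["decoded", "eddy_corrected", "unwrapped", "median_filtered"]


@dataclass
class VelocityField:
    """Velocity volumes plus the provenance of applied corrections."""

    velocity: np.ndarray              # (n_frames, 3, nx, ny, nz) m/s
    spacing: np.ndarray               # (3,) mm
    frame_times: np.ndarray           # (n_frames,) ms
    venc: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    magnitude: np.ndarray | None = None
    flags: dict = field(default_factory=lambda: {s: False for s in _STAGE_ORDER})

    def _set_flag(self, name: str) -> None:
        # flags are monotone: stages run in pipeline order and are never unset
        idx = _STAGE_ORDER.index(name)
        if not self.flags["decoded"]:
            raise RuntimeError(f"stage {name!r} requires a decoded field")
        for later in _STAGE_ORDER[idx + 1:]:
            if self.flags[later]:
                raise RuntimeError(
                    f"stage {name!r} cannot run after {later!r}")
        self.flags[name] = True

    def copy(self) -> "VelocityField":
        return VelocityField(
            velocity=self.velocity.copy(),
            spacing=self.spacing.copy(),
            frame_times=self.frame_times.copy(),
            venc=self.venc,
            origin=self.origin.copy(),
            magnitude=None if self.magnitude is None else self.magnitude.copy(),
            flags=dict(self.flags),
        )

    @classmethod
    def from_dataset(cls, dataset: FourDFlowDataset,
                     decoded: bool = True) -> "VelocityField":
        flags = {s: False for s in _STAGE_ORDER}
        flags["decoded"] = decoded
        return cls(
            velocity=dataset.velocity.copy(),
            spacing=np.asarray(dataset.spacing, float),
            frame_times=np.asarray(dataset.frame_times, float),
            venc=dataset.venc,
            origin=np.asarray(dataset.origin, float),
            magnitude=dataset.magnitude.copy(),
            flags=flags,
        )


def decode_velocity(
    phase: np.ndarray,
    venc: float,
    spacing,
    frame_times,
    origin=None,
    magnitude: np.ndarray | None = None,
) -> VelocityField:
    """Scale phase volumes (radians in (−π, π]) into velocities, v = VENC·φ/π."""
    field_ = VelocityField(
        velocity=decode_phase(phase, venc),
        spacing=np.asarray(spacing, float),
        frame_times=np.asarray(frame_times, float),
        venc=venc,
        origin=np.zeros(3) if origin is None else np.asarray(origin, float),
        magnitude=magnitude,
    )
    field_.flags["decoded"] = True
    return field_


def _static_voxel_mask(field_: VelocityField, static_percentile: float) -> np.ndarray:
    """Voxels whose velocity is temporally steady and that look like background.

    Static candidates are voxels whose largest per-component temporal
    standard deviation falls below the given percentile of that statistic's
    distribution; when a magnitude image is available, voxels bright enough
    to be lumen are additionally excluded.
    """
    temporal_sd = field_.velocity.std(axis=0).max(axis=0)   # (nx, ny, nz)
    threshold = np.percentile(temporal_sd, static_percentile)
    static = temporal_sd <= threshold
    if field_.magnitude is not None:
        mag = field_.magnitude.mean(axis=0)
        lo, hi = np.percentile(mag, [5, 95])
        static &= mag < (lo + hi) / 2.0
    return static


def correct_eddy_currents(
    field_: VelocityField,
    static_percentile: float = 5.0,
) -> VelocityField:
    """Remove a first-order spatial polynomial offset per frame per component.

    A plane ``c0 + c1·x + c2·y + c3·z`` is least-squares fitted to the
    velocities of static voxels and subtracted everywhere, the standard
    first-order background-phase correction.
    """
    if field_.velocity.shape[0] < 2:
        raise ValueError("eddy-current correction needs at least 2 frames")
    out = field_.copy()
    static = _static_voxel_mask(field_, static_percentile)
    n_static = int(static.sum())
    if n_static < 4:
        raise ValueError(
            f"only {n_static} static voxels; need >= 4 to fit a first-order "
            "polynomial")
    centers = voxel_centers(field_.velocity.shape[2:], field_.spacing,
                            field_.origin)
    design_full = np.concatenate(
        [np.ones(centers.shape[:-1] + (1,)), centers], axis=-1)
    design = design_full[static]                        # (n_static, 4)
    for k in range(out.velocity.shape[0]):
        for c in range(3):
            coef, *_ = np.linalg.lstsq(design, field_.velocity[k, c][static],
                                       rcond=None)
            out.velocity[k, c] -= design_full @ coef
    out._set_flag("eddy_corrected")
    return out


def unwrap_aliasing(
    field_: VelocityField,
    venc: float | None = None,
    max_passes: int = 5,
) -> VelocityField:
    """Correct localized velocity wraps against the 26-neighbourhood median.

    A component differing from the median of its 26 neighbours by more than
    VENC is shifted by the nearest multiple of 2·VENC toward that median.
    Iterated to a fixpoint (at most ``max_passes`` sweeps); non-convergence
    is logged, not raised.
    """
    venc = field_.venc if venc is None else venc
    out = field_.copy()
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    for _ in range(max_passes):
        changed = 0
        for k in range(out.velocity.shape[0]):
            for c in range(3):
                v = out.velocity[k, c]
                med = ndimage.median_filter(v, footprint=footprint,
                                            mode="reflect")
                diff = v - med
                wrapped = np.abs(diff) > venc
                if np.any(wrapped):
                    shift = 2.0 * venc * np.round(diff[wrapped] / (2.0 * venc))
                    v[wrapped] -= shift
                    changed += int(wrapped.sum())
        if changed == 0:
            break
    else:
        logger.warning("aliasing unwrap did not converge in %d passes",
                       max_passes)
    out._set_flag("unwrapped")
    return out


def median_filter(field_: VelocityField) -> VelocityField:
    """3×3×3 componentwise median per frame (reflected edges)."""
    out = field_.copy()
    for k in range(out.velocity.shape[0]):
        for c in range(3):
            out.velocity[k, c] = ndimage.median_filter(
                out.velocity[k, c], size=3, mode="reflect")
    out._set_flag("median_filtered")
    return out


def speed(field_: VelocityField) -> np.ndarray:
    """Per-voxel, per-frame Euclidean norm of the velocity vector (m/s)."""
    return np.linalg.norm(field_.velocity, axis=1)


def preprocess(
    phase: np.ndarray | None = None,
    dataset: FourDFlowDataset | None = None,
    venc: float | None = None,
    spacing=None,
    frame_times=None,
    origin=None,
    magnitude=None,
    static_percentile: float = 5.0,
    apply_eddy: bool = True,
    apply_unwrap: bool = True,
    apply_median: bool = True,
) -> VelocityField:
    """Run the full step-1 chain: decode → eddy → unwrap → median."""
    if (phase is None) == (dataset is None):
        raise ValueError("provide exactly one of phase volumes or a dataset")
    if phase is not None:
        field_ = decode_velocity(phase, venc, spacing, frame_times,
                                 origin=origin, magnitude=magnitude)
    else:
        field_ = VelocityField.from_dataset(dataset)
    if apply_eddy:
        field_ = correct_eddy_currents(field_, static_percentile)
    if apply_unwrap:
        field_ = unwrap_aliasing(field_)
    if apply_median:
        field_ = median_filter(field_)
    return field_
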