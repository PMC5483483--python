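"""Synthetic phase-contrast 4D Flow phantoms with analytic ground truth.

Every downstream stage of the pipeline (preprocessing, geometry, cross
sections, bulk flow, wall shear stress, templates) is exercised on tube-shaped
digital flow phantoms generated here.  A phantom is a time series of 3D
Cartesian velocity volumes mimicking a phase-contrast acquisition: an
axisymmetric parabolic (Poiseuille) profile scaled by a per-frame waveform,
sampled on a voxel grid, optionally corrupted by Gaussian noise, first-order
eddy-current offsets and velocity aliasing.

The analytic truth travels with the dataset: for a straight tube with a
parabolic profile of bulk velocity V̄ and radius R the wall shear stress is
``4 μ V̄ / R`` at every wall point and the flow rate is ``π R² V̄``, so every
estimator downstream can be checked against a closed form.

Conventions used throughout the package:

* velocity arrays have shape ``(n_frames, 3, nx, ny, nz)`` in m/s,
* lengths are mm, frame times ms, viscosity Pa·s, shear stress Pa,
* world coordinates of voxel ``(i, j, k)`` are ``origin + (idx + 0.5)·spacing``
  (voxel-centre convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PhantomSpec",
    "FourDFlowDataset",
    "PhantomTruth",
    "make_phantom",
    "make_waveform",
    "encode_phase",
    "decode_phase",
    "wrap_phase",
    "corrupt",
]

#: blood dynamic viscosity, Pa·s (3.7 cP)
DEFAULT_VISCOSITY = 3.7e-3


@dataclass
class PhantomSpec:
    """Parameters of a synthetic flow phantom.

    Defaults mimic a state-of-the-art thoracic 4D Flow acquisition:
    1.6 mm isotropic voxels, 24 cardiac frames, VENC 1.5 m/s.
    """

    geometry_kind: Literal["straight_tube", "torus_arc"] = "straight_tube"
    radius: float = 10.0                      # lumen radius, mm
    length_or_arc: float = 48.0               # tube length mm, or arc degrees
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    voxel_spacing: tuple[float, float, float] = (1.6, 1.6, 1.6)
    grid_shape: tuple[int, int, int] = (25, 25, 36)
    n_frames: int = 24
    frame_times: np.ndarray | None = None     # ms; default uniform 40 ms
    venc: float = 1.5                         # m/s
    mean_velocity: float = 0.5                # peak-frame bulk velocity V̄, m/s
    waveform: np.ndarray | None = None        # per-frame multipliers in [0, 1]
    viscosity: float = DEFAULT_VISCOSITY      # Pa·s
    noise_sd: float = 0.0                     # m/s per component
    eddy_coeffs: np.ndarray | None = None
    alias_fraction: float = 0.0
    torus_center_radius: float = 40.0         # centerline circle radius, mm
    n_wall_samples: int = 72                  # circumferential truth samples
    seed: int = 0

    def __post_init__(self) -> None:
        spacing = np.asarray(self.voxel_spacing, float)
        if self.radius <= 2.0 * spacing.max():
            raise ValueError(
                f"radius {self.radius} mm must exceed twice the largest voxel "
                f"spacing ({spacing.max()} mm) to be resolvable"
            )
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.waveform is None:
            self.waveform = make_waveform(self.n_frames, 0.6)
        self.waveform = np.asarray(self.waveform, float)
        if self.waveform.shape != (self.n_frames,):
            raise ValueError("waveform must have one multiplier per frame")
        if self.frame_times is None:
            self.frame_times = 40.0 * np.arange(self.n_frames)
        self.frame_times = np.asarray(self.frame_times, float)


@dataclass
class FourDFlowDataset:
    """Time-resolved 3D velocity data with acquisition metadata."""

    velocity: np.ndarray          # (n_frames, 3, nx, ny, nz) m/s
    magnitude: np.ndarray         # (n_frames, nx, ny, nz) arbitrary units
    spacing: np.ndarray           # (3,) mm
    frame_times: np.ndarray       # (n_frames,) ms
    venc: float                   # m/s
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[2:]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        return voxel_centers(self.grid_shape, self.spacing, self.origin)

    def copy(self) -> "FourDFlowDataset":
        return FourDFlowDataset(
            velocity=self.velocity.copy(),
            magnitude=self.magnitude.copy(),
            spacing=self.spacing.copy(),
            frame_times=self.frame_times.copy(),
            venc=self.venc,
            origin=self.origin.copy(),
        )


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a phantom dataset."""

    wall_points: np.ndarray       # (n_wall, 3) mm, on the lumen surface
    wall_normals: np.ndarray      # (n_wall, 3) outward unit normals
    wss_magnitude: np.ndarray     # (n_frames, n_wall) Pa
    flow_rate: np.ndarray         # (n_frames,) ml/s
    centerline: np.ndarray        # (n_center, 3) mm
    cross_section_area: float     # mm²
    lumen_mask: np.ndarray        # (nx, ny, nz) bool
    radius: float                 # mm
    mean_velocity: np.ndarray     # (n_frames,) bulk velocity V̄(t), m/s
    curvature_radius: float | None = None   # mm, torus phantoms only
    aliased_voxels: np.ndarray | None = None  # bool (n_frames,3,nx,ny,nz)


def voxel_centers(grid_shape, spacing, origin) -> np.ndarray:
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    axes = [origin[d] + (np.arange(grid_shape[d]) + 0.5) * spacing[d]
            for d in range(3)]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=-1)


def make_waveform(n_frames: int, systole_fraction: float) -> np.ndarray:
    """Half-sine systolic waveform followed by a zero diastole.

    The first ``round(n_frames * systole_fraction)`` frames carry a half
    sine normalised to a unit maximum; the remaining frames are zero, so
    the waveform has a single maximum (nominal peak systole).
    """
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    if not 0.0 < systole_fraction <= 1.0:
        raise ValueError("systole_fraction must be in (0, 1]")
    n_sys = int(round(n_frames * systole_fraction))
    n_sys = max(n_sys, 1)
    w = np.zeros(n_frames)
    k = np.arange(n_sys)
    half_sine = np.sin(np.pi * (k + 0.5) / n_sys)
    w[:n_sys] = half_sine / half_sine.max()
    return w


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed frame."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _check_fits(extent_needed: float, extent_have: float, name: str) -> None:
    if extent_needed > extent_have:
        raise ValueError(
            f"grid too small along {name}: geometry needs {extent_needed:.1f} mm "
            f"but the grid spans {extent_have:.1f} mm"
        )


def make_phantom(spec: PhantomSpec) -> tuple[FourDFlowDataset, PhantomTruth]:
    """Build a synthetic 4D Flow dataset and its analytic truth.

    Voxels whose centre lies inside the analytic lumen surface carry the
    axisymmetric profile ``v(r) = 2 V̄(t) (1 − r²/R²)`` directed along the
    local axis; all other voxels are zero-flow.  Optional truncated Gaussian
    noise is added per component so that speeds stay below VENC (aliasing is
    only introduced explicitly through :func:`corrupt`).
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing, float)
    shape = tuple(spec.grid_shape)
    origin = np.zeros(3)
    centers = voxel_centers(shape, spacing, origin)
    extent = spacing * np.asarray(shape)
    grid_center = origin + extent / 2.0

    R = spec.radius
    if spec.geometry_kind == "straight_tube":
        axis = np.asarray(spec.axis, float)
        axis = axis / np.linalg.norm(axis)
        L = spec.length_or_arc
        # fitting check along each named world axis
        half = np.abs(axis) * (L / 2.0) + np.sqrt(
            np.maximum(0.0, 1.0 - axis**2)) * R
        for d, name in enumerate("xyz"):
            _check_fits(2 * half[d], extent[d], name)
        rel = centers - grid_center
        axial = rel @ axis
        radial_vec = rel - axial[..., None] * axis
        r = np.linalg.norm(radial_vec, axis=-1)
        lumen = (r < R) & (np.abs(axial) < L / 2.0)
        profile = np.where(lumen, 2.0 * (1.0 - (r / R) ** 2), 0.0)
        direction = np.broadcast_to(axis, centers.shape)
        # analytic centerline and wall samples
        t_axis = np.linspace(-L / 2.0, L / 2.0, 65)
        centerline = grid_center + t_axis[:, None] * axis
        e1, e2 = _orthonormal_basis(axis)
        theta = np.linspace(0, 2 * np.pi, spec.n_wall_samples, endpoint=False)
        n_rings = max(3, int(L / spacing.mean() / 2))
        ring_pos = np.linspace(-L / 2.0 * 0.8, L / 2.0 * 0.8, n_rings)
        wall_points, wall_normals = [], []
        for a in ring_pos:
            base = grid_center + a * axis
            for th in theta:
                n = np.cos(th) * e1 + np.sin(th) * e2
                wall_points.append(base + R * n)
                wall_normals.append(n)
        curvature_radius = None
    elif spec.geometry_kind == "torus_arc":
        arc_deg = spec.length_or_arc
        Rc = spec.torus_center_radius
        # circle in the x-z plane centred on the grid centre
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        _check_fits(2 * (Rc + R), extent[0], "x")
        _check_fits(2 * R, extent[1], "y")
        _check_fits(2 * (Rc + R), extent[2], "z")
        rel = centers - grid_center
        u = rel @ e1
        w = rel @ e2
        phi = np.arctan2(w, u)             # angle along the arc, [-pi, pi)
        arc = np.deg2rad(arc_deg)
        in_arc = (phi >= -arc / 2.0) & (phi <= arc / 2.0)
        # distance from the centerline circle
        rho = np.hypot(u, w)
        out_of_plane = rel - u[..., None] * e1 - w[..., None] * e2
        d = np.sqrt((rho - Rc) ** 2 + np.einsum("...i,...i", out_of_plane,
                                                out_of_plane))
        lumen = (d < R) & in_arc
        profile = np.where(lumen, 2.0 * (1.0 - (d / R) ** 2), 0.0)
        # local tangent of the circle, CCW in the (e1, e2) plane
        tangent = (-np.sin(phi))[..., None] * e1 + np.cos(phi)[..., None] * e2
        direction = tangent
        phis = np.linspace(-arc / 2.0, arc / 2.0, 129)
        centerline = (grid_center
                      + Rc * (np.cos(phis)[:, None] * e1
                              + np.sin(phis)[:, None] * e2))
        theta = np.linspace(0, 2 * np.pi, spec.n_wall_samples, endpoint=False)
        wall_points, wall_normals = [], []
        for ph in np.linspace(-arc / 2 * 0.8, arc / 2 * 0.8, 7):
            c = grid_center + Rc * (np.cos(ph) * e1 + np.sin(ph) * e2)
            radial = np.cos(ph) * e1 + np.sin(ph) * e2
            binormal = np.cross(e1, e2)
            for th in theta:
                n = np.cos(th) * radial + np.sin(th) * binormal
                wall_points.append(c + R * n)
                wall_normals.append(n)
        curvature_radius = Rc
    else:
        raise ValueError(f"unknown geometry_kind {spec.geometry_kind!r}")

    vbar_t = spec.mean_velocity * spec.waveform       # (n_frames,)
    velocity = np.zeros((spec.n_frames,) + shape + (3,))
    for k in range(spec.n_frames):
        velocity[k] = (vbar_t[k] * profile)[..., None] * direction
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, velocity.shape)
        velocity += noise
        # truncate so no speed exceeds VENC before phase encoding
        speed = np.linalg.norm(velocity, axis=-1)
        over = speed > spec.venc
        if np.any(over):
            scale = np.where(over, 0.999 * spec.venc / np.maximum(speed, 1e-12),
                             1.0)
            velocity *= scale[..., None]
    velocity = np.moveaxis(velocity, -1, 1)           # (T, 3, nx, ny, nz)

    magnitude = np.where(lumen, 1.0, 0.1)[None].repeat(spec.n_frames, axis=0)
    if spec.noise_sd > 0:
        magnitude = magnitude + rng.normal(0.0, 0.02, magnitude.shape)

    dataset = FourDFlowDataset(
        velocity=velocity,
        magnitude=magnitude,
        spacing=spacing,
        frame_times=spec.frame_times.copy(),
        venc=spec.venc,
        origin=origin,
    )

    wall_points = np.asarray(wall_points)
    wall_normals = np.asarray(wall_normals)
    # τ_wall = 4 μ V̄ / R  (R converted mm -> m)
    wss_t = 4.0 * spec.viscosity * vbar_t / (R * 1e-3)
    wss_magnitude = np.repeat(wss_t[:, None], len(wall_points), axis=1)
    area = np.pi * R**2                                # mm²
    flow_rate = area * vbar_t                          # mm²·(m/s) == ml/s

    truth = PhantomTruth(
        wall_points=wall_points,
        wall_normals=wall_normals,
        wss_magnitude=wss_magnitude,
        flow_rate=flow_rate,
        centerline=centerline,
        cross_section_area=area,
        lumen_mask=lumen,
        radius=R,
        mean_velocity=vbar_t,
        curvature_radius=curvature_radius,
    )

    if spec.eddy_coeffs is not None or spec.alias_fraction > 0:
        dataset, aliased = corrupt(dataset, spec.eddy_coeffs,
                                   spec.alias_fraction, spec.seed + 1)
        truth.aliased_voxels = aliased
    return dataset, truth


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, float), 2.0 * np.pi)


def encode_phase(dataset: FourDFlowDataset) -> np.ndarray:
    """Model the phase-contrast encoding: phase = π·v/VENC wrapped to (−π, π].

    Velocities beyond VENC alias; decoding wrapped phases is the identity
    only for ``|v| < VENC``.
    """
    if dataset.venc <= 0:
        raise ValueError("venc must be positive")
    return wrap_phase(np.pi * dataset.velocity / dataset.venc)


def decode_phase(phase: np.ndarray, venc: float) -> np.ndarray:
    """Inverse of :func:`encode_phase` for non-aliased velocities."""
    if venc <= 0:
        raise ValueError("venc must be positive")
    return venc * np.asarray(phase, float) / np.pi


def corrupt(
    dataset: FourDFlowDataset,
    eddy_coeffs: np.ndarray | None = None,
    alias_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[FourDFlowDataset, np.ndarray]:
    """Add first-order eddy-current offsets and wrap a fraction of voxels.

    ``eddy_coeffs`` has shape ``(n_frames, 3, 4)`` (or broadcastable to it):
    per frame and velocity component the offset is
    ``c0 + c1·x + c2·y + c3·z`` with world coordinates in mm and the result
    in m/s.  ``alias_fraction`` of the highest-speed voxels per frame are
    shifted by exactly ``∓2·VENC`` (the wrap a phase-contrast scanner would
    produce).  Returns the corrupted dataset and the boolean mask of aliased
    samples, shape ``(n_frames, 3, nx, ny, nz)``.
    """
    if not 0.0 <= alias_fraction <= 1.0:
        raise ValueError("alias_fraction must be in [0, 1]")
    out = dataset.copy()
    n_frames = out.n_frames
    shape = out.grid_shape
    aliased = np.zeros_like(out.velocity, dtype=bool)

    if eddy_coeffs is not None:
        coeffs = np.broadcast_to(np.asarray(eddy_coeffs, float),
                                 (n_frames, 3, 4))
        centers = out.voxel_centers()                     # (nx,ny,nz,3)
        design = np.concatenate(
            [np.ones(shape + (1,)), centers], axis=-1)    # (nx,ny,nz,4)
        for k in range(n_frames):
            for c in range(3):
                out.velocity[k, c] += design @ coeffs[k, c]

    if alias_fraction > 0:
        rng = np.random.default_rng(seed)
        for k in range(n_frames):
            speed = np.linalg.norm(out.velocity[k], axis=0)
            n_pick = int(round(alias_fraction * speed.size))
            if n_pick == 0:
                continue
            flat = np.argsort(speed, axis=None)[::-1][:n_pick]
            idx = np.unravel_index(flat, shape)
            for c in range(3):
                v = out.velocity[k, c][idx]
                shift = -2.0 * out.venc * np.sign(v)
                # zero components wrap in a random direction
                zero = v == 0
                if np.any(zero):
                    shift[zero] = 2.0 * out.venc * rng.choice(
                        [-1.0, 1.0], size=int(zero.sum()))
                out.velocity[k, c][idx] = v + shift
                aliased[(k, c) + idx] = True
    return out, aliased
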