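"""Step 5 of the pipeline: dual-method wall shear stress estimation.

Two estimators of the viscous wall shear stress vector are implemented.

**Global Volumetric (GV)** — normalised 3D Sobel derivative filters give the
voxelwise velocity-gradient tensor over the whole volume; the off-diagonal
shear tensor ``τ_ij = μ(∂u_i/∂x_j + ∂u_j/∂x_i)`` (i ≠ j, diagonal zero) is
interpolated at each wall point (offset one voxel inward along the radial
direction so the zero-velocity exterior does not bias the stencil), the
traction is ``T = τ·x'_r`` and the shear vector its tangential projection
``WSS = x'_r × (T × x'_r)``.  GV captures spatial patterns but systematically
underestimates magnitudes, because the Sobel stencil averages across the
steep near-wall velocity gradient.

**Local Planar (LP)** — works on a single cross-section: each local
velocity component is represented by a piecewise-cubic spline interpolant
of the in-plane samples, and its wall-normal derivative is extracted by a
one-sided quadratic fit along the inward radial ray, extrapolated to the
wall.  Along the wall the velocity is identically zero (no slip), so at a
boundary point the full in-plane gradient of each component is its normal
derivative times the normal direction; the shear tensor, traction, and
tangential projection are then assembled exactly as for GV.  Out-of-plane
derivatives are unavailable from one section and are taken as zero.  LP is
markedly more accurate pointwise than GV.

Time-dependency metrics (AWSS, AWSSV, OSI, RRT, TransWSS and the component
oscillation indices) are integrated by the trapezoid rule over the systolic
window, first frame through end systole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import DEFAULT_VISCOSITY
from .sections import CrossSection

logger = logging.getLogger(__name__)

__all__ = [
    "WSSMetrics",
    "velocity_gradient_sobel",
    "strain_tensor_gv",
    "wss_gv",
    "wss_lp",
    "wss_lp_series",
    "decompose",
    "time_metrics",
    "peak_systole_wss",
    "hotspot_timecourse",
]

#: index pairs of the three independent off-diagonal tensor components
_OFFDIAG = [(0, 1), (0, 2), (1, 2)]


@dataclass
class WSSMetrics:
    """Per-wall-point time-dependency metrics over the systolic window."""

    awss: np.ndarray          # time-averaged |WSS|, Pa
    awssv: np.ndarray         # |time-averaged WSS vector|, Pa
    osi: np.ndarray           # 0.5·(1 − AWSSV/AWSS), in [0, 0.5]
    rrt: np.ndarray           # [(1 − 2·OSI)·AWSS]⁻¹, Pa⁻¹
    transwss: np.ndarray      # time-averaged transverse component, Pa
    osi_axial: np.ndarray
    osi_circ: np.ndarray


def velocity_gradient_sobel(vel_frame: np.ndarray, spacing) -> np.ndarray:
    """Velocity-gradient tensor ∂u_i/∂x_j by normalised 3×3×3 Sobel filters.

    ``vel_frame`` has shape (3, nx, ny, nz) in m/s, spacing in mm; the output
    gradients are in 1/s ((m/s)/m).  The derivative kernel [−1, 0, 1]/2 with
    [1, 2, 1]/4 smoothing on the transverse axes is exact for affine
    velocity fields.
    """
    spacing = np.asarray(spacing, float)
    grad = np.empty((3, 3) + vel_frame.shape[1:])
    for i in range(3):
        for j in range(3):
            d = ndimage.sobel(vel_frame[i], axis=j, mode="nearest")
            # sobel kernel weight: 2 (derivative) × 4 × 4 (smoothing) = 32
            grad[i, j] = d / (32.0 * spacing[j] * 1e-3)
    return grad


def strain_tensor_gv(vel_frame: np.ndarray, spacing,
                     mu: float = DEFAULT_VISCOSITY) -> np.ndarray:
    """Off-diagonal viscous shear tensor τ_ij = μ(∂u_i/∂x_j + ∂u_j/∂x_i).

    Returns shape (3, 3, nx, ny, nz) in Pa with an identically zero
    diagonal; the tensor is symmetric by construction.
    """
    grad = velocity_gradient_sobel(vel_frame, spacing)
    tau = np.zeros_like(grad)
    for i, j in _OFFDIAG:
        tau[i, j] = mu * (grad[i, j] + grad[j, i])
        tau[j, i] = tau[i, j]
    return tau


def _tangential_projection(traction: np.ndarray, x_r: np.ndarray) -> np.ndarray:
    """WSS = x'_r × (T × x'_r) = T − (T·x'_r)·x'_r (tangential part of T)."""
    return traction - (np.sum(traction * x_r, axis=-1, keepdims=True)) * x_r


def wss_gv(
    tau: np.ndarray,
    wall_points: np.ndarray,
    x_r: np.ndarray,
    spacing,
    origin=None,
    inward_offset_voxels: float = 1.0,
) -> np.ndarray:
    """GV wall shear stress vectors (Pa) at wall points, world frame.

    τ is interpolated trilinearly at each wall point offset
    ``inward_offset_voxels``·(mean spacing) along the inward radial
    direction.  Points falling outside the grid are dropped with a log
    message and return a zero vector.
    """
    spacing = np.asarray(spacing, float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    offset = inward_offset_voxels * float(spacing.mean())
    pts = np.asarray(wall_points, float) + offset * np.asarray(x_r, float)
    # world -> fractional index (voxel-centre convention)
    idx = (pts - origin) / spacing - 0.5
    shape = np.asarray(tau.shape[2:])
    outside = np.any((idx < 0) | (idx > shape - 1), axis=1)
    if outside.any():
        logger.warning("wss_gv: %d wall points fall outside the grid",
                       int(outside.sum()))
    coords = idx.T
    tau_at = np.zeros((len(pts), 3, 3))
    for i, j in _OFFDIAG:
        vals = ndimage.map_coordinates(tau[i, j], coords, order=1,
                                       mode="nearest")
        vals[outside] = 0.0
        tau_at[:, i, j] = vals
        tau_at[:, j, i] = vals
    traction = np.einsum("nij,nj->ni", tau_at, x_r)
    return _tangential_projection(traction, x_r)


def _wall_normal_derivatives(
    section: CrossSection,
    frame: int,
    fit_depths_voxels: tuple[float, float] = (0.5, 2.5),
) -> np.ndarray:
    """∂v'_c/∂n at each boundary point from the in-plane cubic interpolant.

    Samples the scattered-data cubic spline of each local velocity
    component along the inward radial ray at the upsampled-grid step, over
    depths of half to two and a half voxels, and least-squares fits
    ``v(d) ≈ c + a·d + b·d²``; the slope ``a`` evaluated at the wall is the
    wall-normal derivative in (m/s)/mm.  Fitting interior samples and
    extrapolating to the wall keeps the estimate unbiased for smooth
    (locally quadratic) profiles and insensitive to the sub-voxel
    uncertainty of the wall position; differentiating across the wall
    itself would mix in the zero-velocity exterior and bias the gradient
    low or high depending on the boundary placement.  Returns shape (B, 3).
    """
    step = section.upsample_step or section.dx / 4.0
    d0, d1 = fit_depths_voxels
    depths = np.arange(d0 * section.dx, d1 * section.dx + step / 2, step)
    design = np.stack([np.ones_like(depths), depths, depths**2], axis=-1)
    b_local = section.boundary_local
    nr_local = np.stack([section.x_r @ section.axes[:, 0],
                         section.x_r @ section.axes[:, 1]], axis=-1)
    nr_local /= np.linalg.norm(nr_local, axis=1, keepdims=True)
    interps = section.scattered_interpolators(frame)
    derivs = np.zeros((len(b_local), 3))
    n_short = 0
    for k in range(len(b_local)):
        px = b_local[k, 0] + nr_local[k, 0] * depths
        py = b_local[k, 1] + nr_local[k, 1] * depths
        for c in range(3):
            v = interps[c](px, py)
            ok = np.isfinite(v)
            if ok.sum() < 4:
                n_short += 1
                continue
            coef, *_ = np.linalg.lstsq(design[ok], v[ok], rcond=None)
            derivs[k, c] = coef[1]
    if n_short:
        logger.warning("wss_lp: %d component fits had too few interior "
                       "samples; derivative set to 0 there", n_short)
    return derivs


def wss_lp(
    section: CrossSection,
    frame: int,
    mu: float = DEFAULT_VISCOSITY,
    fit_depths_voxels: tuple[float, float] = (0.5, 2.5),
) -> np.ndarray:
    """LP wall shear stress vectors (Pa) at the section boundary, world frame.

    In-plane derivatives of the local velocity components are evaluated at
    the wall: because velocity vanishes identically along the wall curve
    (no slip), the in-plane gradient of each component reduces to its
    wall-normal derivative times the inward normal.  The off-diagonal shear
    tensor is assembled in the local frame with out-of-plane derivatives set
    to zero, then contracted with the radial direction and projected
    tangentially.
    """
    if section.boundary_local is None:
        raise ValueError("section boundary required for the LP method")
    dvdn = _wall_normal_derivatives(section, frame, fit_depths_voxels)  # (B,3)
    nr_local = np.stack([section.x_r @ section.axes[:, 0],
                         section.x_r @ section.axes[:, 1]], axis=-1)
    nr_local /= np.linalg.norm(nr_local, axis=1, keepdims=True)
    B = len(dvdn)
    # gradient of local component c w.r.t. in-plane axes: dvdn[:,c]·n_local
    # mm -> m so τ is in Pa
    g = dvdn[:, :, None] * nr_local[:, None, :] * 1e3   # (B, 3 comp, 2 axes)
    tau = np.zeros((B, 3, 3))
    tau[:, 0, 1] = mu * (g[:, 0, 1] + g[:, 1, 0])
    tau[:, 0, 2] = mu * g[:, 2, 0]          # ∂v'3/∂x'1 (+ ∂v'1/∂x'3 = 0)
    tau[:, 1, 2] = mu * g[:, 2, 1]
    tau[:, 1, 0] = tau[:, 0, 1]
    tau[:, 2, 0] = tau[:, 0, 2]
    tau[:, 2, 1] = tau[:, 1, 2]
    n3 = np.concatenate([nr_local, np.zeros((B, 1))], axis=1)   # radial, local
    traction = np.einsum("nij,nj->ni", tau, n3)
    wss_local = _tangential_projection(traction, n3)
    return wss_local @ section.axes.T        # back to world frame


def wss_lp_series(section: CrossSection, frames, mu: float = DEFAULT_VISCOSITY
                  ) -> np.ndarray:
    """LP vectors for several frames, shape (len(frames), B, 3)."""
    return np.stack([wss_lp(section, int(k), mu) for k in frames])


def decompose(
    wss_vectors: np.ndarray,
    x3: np.ndarray,
    x_t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axial and circumferential WSS components and angle from axial.

    The angle is arccos(WSS·x'3/|WSS|) in degrees: 0 = downstream axial,
    90 = circumferential, 180 = upstream axial.  Zero-magnitude vectors get
    a NaN angle (direction undefined).
    """
    axial = np.sum(wss_vectors * x3, axis=-1)
    circ = np.sum(wss_vectors * x_t, axis=-1)
    mag = np.linalg.norm(wss_vectors, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = np.degrees(np.arccos(np.clip(
            np.where(mag > 0, axial / np.where(mag > 0, mag, 1.0), np.nan),
            -1.0, 1.0)))
    return axial, circ, angle


def _scalar_osi(w: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Component oscillation index 0.5·(1 − |∫w dt| / ∫|w| dt)."""
    num = np.abs(np.trapezoid(w, t, axis=0))
    den = np.trapezoid(np.abs(w), t, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - num / den)
    osi[den == 0] = np.nan
    return osi


def time_metrics(
    wss_series: np.ndarray,
    frame_times: np.ndarray,
    t_es: int,
    normals: np.ndarray,
    x3: np.ndarray | None = None,
    x_t: np.ndarray | None = None,
) -> WSSMetrics:
    """Time-dependency metrics over the systolic window [first frame, T_Es].

    ``wss_series`` has shape (n_frames, B, 3) in Pa; integration is
    trapezoidal with the actual (possibly non-uniform) frame times.

    * AWSS  = (1/T)·∫|WSS| dt
    * AWSSV = (1/T)·|∫WSS dt|
    * OSI   = 0.5·(1 − AWSSV/AWSS), undefined (NaN) where AWSS = 0
    * RRT   = [(1 − 2·OSI)·AWSS]⁻¹, undefined where the mean vector vanishes
    * TransWSS = (1/T)·∫|WSS·(n × ē)| dt with ē the unit mean-WSS direction
    """
    w = np.asarray(wss_series, float)[:t_es + 1]
    t = np.asarray(frame_times, float)[:t_es + 1] / 1000.0
    if w.shape[0] < 2:
        raise ValueError("need >= 2 frames in the systolic window")
    duration = t[-1] - t[0]
    mag = np.linalg.norm(w, axis=-1)
    awss = np.trapezoid(mag, t, axis=0) / duration
    mean_vec = np.trapezoid(w, t, axis=0) / duration
    awssv = np.linalg.norm(mean_vec, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - awssv / awss)
        rrt = 1.0 / ((1.0 - 2.0 * osi) * awss)
    zero = awss == 0
    if np.any(zero):
        logger.info("time_metrics: %d wall points with AWSS = 0; OSI/RRT "
                    "undefined there", int(zero.sum()))
    osi = np.where(zero, np.nan, osi)
    rrt = np.where(np.isfinite(rrt), rrt, np.nan)
    # transverse direction n × ē in the wall tangent plane
    with np.errstate(invalid="ignore", divide="ignore"):
        e_mean = mean_vec / np.where(awssv > 0, awssv, 1.0)[..., None]
    trans_dir = np.cross(np.asarray(normals, float), e_mean)
    trans = np.abs(np.sum(w * trans_dir[None], axis=-1))
    transwss = np.trapezoid(trans, t, axis=0) / duration
    transwss = np.where(awssv > 0, transwss, np.nan)

    if x3 is not None and x_t is not None:
        axial = np.sum(w * x3, axis=-1)
        circ = np.sum(w * x_t, axis=-1)
        osi_ax = _scalar_osi(axial, t)
        osi_ci = _scalar_osi(circ, t)
    else:
        osi_ax = np.full(awss.shape, np.nan)
        osi_ci = np.full(awss.shape, np.nan)
    return WSSMetrics(awss=awss, awssv=awssv, osi=osi, rrt=rrt,
                      transwss=transwss, osi_axial=osi_ax, osi_circ=osi_ci)


def peak_systole_wss(wss_series: np.ndarray, t_ps: int) -> np.ndarray:
    """Mean |WSS| over three frames centred on peak systole (clipped)."""
    n = wss_series.shape[0]
    frames = np.unique(np.clip(np.arange(t_ps - 1, t_ps + 2), 0, n - 1))
    return np.linalg.norm(wss_series[frames], axis=-1).mean(axis=0)


def hotspot_timecourse(
    subject_curve: np.ndarray,
    subject_times: np.ndarray,
    cohort_curves: list[np.ndarray],
    cohort_times: list[np.ndarray],
    n_samples: int = 50,
) -> dict:
    """Subject time-course vs the cohort 10th–90th percentile band.

    All curves are resampled onto a common normalised systole [0, 1];
    percentiles are computed per timepoint.
    """
    if len(cohort_curves) < 2:
        raise ValueError("cohort must contain >= 2 subjects")
    tau = np.linspace(0.0, 1.0, n_samples)

    def _norm(t):
        t = np.asarray(t, float)
        return (t - t[0]) / (t[-1] - t[0])

    subject = np.interp(tau, _norm(subject_times), subject_curve)
    cohort = np.stack([np.interp(tau, _norm(tc), c)
                       for c, tc in zip(cohort_curves, cohort_times)])
    return {
        "time_normalized": tau,
        "subject": subject,
        "p10": np.percentile(cohort, 10, axis=0),
        "p90": np.percentile(cohort, 90, axis=0),
    }
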