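"""Step 3 of the pipeline: cross-sections, in-plane resampling, local frames.

Equally spaced points ``P_i`` are generated along the centerline (spacing
Δx equal to the mean voxel dimension).  Each defines a cutting plane normal
to the local tangent ``x'3``.  Voxels whose centre lies within 0.5·Δx of the
plane are projected onto it, their velocities rotated into the in-plane
frame ``(x'1, x'2, x'3)``, and the scattered values interpolated to a regular
in-plane grid at a quarter-voxel step.  The lumen boundary Γ_π comes from
the plane–surface intersection (sub-voxel wall placement); each boundary
point carries a wall frame: inward radial ``x'_r``, circumferential
``x'_t = x'_r × x'3``, and longitudinal ``x'3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import CloughTocher2DInterpolator

from .geometry import Centerline, LumenSurface, ROIMask
from .preprocess import VelocityField

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSection",
    "sample_planes",
    "local_frame",
    "gather_and_project",
    "wall_frames",
    "build_sections",
]

#: default anatomical anterior direction for phantoms (+y)
DEFAULT_ANTERIOR = np.array([0.0, 1.0, 0.0])


@dataclass
class CrossSection:
    """One cutting plane with gathered velocities and wall frames."""

    index: int
    center: np.ndarray                 # P_i, world mm
    axes: np.ndarray                   # (3, 3), columns x'1, x'2, x'3
    arc_s: float                       # centerline arc length of P_i, mm
    dx: float                          # plane spacing Δx, mm
    points_local: np.ndarray           # (N, 2) gathered C'_j in-plane coords
    velocities_local: np.ndarray       # (n_frames, N, 3) m/s, local frame
    n_gathered: int                    # N_i
    boundary_local: np.ndarray | None = None   # (B, 2), CCW, r=0 at start
    boundary_world: np.ndarray | None = None   # (B, 3)
    x_r: np.ndarray | None = None      # (B, 3) inward radial, world
    x_t: np.ndarray | None = None      # (B, 3) circumferential, world
    upsample_step: float | None = None
    _grid_cache: dict = field(default_factory=dict, repr=False)

    @property
    def x3(self) -> np.ndarray:
        return self.axes[:, 2]

    def to_local(self, points_world: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points_world) - self.center
        return rel @ self.axes[:, :2]

    def to_world(self, points_local: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_local)
        return self.center + p @ self.axes[:, :2].T

    def boundary_polygon(self) -> shapely.Polygon:
        if self.boundary_local is None:
            raise ValueError("boundary not computed for this section")
        return shapely.Polygon(self.boundary_local)

    def upsampled_grid(self, frame: int):
        """In-plane velocity grid for one frame (cached).

        Returns ``(gx, gy, values)`` with ``values`` of shape
        ``(3, len(gx), len(gy))`` in the local frame.  Scattered gathered
        points are interpolated with piecewise-cubic (Clough–Tocher)
        splines; the no-slip condition contributes zero-velocity samples on
        the wall boundary, and the field is prolonged by zero outside the
        lumen polygon.
        """
        if frame in self._grid_cache:
            return self._grid_cache[frame]
        if self.boundary_local is None:
            raise ValueError("boundary required before in-plane upsampling")
        step = self.upsample_step or self.dx / 4.0
        b = self.boundary_local
        lo = b.min(axis=0) - 2 * self.dx
        hi = b.max(axis=0) + 2 * self.dx
        gx = np.arange(lo[0], hi[0] + step / 2, step)
        gy = np.arange(lo[1], hi[1] + step / 2, step)
        GX, GY = np.meshgrid(gx, gy, indexing="ij")
        # densify the no-slip ring to the grid step
        ring = _resample_closed(b, max(len(b), int(np.ceil(
            _perimeter(b) / step))))
        pts = np.vstack([self.points_local, ring])
        poly = self.boundary_polygon()
        inside = shapely.contains_xy(poly, GX.ravel(), GY.ravel()) \
            .reshape(GX.shape)
        vals = np.zeros((3,) + GX.shape)
        for c in range(3):
            data = np.r_[self.velocities_local[frame, :, c],
                         np.zeros(len(ring))]
            interp = CloughTocher2DInterpolator(pts, data)
            v = interp(GX, GY)
            v[~inside] = 0.0
            v[np.isnan(v)] = 0.0
            vals[c] = v
        self._grid_cache[frame] = (gx, gy, vals)
        return self._grid_cache[frame]

    def scattered_interpolators(self, frame: int):
        """Clough–Tocher cubic interpolants of the three local velocity
        components over the gathered (scattered) points of one frame.

        These pass exactly through the measured samples and are free of the
        exterior zero prolongation, which makes them the right object to
        differentiate near the wall."""
        key = ("ct", frame)
        if key not in self._grid_cache:
            tri_data = np.ascontiguousarray(self.points_local)
            self._grid_cache[key] = [
                CloughTocher2DInterpolator(
                    tri_data, self.velocities_local[frame, :, c])
                for c in range(3)]
        return self._grid_cache[key]


def _perimeter(closed_pts: np.ndarray) -> float:
    d = np.diff(np.vstack([closed_pts, closed_pts[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points equally spaced in arc length,
    keeping the first point fixed."""
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    total = arc[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    return np.stack([np.interp(targets, arc, loop[:, d])
                     for d in range(pts.shape[1])], axis=-1)


def local_frame(x3: np.ndarray, anterior: np.ndarray = DEFAULT_ANTERIOR
                ) -> np.ndarray:
    """Orthonormal in-plane frame: x'1 along the projected anterior axis.

    ``x'1`` is the anterior direction projected into the plane and
    renormalised, ``x'2 = x'3 × x'1`` so the triad (x'1, x'2, x'3) is
    right-handed.  If the anterior axis is (nearly) parallel to the tangent
    an arbitrary perpendicular replaces it.
    """
    x3 = np.asarray(x3, float)
    x3 = x3 / np.linalg.norm(x3)
    a = np.asarray(anterior, float)
    x1 = a - np.dot(a, x3) * x3
    n = np.linalg.norm(x1)
    if n < 1e-6:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, x3)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x1 = ref - np.dot(ref, x3) * x3
        n = np.linalg.norm(x1)
    x1 = x1 / n
    x2 = np.cross(x3, x1)
    return np.stack([x1, x2, x3], axis=-1)


def sample_planes(
    centerline: Centerline,
    dx: float,
    s_start: float | None = None,
    s_end: float | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Equally spaced plane anchors ``(s_i, P_i, x'3_i)`` along the centerline.

    Points sit at arc-length multiples of Δx starting at the LVOT landmark
    (or the curve origin when no landmark is set).
    """
    if s_start is None:
        s_start = centerline.landmarks.get("LVOT", 0.0)
    if s_end is None:
        s_end = centerline.total_length
    if s_end - s_start <= dx:
        raise ValueError("centerline shorter than one plane spacing")
    s_values = s_start + dx * np.arange(int(np.floor((s_end - s_start) / dx)) + 1)
    planes = []
    for s in s_values:
        planes.append((float(s), centerline.at(s), centerline.tangent_at(s)))
    return planes


def gather_and_project(
    field_: VelocityField,
    roi: ROIMask,
    center: np.ndarray,
    x3: np.ndarray,
    arc_s: float = 0.0,
    index: int = 0,
    dx: float | None = None,
    anterior: np.ndarray = DEFAULT_ANTERIOR,
    upsample_factor: int = 4,
) -> CrossSection:
    """Gather in-mask voxels within 0.5·Δx of the plane and project them.

    Velocities are rotated into the local frame; voxels projecting onto
    (numerically) the same in-plane location are averaged.
    """
    dx = float(np.mean(field_.spacing)) if dx is None else dx
    axes = local_frame(x3, anterior)
    centers = roi.voxel_centers_world()[roi.mask]     # (M, 3)
    vel = field_.velocity[:, :, roi.mask]             # (T, 3, M)
    signed = (centers - center) @ axes[:, 2]
    keep = np.abs(signed) < 0.5 * dx                  # strict inequality
    n_i = int(keep.sum())
    if n_i < 4:
        raise ValueError(
            f"degenerate section {index}: only {n_i} voxels within "
            f"0.5·Δx of the plane")
    gathered = centers[keep]
    local_xy = (gathered - center) @ axes[:, :2]      # orthogonal projection
    v_local = np.einsum("tcm,ca->tma", vel[:, :, keep], axes)  # (T, N, 3)

    # average duplicates (same projected location from stacked voxels)
    key = np.round(local_xy / 1e-6).astype(np.int64)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    if np.any(counts > 1):
        n_unique = counts.size
        xy = np.zeros((n_unique, 2))
        np.add.at(xy, inverse, local_xy)
        xy /= counts[:, None]
        vl = np.zeros((v_local.shape[0], n_unique, 3))
        for t in range(v_local.shape[0]):
            np.add.at(vl[t], inverse, v_local[t])
        vl /= counts[None, :, None]
        local_xy, v_local = xy, vl

    return CrossSection(
        index=index,
        center=np.asarray(center, float),
        axes=axes,
        arc_s=float(arc_s),
        dx=dx,
        points_local=local_xy,
        velocities_local=v_local,
        n_gathered=n_i,
        upsample_step=dx / upsample_factor,
    )


def wall_frames(
    section: CrossSection,
    surface: LumenSurface,
    anterior: np.ndarray = DEFAULT_ANTERIOR,
    n_boundary: int = 72,
) -> CrossSection:
    """Boundary Γ_π from the plane–surface intersection, with wall frames.

    The boundary is ordered counterclockwise viewed along +x'3, starts at
    the most anterior point (r = 0 convention of the wall template), and is
    resampled to ``n_boundary`` points equally spaced in arc length.  At each
    point the inward surface normal is projected into the plane to give the
    radial direction ``x'_r``; the circumferential direction is
    ``x'_t = x'_r × x'3``.
    """
    path = surface.mesh.section(plane_origin=section.center,
                                plane_normal=section.axes[:, 2])
    if path is None:
        raise ValueError(f"plane of section {section.index} misses the surface")
    loops = path.discrete
    # choose the loop whose centroid is closest to the section centre
    centroids = [np.mean(lp, axis=0) for lp in loops]
    pick = int(np.argmin([np.linalg.norm(c - section.center)
                          for c in centroids]))
    loop = np.asarray(loops[pick])
    if np.allclose(loop[0], loop[-1]):
        loop = loop[:-1]
    local = section.to_local(loop)
    # counterclockwise viewed along +x'3 <=> positive shoelace area
    area2 = np.sum(local[:, 0] * np.roll(local[:, 1], -1)
                   - np.roll(local[:, 0], -1) * local[:, 1])
    if area2 < 0:
        local = local[::-1]
        loop = loop[::-1]
    local = _resample_closed(local, n_boundary)
    world = section.to_world(local)
    # r = 0 at the most anterior boundary point
    start = int(np.argmax(world @ np.asarray(anterior, float)))
    local = np.roll(local, -start, axis=0)
    world = np.roll(world, -start, axis=0)

    # The boundary curve lies both in the surface and in the plane, so the
    # surface normal is perpendicular to the curve tangent; its in-plane
    # projection is therefore (anti)parallel to the in-plane curve normal.
    # Differentiating the resampled boundary is much better conditioned than
    # querying normals of the coarse triangulation, so the inward radial is
    # built by rotating the curve tangent 90 degrees in-plane, signed toward
    # the section interior.
    x3 = section.axes[:, 2]
    ring = np.vstack([local[-1], local, local[0]])
    tang2 = ring[2:] - ring[:-2]
    tnorm = np.linalg.norm(tang2, axis=1)
    ok = tnorm > 1e-6
    if not ok.all():
        logger.warning("section %d: dropped %d boundary points with "
                       "degenerate tangents", section.index,
                       int((~ok).sum()))
        local, world = local[ok], world[ok]
        ring = np.vstack([local[-1], local, local[0]])
        tang2 = ring[2:] - ring[:-2]
        tnorm = np.linalg.norm(tang2, axis=1)
    tang2 /= tnorm[:, None]
    normal2 = np.stack([-tang2[:, 1], tang2[:, 0]], axis=-1)
    # sign toward the interior (centroid side)
    centroid = local.mean(axis=0)
    flip = np.sum(normal2 * (centroid - local), axis=1) < 0
    normal2[flip] *= -1.0
    x_r = normal2 @ section.axes[:, :2].T
    x_r /= np.linalg.norm(x_r, axis=1, keepdims=True)
    x_t = np.cross(x_r, x3)

    section.boundary_local = local
    section.boundary_world = world
    section.x_r = x_r
    section.x_t = x_t
    section._grid_cache.clear()
    return section


def build_sections(
    field_: VelocityField,
    roi: ROIMask,
    surface: LumenSurface,
    centerline: Centerline,
    dx: float | None = None,
    anterior: np.ndarray = DEFAULT_ANTERIOR,
    n_boundary: int = 72,
    upsample_factor: int = 4,
    s_start: float | None = None,
    s_end: float | None = None,
) -> list[CrossSection]:
    """Full step-3 chain: planes → gather/project → boundary and wall frames.

    Sections whose plane misses the lumen (too few gathered voxels or no
    surface intersection) are skipped with a log message; this happens at
    the very ends of the vessel.
    """
    dx = float(np.mean(field_.spacing)) if dx is None else dx
    sections = []
    for i, (s, p, t) in enumerate(sample_planes(centerline, dx,
                                                s_start=s_start, s_end=s_end)):
        try:
            sec = gather_and_project(field_, roi, p, t, arc_s=s, index=i,
                                     dx=dx, anterior=anterior,
                                     upsample_factor=upsample_factor)
            sec = wall_frames(sec, surface, anterior=anterior,
                              n_boundary=n_boundary)
        except ValueError as exc:
            logger.info("skipping section %d at s=%.1f mm: %s", i, s, exc)
            continue
        sections.append(sec)
    if not sections:
        raise ValueError("no valid cross-sections along the centerline")
    return sections
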