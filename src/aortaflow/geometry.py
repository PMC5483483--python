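"""Step 2 of the pipeline: lumen mask, wall surface, centerline, landmarks.

The lumen region of interest enters either as per-slice polygon tracings
(mirroring a manual segmentation) or as a programmatic binary mask.  From it
the module extracts a smoothed closed iso-surface of the vessel wall, a
skeleton ordered end-to-end by Dijkstra shortest path between the LVOT and
DeA landmark projections, and a dense smoothed spline centerline onto which
the remaining anatomical landmarks (PA, BrA) are projected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
import trimesh
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage import measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "ROIMask",
    "LumenSurface",
    "Centerline",
    "stack_masks",
    "extract_surface",
    "laplacian_smooth",
    "skeletonize_and_order",
    "fit_centerline",
    "project_landmark",
    "curvature_radius",
]

_CONN26 = np.ones((3, 3, 3), bool)


@dataclass
class ROIMask:
    """Binary lumen mask on the acquisition grid."""

    mask: np.ndarray              # (nx, ny, nz) bool
    spacing: np.ndarray           # (3,) mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: str = "programmatic"

    def voxel_centers_world(self) -> np.ndarray:
        from .phantom import voxel_centers
        return voxel_centers(self.mask.shape, self.spacing, self.origin)


@dataclass
class LumenSurface:
    """Closed triangulated vessel-wall surface in world coordinates (mm)."""

    mesh: trimesh.Trimesh

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def triangles(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward unit normals per vertex."""
        return np.asarray(self.mesh.vertex_normals)


@dataclass
class Centerline:
    """Ordered smoothed space curve with arc length and unit tangents."""

    points: np.ndarray            # (n, 3) mm
    arc_length: np.ndarray        # (n,) cumulative, mm, strictly increasing
    tangents: np.ndarray          # (n, 3) unit vectors
    landmarks: dict = field(default_factory=dict)   # name -> arc-length mm

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolated point(s) at arc length ``s``."""
        s = np.atleast_1d(np.asarray(s, float))
        pts = np.stack([np.interp(s, self.arc_length, self.points[:, d])
                        for d in range(3)], axis=-1)
        return pts[0] if pts.shape[0] == 1 else pts

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        t = np.stack([np.interp(s, self.arc_length, self.tangents[:, d])
                      for d in range(3)], axis=-1)
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        return t[0] if t.shape[0] == 1 else t

    def set_landmarks(self, points: dict) -> None:
        """Project named landmark points onto the curve (arc-length positions)."""
        for name, p in points.items():
            self.landmarks[name] = project_landmark(self, np.asarray(p, float))


def stack_masks(
    polygons: dict,
    grid_shape: tuple[int, int, int],
    spacing,
    origin=None,
    slice_axis: int = 2,
) -> ROIMask:
    """Merge per-slice polygon tracings into a 3D binary mask.

    ``polygons`` maps a slice index along ``slice_axis`` to an (N, 2) array of
    in-plane world coordinates (the two axes other than ``slice_axis``, in
    order).  A voxel is foreground iff its centre lies inside (or exactly on)
    the polygon of its slice.  The merged volume must form a single
    26-connected component.
    """
    if not polygons:
        raise ValueError("empty polygon list: no slices traced")
    spacing = np.asarray(spacing, float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    in_plane = [d for d in range(3) if d != slice_axis]
    mask = np.zeros(grid_shape, bool)
    ax_u = origin[in_plane[0]] + (np.arange(grid_shape[in_plane[0]]) + 0.5) \
        * spacing[in_plane[0]]
    ax_v = origin[in_plane[1]] + (np.arange(grid_shape[in_plane[1]]) + 0.5) \
        * spacing[in_plane[1]]
    U, V = np.meshgrid(ax_u, ax_v, indexing="ij")
    pts = shapely.points(U.ravel(), V.ravel())
    for k, poly_xy in polygons.items():
        poly = shapely.Polygon(np.asarray(poly_xy, float))
        if not poly.is_valid:
            raise ValueError(f"polygon on slice {k} is not simple")
        # covers: closed containment, points on the edge count as inside
        inside = shapely.covers(poly, pts).reshape(U.shape)
        sl = [slice(None)] * 3
        sl[slice_axis] = k
        mask[tuple(sl)] = inside
    labels, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValueError(
            f"merged mask is disconnected: {n_comp} components with voxel "
            f"counts {sorted(sizes.tolist(), reverse=True)}")
    return ROIMask(mask=mask, spacing=spacing, origin=origin,
                   provenance="polygon tracings")


def laplacian_smooth(mesh: trimesh.Trimesh, n_iter: int = 20,
                     relaxation: float = 0.1) -> trimesh.Trimesh:
    """Umbrella-operator Laplacian smoothing; vertex count is preserved."""
    if n_iter == 0:
        return mesh.copy()
    verts = mesh.vertices.copy()
    n = len(verts)
    edges = mesh.edges_unique
    # sparse averaging of 1-ring neighbours
    from scipy.sparse import coo_matrix
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1
    for _ in range(n_iter):
        mean_neighbor = adj @ verts / degree[:, None]
        verts += relaxation * (mean_neighbor - verts)
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    return out


def extract_surface(roi: ROIMask, n_iter: int = 20,
                    relaxation: float = 0.1) -> LumenSurface:
    """Iso-surface of the binary mask at level 0.5, Laplacian smoothed.

    The volume is zero-padded before marching cubes so the surface is always
    closed; an open surface after extraction is an error.
    """
    padded = np.pad(roi.mask.astype(np.float32), 1)
    verts_idx, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # padded index -> world (voxel-centre convention)
    verts = roi.origin + (verts_idx - 1.0 + 0.5) * roi.spacing
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not mesh.is_watertight:
        raise ValueError("extracted iso-surface is not closed")
    if mesh.volume < 0:
        mesh.invert()
    smoothed = laplacian_smooth(mesh, n_iter=n_iter, relaxation=relaxation)
    if smoothed.volume < 0:
        smoothed.invert()
    return LumenSurface(mesh=smoothed)


def skeletonize_and_order(
    roi: ROIMask,
    lvot: np.ndarray,
    dea: np.ndarray,
) -> np.ndarray:
    """3D thinning skeleton ordered end-to-end by Dijkstra shortest path.

    The skeleton voxels form a graph under 26-connectivity with Euclidean
    edge weights (mm); the returned ordered world points are the shortest
    path from the skeleton voxel nearest the LVOT landmark to the one
    nearest DeA.
    """
    skel = morphology.skeletonize(roi.mask)
    if not skel.any():
        # thinning can annihilate objects of perfectly even width; fall back
        # to the distance-transform ridge (voxels locally maximizing the
        # Euclidean depth), which serves the same purpose
        logger.warning("3D thinning returned an empty skeleton; falling back "
                       "to the distance-transform ridge")
        edt = ndimage.distance_transform_edt(roi.mask,
                                             sampling=roi.spacing)
        local_max = ndimage.maximum_filter(edt, size=3)
        skel = roi.mask & (edt >= local_max - 1e-9)
    idx = np.argwhere(skel)
    if len(idx) == 0:
        raise ValueError("skeletonization produced no voxels")
    world = roi.origin + (idx + 0.5) * roi.spacing
    # graph over skeleton voxels, 26-connectivity
    voxel_id = {tuple(v): i for i, v in enumerate(map(tuple, idx))}
    graph = nx.Graph()
    graph.add_nodes_from(range(len(idx)))
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
    for i, v in enumerate(idx):
        for off in offsets:
            nb = tuple(v + off)
            j = voxel_id.get(nb)
            if j is not None and j > i:
                w = float(np.linalg.norm(off * roi.spacing))
                graph.add_edge(i, j, weight=w)
    start = int(np.argmin(np.linalg.norm(world - np.asarray(lvot), axis=1)))
    end = int(np.argmin(np.linalg.norm(world - np.asarray(dea), axis=1)))
    try:
        path = nx.dijkstra_path(graph, start, end)
    except nx.NetworkXNoPath as exc:
        raise ValueError("no skeleton path between LVOT and DeA "
                         "projections") from exc
    return world[path]


def _moving_average(arr: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average on each coordinate.

    The window shrinks symmetrically near the curve ends (1-, 3-, then
    5-point) so the endpoints are preserved and the curve is not shortened.
    """
    half = window // 2
    out = arr.copy()
    csum = np.cumsum(np.vstack([np.zeros(3), arr]), axis=0)
    n = len(arr)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def fit_centerline(
    ordered_points: np.ndarray,
    voxel_size: float = 1.6,
    smoothing_window: int = 5,
) -> Centerline:
    """Cubic-spline centerline through ordered skeleton points.

    An interpolating cubic spline (chord-length parametrised) is resampled
    densely at a quarter-voxel step and smoothed with a centred 5-point
    moving average on each coordinate; tangents come from central
    differences, renormalised to unit length.
    """
    pts = np.asarray(ordered_points, float)
    # deduplicate consecutive points
    keep = np.ones(len(pts), bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    if not keep.all():
        logger.info("fit_centerline: dropped %d duplicate consecutive points",
                    int((~keep).sum()))
    pts = pts[keep]
    if len(pts) < 6:
        raise ValueError(f"need >= 6 unique ordered points, got {len(pts)}")
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    spline = CubicSpline(chord, pts, axis=0)
    step = 0.25 * voxel_size
    u = np.arange(0.0, chord[-1], step)
    u = np.r_[u, chord[-1]]            # end exactly at the last point
    dense = spline(u)
    dense = _moving_average(dense, smoothing_window)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    # collapse numerically coincident samples produced by smoothing
    keep = np.r_[True, seg > 1e-12]
    dense = dense[keep]
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    tangents = np.gradient(dense, arc, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return Centerline(points=dense, arc_length=arc, tangents=tangents)


def _fit_circle_radius(pts: np.ndarray) -> float:
    """Radius of the least-squares circle through 3D points.

    The points are projected onto their best-fit plane (SVD) and an
    algebraic (Kåsa) circle fit is solved in that plane.
    """
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    xy = (pts - c) @ vt[:2].T
    design = np.c_[2 * xy, np.ones(len(xy))]
    rhs = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return float(np.sqrt(sol[2] + sol[0]**2 + sol[1]**2))


def curvature_radius(centerline: Centerline,
                     window_mm: float | None = 60.0) -> np.ndarray:
    """Radius of curvature along the centerline by windowed circle fits.

    Pointwise differentiation of a voxel-derived curve amplifies skeleton
    quantization noise, so curvature is measured on arc-length windows
    (default 60 mm, clamped to the curve length) with a least-squares
    circle fit; ``window_mm=None`` fits one circle to the whole curve.
    Returns one radius per window (a single value when global).
    """
    arc = centerline.arc_length
    if window_mm is None or window_mm >= arc[-1]:
        return np.array([_fit_circle_radius(centerline.points)])
    radii = []
    for s0 in np.arange(0.0, arc[-1] - window_mm + 1e-9, window_mm / 8.0):
        sel = (arc >= s0) & (arc <= s0 + window_mm)
        radii.append(_fit_circle_radius(centerline.points[sel]))
    return np.asarray(radii)


def project_landmark(centerline: Centerline, point: np.ndarray) -> float:
    """Arc-length of the centerline sample closest to ``point``.

    Ties are broken toward smaller arc length (argmin returns the first
    minimiser of the strictly increasing arc-length ordering).
    """
    d = np.linalg.norm(centerline.points - np.asarray(point, float), axis=1)
    return float(centerline.arc_length[int(np.argmin(d))])
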