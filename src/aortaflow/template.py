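"""Normalized 2D aortic-wall template, cohort percentile maps, classes.

Wall quantities on the ascending aorta (LVOT → BrA) are flattened onto a
normalized rectangle: longitudinal coordinate ``s`` (0 at LVOT, 1 at BrA)
along the centerline, circumferential coordinate ``r`` (0 at the most
anterior boundary point of the local cross-section, increasing
counterclockwise).  The template is rasterized to 64 × 72 cells, partitioned
into 8 anatomical sectors (proximal/distal × Antero/Left/Posterior/Right),
and compared across subjects via per-cell percentiles of a healthy cohort
and a four-class percentile-relative classification.  A small follow-up
utility converts a diameter change into a growth rate against the
0.5 mm/year guideline threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sections import CrossSection

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateMap",
    "RelativeClassMap",
    "SECTOR_NAMES",
    "template_coordinates",
    "rasterize",
    "sector_partition",
    "group_percentiles",
    "relative_classify",
    "exceedance",
    "growth_rate",
]

N_S_BINS = 64
N_R_BINS = 72   # divisible by 8 so sector boundaries fall on cell edges

#: circumferential quarters centred on the orientation points, CCW from
#: anterior: A at r=0, then L, P, R
_CIRC_ORDER = ["A", "L", "P", "R"]
SECTOR_NAMES = [f"{lon}-{c}" for lon in ("proximal", "distal")
                for c in _CIRC_ORDER]


@dataclass
class TemplateMap:
    """Scalar field on the normalized (s, r) wall template."""

    values: np.ndarray                 # (n_s, n_r), NaN = missing
    s_pa: float                        # landmark line, normalized
    n_s: int = N_S_BINS
    n_r: int = N_R_BINS
    cell_weights: np.ndarray | None = None   # local wall area per cell, mm²

    @property
    def s_centers(self) -> np.ndarray:
        return (np.arange(self.n_s) + 0.5) / self.n_s

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) / self.n_r


@dataclass
class RelativeClassMap:
    """Per-cell percentile class relative to a healthy cohort."""

    classes: np.ndarray                # (n_s, n_r) of {0..3}, -1 = missing
    fractions: dict = field(default_factory=dict)   # class name -> area frac

    CLASS_NAMES = ("below_p10", "p10_to_p50", "p50_to_p90", "above_p90")


def template_coordinates(
    sections: list[CrossSection],
    s_lvot: float,
    s_bra: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s, r) coordinates of every section boundary point in [LVOT, BrA].

    Returns ``(s, r, point_index)`` where ``point_index`` is (section index
    in the list, boundary index), usable to look up wall values.  Sections
    outside the tract are excluded with a log message.  ``r`` follows the
    boundary ordering convention (starts at the most anterior point,
    counterclockwise), so it is simply the normalized boundary index.
    """
    if not s_lvot < s_bra:
        raise ValueError("landmarks must satisfy s(LVOT) < s(BrA)")
    s_list, r_list, idx_list = [], [], []
    n_excluded = 0
    for si, sec in enumerate(sections):
        if sec.boundary_local is None:
            continue
        s_norm = (sec.arc_s - s_lvot) / (s_bra - s_lvot)
        if s_norm < -1e-9 or s_norm > 1.0 + 1e-9:
            n_excluded += 1
            continue
        s_norm = float(np.clip(s_norm, 0.0, 1.0))
        b = len(sec.boundary_local)
        r = np.arange(b) / b
        s_list.append(np.full(b, s_norm))
        r_list.append(r)
        idx_list.append(np.stack([np.full(b, si), np.arange(b)], axis=-1))
    if n_excluded:
        logger.info("template: excluded %d sections outside [LVOT, BrA]",
                    n_excluded)
    if not s_list:
        raise ValueError("no sections fall inside the LVOT-BrA tract")
    return (np.concatenate(s_list), np.concatenate(r_list),
            np.concatenate(idx_list))


def _fill_nearest(values: np.ndarray, max_dist: float = 2.0) -> np.ndarray:
    """Fill empty cells from the nearest occupied cell within ``max_dist``
    cells (circumferential axis wraps); farther cells stay missing."""
    from scipy import ndimage
    missing = np.isnan(values)
    if not missing.any():
        return values
    # pad circumferentially to honour the wrap in the distance transform
    n_r = values.shape[1]
    wrapped = np.concatenate([values, values, values], axis=1)
    miss_w = np.isnan(wrapped)
    dist, (ii, jj) = ndimage.distance_transform_edt(miss_w,
                                                    return_indices=True)
    filled = wrapped[ii, jj]
    filled[dist > max_dist] = np.nan
    return filled[:, n_r:2 * n_r]


def rasterize(
    s: np.ndarray,
    r: np.ndarray,
    values: np.ndarray,
    s_pa: float,
    n_s: int = N_S_BINS,
    n_r: int = N_R_BINS,
    cell_weights: np.ndarray | None = None,
) -> TemplateMap:
    """Bin wall-point values to the template grid (cell mean).

    Empty cells are filled by nearest-neighbour within 2 cells; cells
    farther from any datum remain missing (NaN), never silently zero.
    """
    s = np.asarray(s, float)
    r = np.asarray(r, float)
    values = np.asarray(values, float)
    i = np.clip((s * n_s).astype(int), 0, n_s - 1)
    j = np.clip((r * n_r).astype(int), 0, n_r - 1)
    acc = np.zeros((n_s, n_r))
    cnt = np.zeros((n_s, n_r))
    ok = np.isfinite(values)
    np.add.at(acc, (i[ok], j[ok]), values[ok])
    np.add.at(cnt, (i[ok], j[ok]), 1.0)
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    grid = _fill_nearest(grid)
    return TemplateMap(values=grid, s_pa=float(s_pa), n_s=n_s, n_r=n_r,
                       cell_weights=cell_weights)


def section_cell_weights(
    sections: list[CrossSection],
    s_lvot: float,
    s_bra: float,
    n_s: int = N_S_BINS,
    n_r: int = N_R_BINS,
) -> np.ndarray:
    """Per-cell wall area (mm²) from local circumference × Δs arc length."""
    from .bulkflow import area_and_diameter
    s_centers = (np.arange(n_s) + 0.5) / n_s
    circum = np.full(n_s, np.nan)
    sec_s, sec_c = [], []
    for sec in sections:
        if sec.boundary_local is None:
            continue
        s_norm = (sec.arc_s - s_lvot) / (s_bra - s_lvot)
        if not 0.0 <= s_norm <= 1.0:
            continue
        _, d = area_and_diameter(sec)
        sec_s.append(s_norm)
        sec_c.append(np.pi * d)
    if not sec_s:
        raise ValueError("no sections inside the tract")
    order = np.argsort(sec_s)
    circum = np.interp(s_centers, np.asarray(sec_s)[order],
                       np.asarray(sec_c)[order])
    ds = (s_bra - s_lvot) / n_s
    return np.repeat((circum * ds / n_r)[:, None], n_r, axis=1)


def sector_partition(
    s_pa: float,
    n_s: int = N_S_BINS,
    n_r: int = N_R_BINS,
) -> np.ndarray:
    """Label every template cell with one of the 8 anatomical sectors.

    Longitudinal split at the PA landmark line (proximal [0, s_PA), distal
    [s_PA, 1]); circumferential quarters are centred on the orientation
    points (A at r = 0, then counterclockwise L, P, R) with boundaries at
    r = 1/8, 3/8, 5/8, 7/8.
    """
    if not 0.0 < s_pa < 1.0:
        raise ValueError("s_PA must lie strictly inside (0, 1)")
    s = (np.arange(n_s) + 0.5) / n_s
    r = (np.arange(n_r) + 0.5) / n_r
    lon = np.where(s < s_pa, "proximal", "distal")
    quarter = (np.floor((r + 1.0 / 8.0) * 4) % 4).astype(int)
    circ = np.array(_CIRC_ORDER)[quarter]
    labels = np.char.add(np.char.add(lon[:, None], "-"), circ[None, :])
    return labels


def group_percentiles(
    maps: list[TemplateMap],
    min_count: int = 3,
) -> tuple[TemplateMap, TemplateMap, TemplateMap]:
    """Per-cell 10th/50th/90th percentile maps across a cohort.

    Percentiles use linear interpolation.  Cells present in fewer than
    ``min_count`` subjects are flagged missing.
    """
    if len(maps) < min_count:
        raise ValueError(f"need >= {min_count} cohort subjects")
    stack = np.stack([m.values for m in maps])
    counts = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        p10, p50, p90 = (np.nanpercentile(stack, q, axis=0,
                                          method="linear")
                         for q in (10, 50, 90))
    low = counts < min_count
    if low.any():
        logger.info("group_percentiles: %d cells present in fewer than %d "
                    "subjects; flagged missing", int(low.sum()), min_count)
    for arr in (p10, p50, p90):
        arr[low] = np.nan
    ref = maps[0]
    make = lambda a: TemplateMap(values=a, s_pa=ref.s_pa, n_s=ref.n_s,
                                 n_r=ref.n_r, cell_weights=ref.cell_weights)
    return make(p10), make(p50), make(p90)


def relative_classify(
    subject: TemplateMap,
    p10: TemplateMap,
    p50: TemplateMap,
    p90: TemplateMap,
) -> RelativeClassMap:
    """Four-class percentile-relative classification with area fractions.

    Strictly above the 90th percentile → ``above_p90``; strictly below the
    10th → ``below_p10``; otherwise the 50th percentile splits the two
    middle classes (≤ p50 → ``p10_to_p50``).  Area fractions weight cells by
    local wall area when available, else uniformly.
    """
    v = subject.values
    classes = np.full(v.shape, -1, int)
    valid = np.isfinite(v) & np.isfinite(p10.values) \
        & np.isfinite(p50.values) & np.isfinite(p90.values)
    classes[valid & (v > p90.values)] = 3
    classes[valid & (v < p10.values)] = 0
    mid = valid & (classes == -1)
    classes[mid & (v <= p50.values)] = 1
    classes[mid & (v > p50.values)] = 2
    weights = subject.cell_weights
    if weights is None:
        weights = np.ones_like(v)
    total = weights[classes >= 0].sum()
    fractions = {}
    for ci, name in enumerate(RelativeClassMap.CLASS_NAMES):
        fractions[name] = float(weights[classes == ci].sum() / total) \
            if total > 0 else np.nan
    return RelativeClassMap(classes=classes, fractions=fractions)


def exceedance(subject: TemplateMap, p90: TemplateMap) -> float:
    """Maximum percent excess over the cohort 90th percentile.

    max over cells of 100·(value − p90)/p90 restricted to cells where the
    subject exceeds p90; 0 when no cell does.  Cells with non-positive p90
    are skipped with a log message.
    """
    v = subject.values
    p = p90.values
    valid = np.isfinite(v) & np.isfinite(p)
    bad = valid & (p <= 0)
    if bad.any():
        logger.info("exceedance: skipped %d cells with non-positive p90",
                    int(bad.sum()))
    valid &= p > 0
    over = valid & (v > p)
    if not over.any():
        return 0.0
    return float(np.max(100.0 * (v[over] - p[over]) / p[over]))


def growth_rate(
    d_baseline_mm: float,
    d_followup_mm: float,
    years: float,
    threshold_mm_per_year: float = 0.5,
) -> tuple[float, bool]:
    """Aortic diameter growth rate (mm/year) and guideline-threshold flag.

    The flag is raised for rates strictly above the 0.5 mm/year guideline
    threshold for disease progression.
    """
    if years <= 0:
        raise ValueError("follow-up interval must be positive")
    rate = (d_followup_mm - d_baseline_mm) / years
    return rate, rate > threshold_mm_per_year
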