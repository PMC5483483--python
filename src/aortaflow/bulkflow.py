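"""Step 4 of the pipeline: bulk-flow quantification per cross-section.

Computes lumen area and equivalent diameter, the net flow-rate waveform
Q_i(t) = (A_i/N_i)·Σ v'3, the systolic timing frames (peak systole T_Ps, end
systole T_Es, mid-deceleration T_dec), stroke volume, velocity statistics,
flow jet angle, normalized flow displacement, per-tract summaries over the
LVOT–PA and PA–BrA tracts, and the Mann–Whitney group comparison.

Units follow clinical reporting: areas mm², diameters mm, flow ml/s
(peak flow l/min), stroke volume ml, velocities cm/s, angles degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sections import CrossSection

logger = logging.getLogger(__name__)

__all__ = [
    "FlowWaveform",
    "SectionStats",
    "area_and_diameter",
    "flow_rate",
    "flow_waveform",
    "detect_timings",
    "stroke_volume",
    "velocity_stats",
    "jet_angle",
    "flow_displacement",
    "section_stats",
    "tract_summary",
    "compare_groups",
]


@dataclass
class FlowWaveform:
    """Flow-rate waveform of one section plus derived systolic timings."""

    q: np.ndarray                # (n_frames,) ml/s
    frame_times: np.ndarray      # (n_frames,) ms
    t_ps: int                    # peak-systole frame (0-based)
    t_es: int                    # end-systole frame
    t_dec: int                   # mid-deceleration frame
    q_max_lpm: float             # peak flow, l/min
    sv_ml: float                 # stroke volume, ml/beat


@dataclass
class SectionStats:
    """Per-section bulk-flow statistics around peak systole."""

    index: int
    arc_s: float                 # mm
    area_mm2: float
    diameter_mm: float
    v_max_cms: float
    v_mean_cms: float
    jet_angle_deg: float
    flow_displacement: float


def _polygon_area(boundary: np.ndarray) -> float:
    """Shoelace area of a closed piecewise-linear polygon (absolute value)."""
    x, y = boundary[:, 0], boundary[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _self_intersects(boundary: np.ndarray) -> bool:
    import shapely
    ring = shapely.LinearRing(boundary)
    return not ring.is_simple


def area_and_diameter(section: CrossSection) -> tuple[float, float]:
    """Polygon area A_i (mm²) and equivalent diameter D_i = 2·√(A_i/π) (mm)."""
    if section.boundary_local is None or len(section.boundary_local) < 3:
        raise ValueError("section boundary with >= 3 points required")
    if _self_intersects(section.boundary_local):
        raise ValueError(f"section {section.index}: boundary polygon "
                         "self-intersects")
    area = _polygon_area(section.boundary_local)
    return area, 2.0 * np.sqrt(area / np.pi)


def flow_rate(section: CrossSection) -> np.ndarray:
    """Q_i(t_k) = (A_i / N_i) · Σ_j v'3_j(t_k), in ml/s.

    With area in mm² and velocity in m/s the product is numerically ml/s
    (1 mm²·m/s = 1 cm³/s).
    """
    area, _ = area_and_diameter(section)
    mean_axial = section.velocities_local[:, :, 2].mean(axis=1)   # m/s
    return area * mean_axial


def detect_timings(q: np.ndarray) -> tuple[int, int, int]:
    """Peak systole, end systole and mid-deceleration frames from Q(t).

    T_Ps is the (first) maximum of Q; T_Es is the last frame of the maximal
    strictly descending run starting at T_Ps; T_dec is the floor midpoint.
    """
    q = np.asarray(q, float)
    if q.size < 3:
        raise ValueError("need >= 3 frames to detect systolic timings")
    t_ps = int(np.argmax(q))
    if t_ps == q.size - 1 or np.all(np.diff(q) >= 0):
        raise ValueError("flow waveform has no descending (systolic decay) "
                         "phase")
    # a flat plateau at the maximum belongs to the peak, not the descent
    start = t_ps
    while start + 1 < q.size and q[start + 1] == q[start]:
        start += 1
    if start == q.size - 1:
        raise ValueError("flow waveform has no descending phase after its "
                         "maximum")
    t_es = q.size - 1
    for k in range(start, q.size - 1):
        if q[k + 1] >= q[k]:
            t_es = k
            break
    t_dec = (t_ps + t_es) // 2
    return t_ps, t_es, t_dec


def stroke_volume(q: np.ndarray, frame_times: np.ndarray, t_es: int) -> float:
    """Trapezoidal integral of Q (ml/s) from the first frame to T_Es, in ml."""
    q = np.asarray(q, float)
    t = np.asarray(frame_times, float) / 1000.0       # ms -> s
    if q.size < 2 or t_es < 1:
        raise ValueError("stroke volume needs at least two frames up to T_Es")
    return float(np.trapezoid(q[:t_es + 1], t[:t_es + 1]))


def flow_waveform(section: CrossSection,
                  frame_times: np.ndarray) -> FlowWaveform:
    """Q_i(t) with systolic timings, peak flow (l/min) and stroke volume."""
    q = flow_rate(section)
    t_ps, t_es, t_dec = detect_timings(q)
    return FlowWaveform(
        q=q,
        frame_times=np.asarray(frame_times, float),
        t_ps=t_ps,
        t_es=t_es,
        t_dec=t_dec,
        q_max_lpm=float(q.max()) * 60.0 / 1000.0,
        sv_ml=stroke_volume(q, frame_times, t_es),
    )


def _window3(t_ps: int, n_frames: int) -> np.ndarray:
    """Three consecutive frames centred on T_Ps, clipped at the ends."""
    frames = np.arange(t_ps - 1, t_ps + 2)
    clipped = np.clip(frames, 0, n_frames - 1)
    if not np.array_equal(frames, clipped):
        logger.warning("3-frame window clipped at sequence boundary "
                       "(T_Ps=%d, n_frames=%d)", t_ps, n_frames)
    return np.unique(clipped)


def velocity_stats(section: CrossSection, t_ps: int) -> tuple[float, float]:
    """Peak and mean in-section speed (cm/s) averaged over T_Ps ± 1."""
    frames = _window3(t_ps, section.velocities_local.shape[0])
    speeds = np.linalg.norm(section.velocities_local[frames], axis=2)
    return (float(speeds.max(axis=1).mean()) * 100.0,
            float(speeds.mean(axis=1).mean()) * 100.0)


def jet_angle(section: CrossSection, frame: int) -> float:
    """Angle (degrees) between the mean positive-v'3 velocity vector and x'3."""
    v = section.velocities_local[frame]
    pos = v[:, 2] > 0
    if not np.any(pos):
        raise ValueError(f"section {section.index}: no positive axial flow")
    mean_v = v[pos].mean(axis=0)
    cosang = mean_v[2] / np.linalg.norm(mean_v)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def flow_displacement(section: CrossSection, frame: int) -> float:
    """Distance between the centre of velocity and the lumen centre P_i,
    normalised by the equivalent diameter."""
    v = section.velocities_local[frame]
    pos = v[:, 2] > 0
    if not np.any(pos):
        raise ValueError(f"section {section.index}: no positive axial flow")
    w = v[pos, 2]
    center_vel = (w[:, None] * section.points_local[pos]).sum(axis=0) / w.sum()
    _, d = area_and_diameter(section)
    return float(np.linalg.norm(center_vel) / d)


def _mean_window(fn, section, frames) -> float:
    return float(np.mean([fn(section, int(k)) for k in frames]))


def section_stats(section: CrossSection, t_ps: int) -> SectionStats:
    """All per-section statistics, 3-frame averaged around peak systole."""
    area, diam = area_and_diameter(section)
    vmax, vmean = velocity_stats(section, t_ps)
    frames = _window3(t_ps, section.velocities_local.shape[0])
    return SectionStats(
        index=section.index,
        arc_s=section.arc_s,
        area_mm2=area,
        diameter_mm=diam,
        v_max_cms=vmax,
        v_mean_cms=vmean,
        jet_angle_deg=_mean_window(jet_angle, section, frames),
        flow_displacement=_mean_window(flow_displacement, section, frames),
    )


def tract_summary(
    stats: list[SectionStats],
    landmarks: dict,
) -> pd.DataFrame:
    """Per-tract reductions between LVOT–PA and PA–BrA landmarks.

    Tracts are half-open in arc length, [s_start, s_end).  Reported values
    mirror the clinical table: peak diameter and peak |V|max, mean of
    |V|mean, jet angle and flow displacement.
    """
    tracts = {
        "LVOT-PA": (landmarks["LVOT"], landmarks["PA"]),
        "PA-BrA": (landmarks["PA"], landmarks["BrA"]),
    }
    rows = []
    for name, (s0, s1) in tracts.items():
        sel = [st for st in stats if s0 <= st.arc_s < s1]
        if not sel:
            raise ValueError(f"tract {name} contains no sections")
        rows.append({
            "tract": name,
            "D_max_mm": max(st.diameter_mm for st in sel),
            "V_max_cms": max(st.v_max_cms for st in sel),
            "V_mean_cms": float(np.mean([st.v_mean_cms for st in sel])),
            "jet_angle_deg": float(np.mean([st.jet_angle_deg for st in sel])),
            "flow_displacement": float(np.mean([st.flow_displacement
                                                for st in sel])),
            "n_sections": len(sel),
        })
    return pd.DataFrame(rows).set_index("tract")


def compare_groups(values_a, values_b, alpha: float = 0.05
                   ) -> tuple[float, bool]:
    """Two-sided Mann–Whitney U test; returns (p-value, significant flag)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        logger.info("compare_groups: all observations tied; p = 1")
        return 1.0, False
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(min(res.pvalue, 1.0))
    return p, p < alpha
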