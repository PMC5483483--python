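"""Bulk-flow quantities: area, flow rate, timings, jet metrics, statistics."""

import numpy as np
import pytest

from aortaflow import bulkflow
from aortaflow.bulkflow import (
    area_and_diameter,
    compare_groups,
    detect_timings,
    flow_displacement,
    flow_rate,
    jet_angle,
    section_stats,
    stroke_volume,
    tract_summary,
    velocity_stats,
)
from aortaflow.phantom import PhantomSpec, make_phantom
from aortaflow.preprocess import VelocityField
from aortaflow.sections import CrossSection
from aortaflow import geometry, sections as sections_mod


def _synthetic_section(points, velocities, boundary, index=0, arc_s=0.0):
    """CrossSection with hand-set in-plane data (axes = identity)."""
    velocities = np.asarray(velocities, float)
    if velocities.ndim == 2:
        velocities = velocities[None]
    return CrossSection(
        index=index, center=np.zeros(3), axes=np.eye(3), arc_s=arc_s,
        dx=1.6, points_local=np.asarray(points, float),
        velocities_local=velocities,
        n_gathered=len(points), boundary_local=np.asarray(boundary, float))


def _disc_section(radius=10.0, v_axial=1.0, n_boundary=90):
    th = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    boundary = radius * np.stack([np.cos(th), np.sin(th)], axis=-1)
    g = np.arange(-radius, radius + 0.1, 1.6)
    X, Y = np.meshgrid(g, g, indexing="ij")
    keep = np.hypot(X, Y) < radius
    pts = np.c_[X[keep], Y[keep]]
    v = np.zeros((len(pts), 3))
    v[:, 2] = v_axial
    return _synthetic_section(pts, v, boundary), pts


class TestAreaDiameter:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        sec = _synthetic_section(np.zeros((4, 2)), np.zeros((4, 3)), square)
        a, d = area_and_diameter(sec)
        assert a == pytest.approx(1.0)
        assert d == pytest.approx(2 / np.sqrt(np.pi))

    def test_fine_polygon_approximates_circle(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        boundary = 12.0 * np.stack([np.cos(th), np.sin(th)], axis=-1)
        sec = _synthetic_section(np.zeros((4, 2)), np.zeros((4, 3)), boundary)
        a, d = area_and_diameter(sec)
        assert a == pytest.approx(np.pi * 144, rel=1e-3)
        assert d == pytest.approx(24.0, rel=1e-3)

    def test_orientation_independent(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        boundary = 5.0 * np.stack([np.cos(th), np.sin(th)], axis=-1)
        fwd = _synthetic_section(np.zeros((4, 2)), np.zeros((4, 3)), boundary)
        rev = _synthetic_section(np.zeros((4, 2)), np.zeros((4, 3)),
                                 boundary[::-1])
        assert area_and_diameter(fwd)[0] == pytest.approx(
            area_and_diameter(rev)[0])

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        sec = _synthetic_section(np.zeros((4, 2)), np.zeros((4, 3)), bowtie)
        with pytest.raises(ValueError, match="self-intersect"):
            area_and_diameter(sec)


@pytest.fixture(scope="module")
def wide_tube_section():
    """Poiseuille tube R = 15 mm, V̄ = 0.3 m/s on its own grid."""
    spec = PhantomSpec(radius=15.0, length_or_arc=20.0,
                       grid_shape=(41, 41, 13), n_frames=3,
                       waveform=np.ones(3), mean_velocity=0.3,
                       noise_sd=0.0, seed=2)
    dataset, truth = make_phantom(spec)
    field = VelocityField.from_dataset(dataset)
    roi = geometry.ROIMask(mask=truth.lumen_mask, spacing=dataset.spacing,
                           origin=dataset.origin)
    surface = geometry.extract_surface(roi)
    center = truth.centerline[len(truth.centerline) // 2]
    sec = sections_mod.gather_and_project(
        field, roi, center=center, x3=np.array([0.0, 0.0, 1.0]))
    return sections_mod.wall_frames(sec, surface), truth


class TestFlowRate:
    def test_poiseuille_flow_rate(self, wide_tube_section):
        """Q = π R² V̄ ≈ 212 ml/s within 3% (discretization)."""
        sec, truth = wide_tube_section
        q = flow_rate(sec)[0]
        assert q == pytest.approx(np.pi * 15.0**2 * 0.3, rel=0.03)
        assert q == pytest.approx(212.0, rel=0.03)

    def test_zero_flow(self):
        sec, _ = _disc_section(v_axial=0.0)
        assert flow_rate(sec) == pytest.approx(0.0)

    def test_linearity(self, wide_tube_section):
        sec, _ = wide_tube_section
        doubled = _synthetic_section(sec.points_local,
                                     2 * sec.velocities_local,
                                     sec.boundary_local)
        assert flow_rate(doubled)[0] == pytest.approx(2 * flow_rate(sec)[0])


class TestTimings:
    def test_half_sine(self):
        """Half-sine over 11 frames: peak frame 5, end frame 10, mid 7."""
        q = np.sin(np.pi * np.arange(1, 12) / 12.0)
        assert detect_timings(q) == (5, 10, 7)

    def test_tie_broken_to_earlier_frame(self):
        q = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.2])
        t_ps, t_es, t_dec = detect_timings(q)
        assert t_ps == 2
        assert t_ps <= t_dec <= t_es

    def test_monotone_waveform_rejected(self):
        with pytest.raises(ValueError):
            detect_timings(np.arange(6.0))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            q = rng.random(12)
            try:
                t_ps, t_es, t_dec = detect_timings(q)
            except ValueError:
                continue
            assert t_ps <= t_dec <= t_es


class TestStrokeVolume:
    def test_constant_flow_rectangle(self):
        t = np.array([0.0, 100.0, 200.0, 300.0])     # ms
        q = np.full(4, 300.0)                        # ml/s
        assert stroke_volume(q, t, t_es=3) == pytest.approx(90.0)

    def test_zero_flow(self):
        assert stroke_volume(np.zeros(5), 40.0 * np.arange(5), 4) == 0.0

    def test_trapezoid_convergence(self):
        t1 = np.linspace(0, 400, 11)
        t2 = np.linspace(0, 400, 21)
        q1 = np.sin(np.pi * t1 / 400.0)
        q2 = np.sin(np.pi * t2 / 400.0)
        sv1 = stroke_volume(q1, t1, 10)
        sv2 = stroke_volume(q2, t2, 20)
        assert abs(sv2 - sv1) / sv2 < 0.01


class TestVelocityStats:
    def test_uniform_section(self):
        sec, _ = _disc_section(v_axial=1.0)
        vmax, vmean = velocity_stats(sec, t_ps=0)
        assert vmax == pytest.approx(100.0)
        assert vmean == pytest.approx(100.0)

    def test_poiseuille_max_twice_mean(self, tube_chain):
        sec = tube_chain["sections"][len(tube_chain["sections"]) // 2]
        vmax, vmean = velocity_stats(sec, t_ps=1)
        assert vmax == pytest.approx(2 * vmean, rel=0.05)

    def test_outlier_hits_max_not_mean(self):
        sec, pts = _disc_section(v_axial=0.5)
        v2 = sec.velocities_local.copy()
        v2[0, 0, 2] = 3.0
        spiked = _synthetic_section(pts, v2[0], sec.boundary_local)
        vmax0, vmean0 = velocity_stats(sec, 0)
        vmax1, vmean1 = velocity_stats(spiked, 0)
        # max jumps by the full spike; the mean moves only by spike/N
        assert vmax1 - vmax0 == pytest.approx(250.0)
        assert vmean1 - vmean0 < 0.1 * (vmax1 - vmax0)


class TestJetMetrics:
    def test_axial_jet_angle_zero(self):
        sec, _ = _disc_section(v_axial=1.0)
        assert jet_angle(sec, 0) == pytest.approx(0.0, abs=1e-9)

    def test_oblique_jet_angle_45(self):
        sec, pts = _disc_section()
        v = np.zeros((len(pts), 3))
        v[:, 0] = 1 / np.sqrt(2)
        v[:, 2] = 1 / np.sqrt(2)
        oblique = _synthetic_section(pts, v, sec.boundary_local)
        assert jet_angle(oblique, 0) == pytest.approx(45.0)
        # invariant to uniform scaling
        scaled = _synthetic_section(pts, 3.3 * v, sec.boundary_local)
        assert jet_angle(scaled, 0) == pytest.approx(45.0)

    def test_no_positive_flow_raises(self):
        sec, pts = _disc_section(v_axial=-1.0)
        with pytest.raises(ValueError):
            jet_angle(sec, 0)
        with pytest.raises(ValueError):
            flow_displacement(sec, 0)

    def test_centered_jet_zero_displacement(self):
        sec, _ = _disc_section(v_axial=1.0)
        assert flow_displacement(sec, 0) < 0.02

    def test_half_disc_jet_displaced(self):
        sec, pts = _disc_section()
        v = np.zeros((len(pts), 3))
        v[pts[:, 0] > 0, 2] = 1.0
        half = _synthetic_section(pts, v, sec.boundary_local)
        assert flow_displacement(half, 0) > 0.1


class TestTractSummary:
    def _stats(self, arc_values):
        return [
            bulkflow.SectionStats(index=i, arc_s=s, area_mm2=314.0,
                                  diameter_mm=20.0, v_max_cms=100.0 + i,
                                  v_mean_cms=50.0, jet_angle_deg=5.0,
                                  flow_displacement=0.05)
            for i, s in enumerate(arc_values)]

    def test_half_open_tract_boundaries(self):
        stats = self._stats([0.0, 10.0, 20.0, 30.0])
        lm = {"LVOT": 0.0, "PA": 20.0, "BrA": 40.0}
        table = tract_summary(stats, lm)
        # s = 20 belongs to PA-BrA, not LVOT-PA
        assert table.loc["LVOT-PA", "n_sections"] == 2
        assert table.loc["PA-BrA", "n_sections"] == 2

    def test_single_section_tract_equals_stats(self):
        stats = self._stats([0.0, 25.0])
        lm = {"LVOT": 0.0, "PA": 20.0, "BrA": 40.0}
        table = tract_summary(stats, lm)
        assert table.loc["PA-BrA", "V_max_cms"] == stats[1].v_max_cms
        assert table.loc["PA-BrA", "D_max_mm"] == stats[1].diameter_mm

    def test_uniform_tube_peak_equals_every_diameter(self, tube_chain):
        secs = tube_chain["sections"]
        stats = [section_stats(s, t_ps=1) for s in secs]
        lm = {"LVOT": secs[0].arc_s, "PA": secs[len(secs) // 2].arc_s,
              "BrA": secs[-1].arc_s + 0.1}
        table = tract_summary(stats, lm)
        diams = [s.diameter_mm for s in stats]
        assert table["D_max_mm"].max() <= max(diams) + 1e-9
        assert table["D_max_mm"].min() >= min(diams) - 1e-9

    def test_empty_tract_raises(self):
        stats = self._stats([30.0])
        with pytest.raises(ValueError):
            tract_summary(stats, {"LVOT": 0.0, "PA": 20.0, "BrA": 40.0})


class TestMannWhitney:
    def test_identical_samples(self):
        p, sig = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert not sig

    def test_fully_separated_exact_p(self):
        """Exact two-sided p for n = 3 vs 3 with no overlap is 0.1."""
        p, sig = compare_groups([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        assert not sig

    def test_symmetric_under_swap(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        assert compare_groups(a, b)[0] == pytest.approx(
            compare_groups(b, a)[0])

    def test_all_tied_degenerate(self):
        p, sig = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0
        assert not sig

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
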