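"""Analysis pipeline: maps, pole detection, link census, kymographs, width."""

import numpy as np
import pytest

from helpers import frames_from_end_points
from spindlesim import quantify
from spindlesim.quantify import (
    DensityMap,
    LinkGeometry,
    NetworkState,
    PoleStats,
    build_count_map,
    build_density_map,
    classify_links,
    classify_state,
    detect_poles,
    fit_width_scaling,
    flux_speed,
    kymograph,
    pole_stats,
    ratio_map,
    spindle_axis,
    spindle_width,
)
from spindlesim.synthetic_fixtures import drifting_speckle_field, planted_pole_cloud

EXTENT = (-7.5, 7.5, -7.5, 7.5)


def make_ratio(values, grid=0.5):
    return quantify.RatioMap(np.asarray(values, dtype=float), EXTENT, grid)


class TestDensityMap:
    def test_single_point_unit_mass(self):
        m = build_density_map(np.array([[1.3, -2.1]]), EXTENT)
        assert m.total == pytest.approx(1.0, abs=1e-3)
        ix, iy = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert (ix, iy) == m.cell_of((1.3, -2.1))

    def test_two_frames_double_intensity(self):
        p = np.array([[0.2, 0.7]])
        one = build_density_map([p], EXTENT)
        two = build_density_map([p, p], EXTENT)
        assert np.allclose(two.values, 2 * one.values)

    def test_mass_conservation_scattered(self, rng):
        pts = rng.uniform(-5, 5, size=(100, 2))
        m = build_density_map(pts, EXTENT)
        assert m.total == pytest.approx(100.0, rel=0.01)

    def test_empty_window_zero_map(self):
        m = build_density_map([], EXTENT)
        assert m.total == 0.0


class TestRatioMap:
    def test_formula(self):
        minus = DensityMap(np.array([[8.0]]), EXTENT)
        plus = DensityMap(np.array([[3.0]]), EXTENT)
        assert ratio_map(minus, plus).values[0, 0] == pytest.approx(2.0)

    def test_zero_plus_gives_minus(self):
        minus = DensityMap(np.array([[5.0, 5.0]]), EXTENT)
        plus = DensityMap(np.array([[0.0, 0.0]]), EXTENT)
        assert np.allclose(ratio_map(minus, plus).values, 5.0)

    def test_weak_signal_filtered(self):
        minus = DensityMap(np.array([[100.0, 0.9]]), EXTENT)
        plus = DensityMap(np.zeros((1, 2)), EXTENT)
        r = ratio_map(minus, plus, filter_fraction=0.05)
        assert r.values[0, 1] == 0.0  # 0.9 < 5% of 100
        assert r.values[0, 0] == pytest.approx(100.0)

    def test_incongruent_maps_rejected(self):
        with pytest.raises(ValueError):
            ratio_map(
                DensityMap(np.zeros((2, 2)), EXTENT),
                DensityMap(np.zeros((3, 2)), EXTENT),
            )


class TestDetectPoles:
    def test_uniform_map_no_poles(self):
        assert detect_poles(make_ratio(np.full((20, 20), 50.0))) == []

    def test_two_planted_clusters(self, rng):
        # tight clusters (negligible plus ends): poles at the cluster cells
        # with close to the full per-cluster end count in the pole pixel
        scene = planted_pole_cloud(
            2, ends_per_pole=50, separation=5.0, spread=0.15, plus_cloud=0, seed=1
        )
        mm = build_density_map(scene["minus_frames"], EXTENT)
        pm = build_density_map(scene["plus_frames"], EXTENT)
        cm = build_count_map(scene["minus_frames"], EXTENT)
        poles = detect_poles(ratio_map(mm, pm), cm)
        assert len(poles) == 2
        got = sorted(p.position[0] for p in poles)
        truth = sorted(scene["truth"]["pole_positions"][:, 0])
        assert got[0] == pytest.approx(truth[0], abs=0.5)
        assert got[1] == pytest.approx(truth[1], abs=0.5)
        for p in poles:
            assert p.minus_count == pytest.approx(50.0, rel=0.35)

    def test_close_maxima_merge_keeping_higher(self):
        V = np.zeros((20, 20))
        V[10, 10] = 20.0
        V[10, 11] = 15.0
        poles = detect_poles(make_ratio(V))
        assert len(poles) == 1
        assert (poles[0].ix, poles[0].iy) == (10, 10)

    def test_threshold_strictly_exceeded(self):
        V = np.zeros((9, 9))
        V[4, 4] = 8.0  # not > 8
        assert detect_poles(make_ratio(V)) == []
        V[4, 4] = 8.1
        assert len(detect_poles(make_ratio(V))) == 1

    def test_translation_and_mirror_equivariance(self, rng):
        V = np.zeros((30, 30))
        V[8, 9] = 20.0
        V[20, 22] = 15.0
        base = {(p.ix, p.iy) for p in detect_poles(make_ratio(V))}
        shifted = {(p.ix, p.iy) for p in detect_poles(make_ratio(np.roll(V, (3, 2), (0, 1))))}
        assert shifted == {(ix + 3, iy + 2) for ix, iy in base}
        mirrored = {(p.ix, p.iy) for p in detect_poles(make_ratio(V[::-1].copy()))}
        assert mirrored == {(29 - ix, iy) for ix, iy in base}


class TestPoleStats:
    def planted_traj(self, ks, rng, ends=150, sep=5.0):
        minus, plus = [], []
        for k in ks:
            scene = planted_pole_cloud(
                k,
                ends_per_pole=ends,
                separation=sep,
                spread=0.25,
                n_frames=1,
                seed=int(rng.integers(1 << 30)),
            )
            minus.append(scene["minus_frames"][0])
            plus.append(scene["plus_frames"][0])
        return frames_from_end_points(minus, plus)

    def test_constant_two_poles(self, rng):
        traj = self.planted_traj([2] * 12, rng)
        st = pole_stats(
            traj, sample_interval=1.98, map_window=1, stats_window=1e9, extent=EXTENT
        )
        assert st.mean == pytest.approx(2.0)
        assert st.sd == 0.0
        # pole-pixel count ~ ends x (2D Gaussian mass of the 0.5 um cell)
        from scipy.special import erf

        sigma = np.hypot(0.25, 0.05)
        expected = 150.0 * erf(0.25 / (sigma * np.sqrt(2))) ** 2
        assert st.mean_ends_per_pole == pytest.approx(expected, rel=0.4)

    def test_alternating_counts(self, rng):
        traj = self.planted_traj([2, 3] * 8, rng)
        st = pole_stats(
            traj, sample_interval=1.98, map_window=1, stats_window=1e9, extent=EXTENT
        )
        assert st.mean == pytest.approx(2.5)
        assert st.sd == pytest.approx(0.5)

    def test_zero_pole_trajectory_flagged(self, rng):
        traj = self.planted_traj([0] * 8, rng)
        st = pole_stats(
            traj, sample_interval=1.98, map_window=1, stats_window=1e9, extent=EXTENT
        )
        assert st.mean == 0.0 and st.no_poles
        assert st.mean_ends_per_pole == 0.0

    def test_too_short_trajectory_rejected(self, rng):
        traj = self.planted_traj([2] * 5, rng)
        with pytest.raises(ValueError):
            pole_stats(traj, map_window=51, extent=EXTENT)


class TestClassifyState:
    def stats(self, mean, sd, epp=61.0):
        return PoleStats(
            times=np.zeros(1),
            counts=np.zeros(1),
            ends_per_pole=np.zeros(1),
            mean=mean,
            sd=sd,
            mean_ends_per_pole=epp,
            no_poles=epp == 0,
        )

    @pytest.mark.parametrize(
        "mean, sd, epp, expected",
        [
            (2.0, 0.2, 61.0, NetworkState.BIPOLAR),
            (1.0, 0.1, 40.0, NetworkState.MONOPOLAR),
            (4.2, 1.5, 30.0, NetworkState.MULTIPOLAR),
            (2.0, 1.2, 30.0, NetworkState.MULTIPOLAR),
            (2.0, 0.2, 1.0, NetworkState.UNFOCUSED),
            (0.0, 0.0, 0.0, NetworkState.UNFOCUSED),
        ],
    )
    def test_rules(self, mean, sd, epp, expected):
        assert classify_state(self.stats(mean, sd, epp)) == expected


class TestClassifyLinks:
    ex = np.array([1.0, 0, 0])
    ey = np.array([0.0, 1, 0])

    def lg(self, aa, ab, ta, tb, L=2.5):
        return LinkGeometry(aa, L, np.asarray(ta, float), ab, L, np.asarray(tb, float))

    def test_parallel_side_side(self):
        c = classify_links([self.lg(1.0, 1.2, self.ex, self.ex)])
        assert c.counts["H_parallel"] == 1

    def test_end_side_is_T(self):
        c = classify_links([self.lg(0.01, 1.0, self.ex, self.ey)])
        assert c.counts["T"] == 1
        # plus-end side also counts as an end
        c = classify_links([self.lg(2.49, 1.0, self.ex, self.ex)])
        assert c.counts["T"] == 1

    def test_end_end_is_V(self):
        c = classify_links([self.lg(0.0, 0.0, self.ex, -self.ex)])
        assert c.counts["V"] == 1

    def test_partition_property(self, rng):
        def unit():
            v = rng.normal(size=3)
            return v / np.linalg.norm(v)

        links = [
            self.lg(rng.uniform(0, 2.5), rng.uniform(0, 2.5), unit(), unit())
            for _ in range(300)
        ]
        c = classify_links(links)
        assert c.total == 300
        assert sum(c.fractions.values()) == pytest.approx(1.0)


class TestKymographAndFlux:
    def test_static_points_vertical_stripes(self):
        pts = [np.array([[1.0, 0.0], [3.0, 0.5]])] * 10
        ky = kymograph(pts, np.arange(10) * 1.98, np.zeros(2), [1.0, 0.0])
        assert np.all(ky.matrix == ky.matrix[0])
        assert ky.matrix.sum() == 20

    def test_drifting_points_slope_recovered(self):
        v = 0.03  # um/s = 30 nm/s
        times = np.arange(100) * 1.98
        pts = [np.array([[2.0 + v * t, 0.0]]) for t in times]
        ky = kymograph(pts, times, np.zeros(2), [1.0, 0.0], bin_size=0.1)
        peak_pos = ky.positions[np.argmax(ky.matrix, axis=1)]
        slope = np.polyfit(times, peak_pos, 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_empty_window(self):
        ky = kymograph([], np.zeros(0), np.zeros(2), [1.0, 0.0])
        assert ky.matrix.shape[0] == 0

    def test_flux_bidirectional_field(self):
        data = drifting_speckle_field(30.0, bidirectional=True, seed=2)
        speed, per_side = flux_speed(
            data["tracks"], data["axis_origin"], data["axis_direction"]
        )
        assert speed == pytest.approx(30.0, abs=1.0)
        assert per_side[1] > 0 and per_side[-1] < 0

    def test_flux_static_zero(self):
        data = drifting_speckle_field(0.0, seed=3)
        speed, _ = flux_speed(data["tracks"], data["axis_origin"], data["axis_direction"])
        assert abs(speed) < 1.0

    def test_flux_median_robust_to_outlier(self):
        data = drifting_speckle_field(30.0, n_tracks=50, seed=4)
        bad = data["tracks"][0]
        bad["positions"][:, 0] += np.linspace(0, 100.0, bad["times"].size)
        speed, _ = flux_speed(data["tracks"], data["axis_origin"], data["axis_direction"])
        assert speed == pytest.approx(30.0, abs=1.5)

    def test_too_few_tracks_rejected(self):
        data = drifting_speckle_field(30.0, n_tracks=3, seed=5)
        with pytest.raises(ValueError):
            flux_speed(data["tracks"], data["axis_origin"], data["axis_direction"])

    def test_axis_from_two_poles_and_fallback(self, rng):
        from spindlesim.quantify import Pole

        poles = [
            Pole(0, 0, np.array([-2.0, 0.0]), 10.0, 5.0),
            Pole(0, 0, np.array([2.0, 0.0]), 10.0, 5.0),
        ]
        origin, d = spindle_axis(poles)
        assert np.allclose(origin, 0.0) and abs(d[0]) == pytest.approx(1.0)
        minus = np.column_stack([rng.uniform(-3, 3, 100), rng.normal(0, 0.1, 100)])
        with pytest.warns(UserWarning):
            _, d = spindle_axis([], minus)
        assert abs(d[0]) > 0.99


class TestSpindleWidth:
    def make_bundle_frame(self, laterals):
        minus = np.array([[-2.0, y] for y in laterals])
        plus = np.array([[2.0, y] for y in laterals])
        return frames_from_end_points([minus], [plus]).frames[0]

    def poles(self):
        from spindlesim.quantify import Pole

        return [
            Pole(0, 0, np.array([-2.0, 0.0]), 10.0, 5.0),
            Pole(0, 0, np.array([2.0, 0.0]), 10.0, 5.0),
        ]

    def test_planted_uniform_bundle(self):
        frame = self.make_bundle_frame(np.linspace(-0.5, 0.5, 41))
        w = spindle_width(frame, self.poles())
        # central 90% of a uniform 1-um-wide bundle
        assert w == pytest.approx(0.9, abs=0.1)

    def test_planted_gaussian_bundle(self, rng):
        lat = rng.normal(0.0, 0.5, size=400)
        frame = self.make_bundle_frame(lat)
        w = spindle_width(frame, self.poles())
        assert w == pytest.approx(2 * 1.645 * 0.5, rel=0.1)

    def test_non_bipolar_rejected(self):
        frame = self.make_bundle_frame(np.zeros(3))
        with pytest.raises(ValueError):
            spindle_width(frame, self.poles()[:1])

    def test_sqrt_fit_exact_recovery(self):
        N = np.array([100.0, 200.0, 400.0])
        c = 0.123
        assert fit_width_scaling(c * np.sqrt(N), N) == pytest.approx(c, rel=0.01)

    def test_sqrt_scaling_doubles(self):
        c = fit_width_scaling([1.0], [100.0])
        assert c * np.sqrt(200.0) == pytest.approx(np.sqrt(2) * c * np.sqrt(100.0))
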