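import math

import numpy as np
import pytest

import explometrics as em
from conftest import make_traj
from explometrics import measures as M
from explometrics.trajio import Environment, Landmark, MeasureParams


def unit_env(n=10, landmarks=()):
    """n x n environment with 1-vm cells."""
    return Environment(
        name="unit",
        bounds=(0.0, 0.0, float(n), float(n)),
        bin_size=1.0,
        k_norm=n * n,
        landmarks=list(landmarks),
    )


class TestBinSequence:
    def test_single_cell(self):
        traj = make_traj([[0.2, 0.2], [0.8, 0.8], [0.5, 0.5]])
        bins = M.bin_sequence(traj, unit_env())
        assert M.area_covered(bins) == 1
        assert len(bins.entries) == 1

    def test_straight_crossing_ten_cells(self):
        xs = np.linspace(0.5, 9.5, 19)
        traj = make_traj(np.column_stack([xs, np.full(19, 0.5)]))
        bins = M.bin_sequence(traj, unit_env())
        assert M.area_covered(bins) == 10
        assert len(bins.entries) == 10
        assert M.area_efficiency(bins) == 1.0

    def test_out_and_back_three_cells(self):
        xs = [0.5, 1.5, 2.5, 1.5, 0.5]
        traj = make_traj(np.column_stack([xs, np.full(5, 0.5)]))
        bins = M.bin_sequence(traj, unit_env())
        assert M.area_covered(bins) == 3
        assert len(bins.entries) == 5
        assert M.area_efficiency(bins) == pytest.approx(0.6)

    def test_entries_match_bruteforce_runlength(self, rng):
        pts = np.cumsum(rng.normal(scale=0.7, size=(300, 2)), axis=0) + 50
        traj = make_traj(pts)
        env = unit_env(100)
        bins = M.bin_sequence(traj, env)
        brute = []
        for i, j in bins.bins:
            if not brute or brute[-1] != (i, j):
                brute.append((i, j))
        assert [tuple(e) for e in bins.entries] == brute

    def test_out_of_bounds_clamped(self):
        traj = make_traj([[-5.0, 0.5], [0.5, 0.5]])
        bins = M.bin_sequence(traj, unit_env())
        assert bins.n_clamped == 1
        assert tuple(bins.bins[0]) == (0, 0)


class TestPathLengthAndPausing:
    def test_pythagoras(self):
        assert M.path_length(make_traj([[0, 0], [3, 4]])) == pytest.approx(5.0)

    def test_unit_square_loop(self, fixture_lib):
        assert M.path_length(fixture_lib["unit_square_loop"]) == pytest.approx(4.0)

    def test_matches_step_sum(self, rng):
        pts = rng.normal(size=(50, 2))
        traj = make_traj(pts)
        oracle = sum(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(49))
        assert M.path_length(traj) == pytest.approx(oracle)

    def test_pausing_counts_zero_steps(self):
        pts = np.vstack([np.zeros((31, 2)),
                         np.column_stack([np.arange(1, 11), np.zeros(10)])])
        traj = make_traj(pts, hz=10.0)
        assert M.pausing(traj) == pytest.approx(3.0)

    def test_no_pauses(self):
        traj = make_traj([[0, 0], [1, 0], [2, 0]], hz=10.0)
        assert M.pausing(traj) == 0.0

    def test_unknown_rate_is_error(self):
        traj = make_traj([[0, 0], [1, 0]], hz=None)
        with pytest.raises(ValueError):
            M.pausing(traj)


class TestRoamingEntropy:
    def test_single_bin_zero(self):
        bins = M.bin_sequence(make_traj([[0.1, 0.1], [0.2, 0.2]]), unit_env())
        assert M.roaming_entropy(bins, 100) == 0.0

    def test_uniform_over_k_bins_is_one(self):
        # one sample in each of the k = 16 cells of a 4x4 environment
        pts = [[i + 0.5, j + 0.5] for i in range(4) for j in range(4)]
        bins = M.bin_sequence(make_traj(pts), unit_env(4))
        assert M.roaming_entropy(bins, 16) == pytest.approx(1.0, abs=1e-12)

    def test_two_bins_half_half(self):
        pts = [[0.5, 0.5], [1.5, 0.5]] * 5
        bins = M.bin_sequence(make_traj(pts), unit_env())
        expected = math.log(2) / math.log(100)
        assert M.roaming_entropy(bins, 100) == pytest.approx(expected, abs=1e-12)

    def test_small_k_rejected(self):
        bins = M.bin_sequence(make_traj([[0.1, 0.1], [0.2, 0.2]]), unit_env())
        with pytest.raises(ValueError):
            M.roaming_entropy(bins, 1)


def _giftwrap_hull_area(pts):
    """O(n^2) gift wrapping + shoelace, independent of scipy."""
    pts = np.unique(pts, axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for i in range(len(pts)):
            if i == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[i] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[i] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = i
        if cand == start:
            break
        hull.append(cand)
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestMinConvexPolygon:
    def test_unit_square(self):
        traj = make_traj([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert M.min_convex_polygon(traj) == pytest.approx(1.0)

    def test_collinear_zero(self):
        traj = make_traj(np.column_stack([np.arange(5.0), np.arange(5.0)]))
        assert M.min_convex_polygon(traj) == 0.0

    def test_matches_giftwrap_oracle(self, rng):
        for _ in range(10):
            pts = rng.uniform(size=(200, 2)) * rng.uniform(1, 50)
            traj = make_traj(pts)
            assert abs(M.min_convex_polygon(traj) - _giftwrap_hull_area(pts)) < 1e-9


class TestFractalDimension:
    def test_straight_line_is_one(self, fixture_lib):
        d = M.fractal_dimension(fixture_lib["straight_line"])
        assert d == pytest.approx(1.0, abs=0.02)

    def test_isometry_invariance(self, fixture_lib):
        traj = fixture_lib["dense_random_walk"]
        d0 = M.fractal_dimension(traj)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = make_traj(traj.points @ rot.T + np.array([13.0, -4.0]))
        assert M.fractal_dimension(moved) == pytest.approx(d0, abs=1e-6)

    def test_confined_walk_between_one_and_two(self, fixture_lib):
        d = M.fractal_dimension(fixture_lib["dense_random_walk"])
        assert 1.0 < d <= 2.0

    def test_matches_independent_divider_oracle(self, rng):
        # oracle: same definition, independently coded with the
        # fine-subdivision arc walker from the preprocessing tests
        from test_preprocess import _redisc_oracle

        pts = np.cumsum(rng.normal(scale=0.5, size=(150, 2)), axis=0)
        traj = make_traj(pts)
        params = MeasureParams(fd_n_steps=6)
        d = M.fractal_dimension(traj, params)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        med = np.median(steps[steps > 0])
        deltas = np.geomspace(0.5 * med, 10 * med, 6)
        log_d, log_l = [], []
        total = steps.sum()
        for delta in deltas:
            if total < 2 * delta:
                continue
            walked = _redisc_oracle(pts, delta)
            if len(walked) < 2:
                continue
            log_d.append(np.log(delta))
            log_l.append(np.log((len(walked) - 1) * delta))
        oracle = 1.0 - np.polyfit(log_d, log_l, 1)[0]
        assert d == pytest.approx(oracle, abs=0.02)


class TestSinuosity:
    def test_straight_line_zero(self, fixture_lib):
        rd = em.rediscretize_spatial(fixture_lib["straight_line"], 0.5)
        assert M.sinuosity(rd) == 0.0

    def test_formula_on_constructed_sigma(self):
        # constant-step path whose signed turning angles are +/- 0.2 rad
        # exactly: population sd is 0.2
        q = 0.5
        angles = np.tile([0.2, -0.2], 50)
        headings = np.concatenate([[0.0], np.cumsum(angles)])
        steps = q * np.column_stack([np.cos(headings), np.sin(headings)])
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        traj = make_traj(pts)
        expected = 1.18 * 0.2 / math.sqrt(q)
        assert M.sinuosity(traj) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.33376, abs=5e-5)

    def test_linear_in_sigma(self):
        def path(sig):
            angles = np.tile([sig, -sig], 50)
            headings = np.concatenate([[0.0], np.cumsum(angles)])
            steps = 0.5 * np.column_stack([np.cos(headings), np.sin(headings)])
            return make_traj(np.vstack([[0, 0], np.cumsum(steps, axis=0)]))

        assert M.sinuosity(path(0.4)) == pytest.approx(2 * M.sinuosity(path(0.2)))


class TestLandmarkMetrics:
    def _env(self):
        lms = [Landmark(f"L{i}", 100.0 * i, 0.0) for i in range(20)]
        return Environment("lmtest", (-50, -50, 2000, 50), 14.0, 100, lms)

    def test_single_pass_three_landmarks(self):
        xs = np.linspace(-10, 215, 100)
        traj = make_traj(np.column_stack([xs, np.zeros(100)]))
        visits, revisits, eff, _ = M.landmark_metrics(traj, self._env())
        assert (visits, revisits, eff) == (3, 0, 1.0)

    def test_reentry_requires_full_exit(self):
        xs = np.concatenate([np.linspace(-30, 30, 30),  # enter L0
                             np.linspace(30, 60, 15),   # leave (r=20)
                             np.linspace(60, 0, 30)])   # re-enter
        traj = make_traj(np.column_stack([xs, np.zeros(len(xs))]))
        visits, revisits, eff, log = M.landmark_metrics(traj, self._env())
        assert (visits, revisits) == (1, 1)
        assert eff == pytest.approx(0.5)
        assert log.total_entries == 2

    def test_no_entries_gives_nan_efficiency(self):
        traj = make_traj([[1000.0, 45.0], [1001.0, 45.0]])
        visits, revisits, eff, _ = M.landmark_metrics(traj, self._env())
        assert (visits, revisits) == (0, 0)
        assert math.isnan(eff)

    def test_entries_match_bruteforce_scan(self, rng):
        env = self._env()
        pts = np.cumsum(rng.normal(scale=8.0, size=(400, 2)), axis=0)
        traj = make_traj(pts)
        _, _, _, log = M.landmark_metrics(traj, env)
        brute = 0
        for lm in env.landmarks:
            inside = (pts[:, 0] - lm.x) ** 2 + (pts[:, 1] - lm.y) ** 2 <= 400.0
            brute += inside[0] + int(np.sum(inside[1:] & ~inside[:-1]))
        assert log.total_entries == brute


class TestRevisiting:
    def test_monotone_line_no_revisits(self):
        xs = np.linspace(0, 500, 1001)
        traj = make_traj(np.column_stack([xs, np.zeros(1001)]))
        assert M.revisiting(traj) == 0.0

    def test_out_and_back_about_one(self):
        xs = np.concatenate([np.linspace(0, 300, 601), np.linspace(300, 0, 601)[1:]])
        traj = make_traj(np.column_stack([xs, np.zeros(len(xs))]))
        value = M.revisiting(traj)
        brute = _revisit_bruteforce(traj.points, 14.0)
        assert value == pytest.approx(brute)
        assert 0.8 <= value <= 1.0  # each place entered twice, ends excepted

    def test_k_loop_traversals(self):
        angles = np.linspace(0, 6 * np.pi, 1801)  # 3 loops of radius 60
        pts = np.column_stack([60 * np.cos(angles), 60 * np.sin(angles)])
        value = M.revisiting(make_traj(pts))
        assert value == pytest.approx(2.0, abs=0.35)  # ~ k - 1 returns


def _revisit_bruteforce(pts, r):
    centers = [pts[0]]
    for p in pts[1:]:
        if all(np.linalg.norm(p - c) > r for c in centers):
            centers.append(p)
    total = 0.0
    for c in centers:
        inside = np.linalg.norm(pts - c, axis=1) <= r
        entries = inside[0] + int(np.sum(inside[1:] & ~inside[:-1]))
        total += entries - 1
    return total / len(centers)


class TestTurnarounds:
    def test_single_out_and_back(self, fixture_lib):
        assert M.turnarounds(fixture_lib["out_and_back"]) == 1

    def test_smooth_arc_zero(self, fixture_lib):
        assert M.turnarounds(fixture_lib["circle"]) == 0

    def test_strafing_inflates_step_scale_only(self):
        # forward corridor with stationary lateral jiggles: each jiggle
        # is an exact small-scale reversal invisible at flight scale
        pts = [[0.0, 0.0]]
        x = 0.0
        for k in range(20):
            for _ in range(10):
                x += 0.5
                pts.append([x, 0.0])
            pts.append([x, 0.3])
            pts.append([x, 0.0])  # pure strafe out and back: 180 degrees
        traj = make_traj(np.array(pts))
        step_count = M.turnarounds(traj)
        angles = em.preprocess.turning_angles(traj)
        assert step_count == int(np.sum(angles >= 179.5))
        assert step_count == 20
        assert M.flight_turnarounds(traj) == 0

    def test_comb_flight_turnarounds(self, fixture_lib, params):
        comb = fixture_lib["comb_5_teeth"]
        assert M.flight_turnarounds(comb, params) == 5
        assert M.turnarounds(comb, params) != 5

    def test_unjittered_comb_step_scale_finds_reversals(self, params):
        from explometrics.synthdata import comb_trajectory

        clean = comb_trajectory(jitter=0.0)
        assert M.turnarounds(clean, params) == 5
        assert M.flight_turnarounds(clean, params) == 5

    def test_flight_invariant_to_subepsilon_jitter(self, params):
        from explometrics.synthdata import comb_trajectory

        for amp in (0.0, 0.4, 1.0):
            assert M.flight_turnarounds(comb_trajectory(jitter=amp), params) == 5

    def test_circle_and_subepsilon_zigzag(self, fixture_lib, params):
        assert M.flight_turnarounds(fixture_lib["circle"], params) == 0
        x = np.arange(200.0)
        y = np.where(x % 2 == 0, 0.5, -0.5)
        zig = make_traj(np.column_stack([x, y]))
        assert M.flight_turnarounds(zig, params) == 0


class TestComputeAll:
    def test_straight_line_composite(self, fixture_lib, env140, params):
        row = M.compute_all(fixture_lib["straight_line"], env140, params)
        assert row.path_length == pytest.approx(100.0)
        assert row.pausing == 0.0
        assert row.sinuosity == pytest.approx(0.0, abs=1e-9)
        assert row.fractal_dimension == pytest.approx(1.0, abs=0.02)
        assert row.turnarounds == 0
        assert row.flight_turnarounds == 0
        assert row.area_efficiency == 1.0
        assert row.revisiting == 0.0

    def test_determinism(self, fixture_lib, env140, params):
        a = M.compute_all(fixture_lib["dense_random_walk"], env140, params)
        b = M.compute_all(fixture_lib["dense_random_walk"], env140, params)
        assert a.as_dict() == b.as_dict()

    def test_self_consistency_with_individual_ops(self, env140, params):
        cfg = em.SimConfig(env=env140, n_agents=1, duration_s=60.0, seed=5)
        traj = em.simulate_cohort(cfg)[0][0]
        row = M.compute_all(traj, env140, params)
        bins = M.bin_sequence(traj, env140)
        assert row.path_length == M.path_length(traj)
        assert row.area_covered == M.area_covered(bins)
        assert row.roaming_entropy == M.roaming_entropy(bins, env140.k_norm)
        assert row.area_efficiency == M.area_efficiency(bins)
        assert row.min_convex_polygon == M.min_convex_polygon(traj)
        assert row.fractal_dimension == M.fractal_dimension(traj, params)
        assert row.turnarounds == M.turnarounds(traj, params)
        assert row.flight_turnarounds == M.flight_turnarounds(traj, params)
        assert row.revisiting == M.revisiting(traj, params)


class TestDispersionMonotonicity:
    """Shape measures must grow with turning-angle dispersion."""

    @staticmethod
    def _crw(sigma, seed, n=600, q=0.5):
        rng = np.random.default_rng(seed)
        headings = np.cumsum(rng.normal(0, sigma, size=n))
        steps = q * np.column_stack([np.cos(headings), np.sin(headings)])
        return make_traj(np.vstack([[0, 0], np.cumsum(steps, axis=0)]))

    def test_sinuosity_and_fd_increase_with_dispersion(self):
        sins = {s: [] for s in (0.1, 0.3)}
        fds = {s: [] for s in (0.1, 0.3)}
        for seed in range(50):
            for sigma in (0.1, 0.3):
                traj = self._crw(sigma, seed)
                sins[sigma].append(M.sinuosity(traj))
                fds[sigma].append(M.fractal_dimension(traj))
        assert np.mean(sins[0.3]) > np.mean(sins[0.1])
        assert np.mean(fds[0.3]) > np.mean(fds[0.1])
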