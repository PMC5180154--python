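import math

import numpy as np
import pytest

from shoaltrack.core import ArenaGeometry, Trajectory, RecordingMeta
from shoaltrack import behaviour_metrics as bm
from tests.conftest import make_trial


def traj(x, y):
    meta = RecordingMeta(duration_frames=max(len(x), 1))
    return Trajectory(np.asarray(x, float), np.asarray(y, float), meta=meta)


# ---------------------------------------------------------------- oracles
def oracle_speeds(x, y, fr=25.0):
    out = []
    for t in range(1, len(x)):
        if any(math.isnan(v) for v in (x[t], y[t], x[t - 1], y[t - 1])):
            continue
        out.append(fr * math.hypot(x[t] - x[t - 1], y[t] - y[t - 1]))
    return out


def oracle_exploration(x, y, grid, fr=25.0, frac=0.10):
    seen, t_reach = set(), float("nan")
    thr = math.ceil(frac * grid.n_cells)
    for t in range(len(x)):
        if math.isnan(x[t]) or math.isnan(y[t]):
            continue
        c = (math.floor(x[t] / grid.cell_size),
             math.floor(y[t] / grid.cell_size))
        if c in grid.cells and c not in seen:
            seen.add(c)
            if math.isnan(t_reach) and len(seen) >= thr:
                t_reach = t / fr
    return t_reach, len(seen) / grid.n_cells


def oracle_pairwise(trial):
    """Per-frame per-fish NN distances and the pooled pair distances."""
    T, n = trial.n_frames, trial.n_fish
    P = trial.positions()
    nn = np.full((T, n), np.nan)
    pool = []
    for t in range(T):
        for i in range(n):
            best = np.nan
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(P[t, i, 0] - P[t, j, 0],
                               P[t, i, 1] - P[t, j, 1])
                if not math.isnan(d) and (math.isnan(best) or d < best):
                    best = d
                if i < j and not math.isnan(d):
                    pool.append(d)
            nn[t, i] = best
    return nn, pool


# ---------------------------------------------------------------- activity
class TestActivity:
    def test_constant_speed(self):
        x = np.arange(20) * 0.2   # 5 cm/s at 25 Hz
        assert bm.median_speed(traj(x, np.zeros(20))) == pytest.approx(5.0)

    def test_alternating_speeds_median(self):
        # displacement alternates 0 and 0.4 cm -> speeds 0 and 10 cm/s
        x = np.repeat(np.arange(11) * 0.4, 2)[:21]   # 20 speeds: 10 of each
        assert bm.median_speed(traj(x, np.zeros(21))) == pytest.approx(5.0)

    def test_median_speed_matches_sort_oracle(self, rng):
        x = rng.uniform(-10, 10, 80)
        y = rng.uniform(-10, 10, 80)
        x[rng.integers(0, 80, 5)] = np.nan
        expected = float(np.median(oracle_speeds(x, y)))
        assert bm.median_speed(traj(x, y)) == pytest.approx(expected)

    def test_no_valid_speed_warns_and_is_missing(self):
        x = np.array([1.0, np.nan, 2.0])
        with pytest.warns(UserWarning):
            out = bm.median_speed(traj(x, x.copy()))
        assert math.isnan(out)

    def test_stillness_extremes(self):
        assert bm.proportion_still(traj(np.ones(50), np.ones(50))) == 1.0
        fast = np.arange(50) * 0.4
        assert bm.proportion_still(traj(fast, np.zeros(50))) == 0.0

    def test_pixel_threshold_restated_per_second_rounds_to_0_7(self):
        assert round(bm.DEFAULT_STILL_THRESHOLD_CM * 25, 1) == 0.7


# ------------------------------------------------------------ arena use
class TestArenaReaction:
    def test_edge_extremes(self, arena):
        centre = traj(np.zeros(10), np.zeros(10))
        assert bm.proportion_near_edge(centre, arena) == 0.0
        r = arena.radius_cm - 1.0
        rim = traj(np.full(10, r), np.zeros(10))
        assert bm.proportion_near_edge(rim, arena) == 1.0

    def test_uniform_disc_matches_area_ratio(self, arena, rng):
        # P(edge zone) = 1 - (11.5/14.5)^2 for uniform points in the disc
        n = 200_000
        r = arena.radius_cm * np.sqrt(rng.uniform(size=n))
        a = rng.uniform(0, 2 * np.pi, n)
        p = bm.proportion_near_edge(traj(r * np.cos(a), r * np.sin(a)),
                                    arena)
        expect = 1 - (11.5 / 14.5) ** 2
        assert p == pytest.approx(expect, abs=0.005)

    def test_unit_radius_grid_has_four_cells(self):
        tiny = ArenaGeometry(radius_cm=1.0, edge_zone_width_cm=0.5)
        assert bm.build_exploration_grid(tiny).n_cells == 4

    def test_centre_cell_always_included(self, grid):
        assert (0, 0) in grid.cells and (-1, -1) in grid.cells

    @pytest.mark.parametrize("radius,convention", [
        (3.0, "intersects_disc"), (3.0, "centre_in_disc"),
        (14.5, "intersects_disc")])
    def test_grid_against_rasterization_oracle(self, radius, convention):
        arena = ArenaGeometry(radius_cm=radius, edge_zone_width_cm=1.0,
                              grid_convention=convention)
        grid = bm.build_exploration_grid(arena)
        m = int(np.ceil(radius))
        cells = set()
        eps = np.linspace(0.005, 0.995, 100)
        for i in range(-m, m):
            for j in range(-m, m):
                if convention == "centre_in_disc":
                    ok = np.hypot(i + 0.5, j + 0.5) < radius
                else:
                    xs = i + eps
                    ys = j + eps
                    ok = (np.hypot(xs[:, None], ys[None, :]) < radius).any()
                if ok:
                    cells.add((i, j))
        assert grid.cells == cells

    def test_motionless_fish_explores_one_cell(self, grid):
        t10, pct = bm.exploration_stats(traj(np.full(100, 3.3),
                                             np.full(100, 3.3)), grid)
        assert math.isnan(t10)
        assert pct == pytest.approx(1 / grid.n_cells)

    def test_boustrophedon_path_covers_everything(self, arena, grid):
        xs, ys = [], []
        for (i, j) in sorted(grid.cells):
            xs.append(i + 0.5)
            ys.append(j + 0.5)
        t10, pct = bm.exploration_stats(traj(xs, ys), grid)
        assert pct == 1.0
        assert t10 == pytest.approx((math.ceil(0.1 * grid.n_cells) - 1) / 25)

    def test_exploration_matches_oracle_on_random_walk(self, grid,
                                                       random_walk_trial):
        for tr in random_walk_trial.trajectories:
            got = bm.exploration_stats(tr, grid)
            exp = oracle_exploration(tr.x, tr.y, grid)
            assert got[1] == pytest.approx(exp[1])
            assert (math.isnan(got[0]) and math.isnan(exp[0])) or \
                got[0] == pytest.approx(exp[0])

    def test_visited_fraction_nondecreasing(self, grid, random_walk_trial):
        tr = random_walk_trial.trajectories[0]
        fractions = [bm.exploration_stats(
            Trajectory(tr.x[:k], tr.y[:k], meta=tr.meta), grid)[1]
            for k in (10, 40, 70, 100)]
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


# ------------------------------------------------------------- sociality
class TestSociality:
    def test_two_fish_constant_distance(self):
        pos = np.zeros((10, 2, 2))
        pos[:, 1, 0] = 5.0
        ctx = bm.pairwise_distance_stats(make_trial(pos))
        assert ctx.median_interfish_cm == 5.0
        np.testing.assert_allclose(ctx.nn_distance, 5.0)

    def test_min_pairwise_le_median(self, random_walk_trial):
        ctx = bm.pairwise_distance_stats(random_walk_trial)
        n = random_walk_trial.n_fish
        iu, ju = np.triu_indices(n, k=1)
        for t in range(random_walk_trial.n_frames):
            pairs = ctx.distances[t, iu, ju]
            assert np.nanmin(pairs) <= np.nanmedian(pairs) + 1e-12

    def test_pairwise_matches_brute_force(self, random_walk_trial):
        ctx = bm.pairwise_distance_stats(random_walk_trial)
        nn, pool = oracle_pairwise(random_walk_trial)
        np.testing.assert_allclose(ctx.nn_distance, nn, atol=1e-12)
        assert ctx.median_interfish_cm == pytest.approx(
            float(np.median(pool)))

    def test_single_fish_rejected(self):
        pos = np.zeros((5, 1, 2))
        with pytest.raises(ValueError):
            bm.pairwise_distance_stats(make_trial(pos))

    def test_dataset_radius_single_pair(self):
        pos = np.zeros((10, 2, 2))
        pos[:, 1, 0] = 5.0
        assert bm.dataset_neighbour_radius([make_trial(pos)]) == 5.0

    def test_dataset_radius_matches_flatten_sort_oracle(self, rng, arena):
        trials = []
        pools = []
        for k in range(3):
            pos = rng.uniform(-8, 8, size=(30, 3, 2))
            trial = make_trial(pos)
            trials.append(trial)
            pools.extend(oracle_pairwise(trial)[1])
        got = bm.dataset_neighbour_radius(trials)
        assert got == pytest.approx(float(np.median(pools)))

    def test_local_neighbour_extremes(self):
        pos = np.zeros((10, 10, 2))          # all coincident
        out = bm.mean_local_neighbour_prop(make_trial(pos), radius_cm=6.9)
        np.testing.assert_allclose(out, 1.0)
        spread = np.zeros((5, 3, 2))
        spread[:, 1, 0] = 10.0
        spread[:, 2, 1] = 10.0
        out = bm.mean_local_neighbour_prop(make_trial(spread), radius_cm=2.0)
        np.testing.assert_allclose(out, 0.0)

    def test_local_neighbour_matches_count_oracle(self, random_walk_trial):
        radius = 3.0
        got = bm.mean_local_neighbour_prop(random_walk_trial, radius)
        P = random_walk_trial.positions()
        T, n = P.shape[:2]
        for i in range(n):
            vals = []
            for t in range(T):
                if np.isnan(P[t, i]).any():
                    continue
                c = sum(1 for j in range(n) if j != i
                        and not np.isnan(P[t, j]).any()
                        and math.hypot(*(P[t, i] - P[t, j])) < radius)
                vals.append(c / (n - 1))
            assert got[i] == pytest.approx(float(np.mean(vals)))


# -------------------------------------------------------------- profiles
class TestProfiles:
    def test_one_profile_per_fish(self, arena, grid, random_walk_trial):
        profs = bm.build_behavioural_profile(random_walk_trial, arena,
                                             grid=grid)
        assert len(profs) == random_walk_trial.n_fish

    def test_rotation_invariance(self, arena, grid, random_walk_trial):
        cfg = bm.MetricsConfig(neighbour_radius_cm=3.0)
        base = bm.build_behavioural_profile(random_walk_trial, arena, cfg,
                                            grid=grid)
        ang = 2 * np.pi / 3
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        rot = make_trial(random_walk_trial.positions() @ R.T)
        rotated = bm.build_behavioural_profile(rot, arena, cfg, grid=grid)
        for a, b in zip(base, rotated):
            # grid-based quantities change cells under rotation but only
            # slightly in value; point-wise metrics are exact
            assert a.median_speed == pytest.approx(b.median_speed)
            assert a.prop_still == pytest.approx(b.prop_still)
            assert a.prop_near_edge == pytest.approx(b.prop_near_edge)
            assert a.median_nn_distance == pytest.approx(b.median_nn_distance)
            assert a.mean_local_neighbour_prop == pytest.approx(
                b.mean_local_neighbour_prop)

    def test_permutation_invariance(self, arena, grid, random_walk_trial):
        cfg = bm.MetricsConfig(neighbour_radius_cm=3.0)
        base = bm.build_behavioural_profile(random_walk_trial, arena, cfg,
                                            grid=grid)
        perm = [2, 0, 1]
        shuffled = make_trial(random_walk_trial.positions()[:, perm, :])
        out = bm.build_behavioural_profile(shuffled, arena, cfg, grid=grid)
        for k_new, k_old in enumerate(perm):
            a, b = base[k_old], out[k_new]
            for field in ("median_speed", "prop_still", "prop_near_edge",
                          "pct_arena_explored", "median_nn_distance",
                          "mean_local_neighbour_prop"):
                assert getattr(a, field) == pytest.approx(
                    getattr(b, field)), field

    def test_time_reversal_preserves_occupancy_metrics(self, arena, grid,
                                                       random_walk_trial):
        cfg = bm.MetricsConfig(neighbour_radius_cm=3.0)
        base = bm.build_behavioural_profile(random_walk_trial, arena, cfg,
                                            grid=grid)
        rev = make_trial(random_walk_trial.positions()[::-1])
        out = bm.build_behavioural_profile(rev, arena, cfg, grid=grid)
        for a, b in zip(base, out):
            assert a.prop_still == pytest.approx(b.prop_still)
            assert a.pct_arena_explored == pytest.approx(b.pct_arena_explored)
            assert a.median_nn_distance == pytest.approx(b.median_nn_distance)

    def test_trial_level_aggregation(self, arena, grid, random_walk_trial):
        cfg = bm.MetricsConfig(neighbour_radius_cm=3.0, per_trial=True)
        profs = bm.build_behavioural_profile(random_walk_trial, arena, cfg,
                                             grid=grid)
        assert len(profs) == 1
        assert profs[0].unit_id == random_walk_trial.trial_id
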