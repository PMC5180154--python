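"""Agent-based null model: non-interacting fish with empirical kinematics.

Each simulated fish performs a correlated random walk whose per-frame
speeds v and heading changes (angular speeds) omega are drawn uniformly,
with replacement, from pools harvested from observed trajectories:

    x(t+1) = x(t) + v(t) * cos(theta(t) + omega(t))
    y(t+1) = y(t) + v(t) * sin(theta(t) + omega(t))
    theta(t+1) = theta(t) + omega(t)

Fish are independent — the model deliberately contains no attraction,
alignment or wall-following, so differences between real groups and this
null quantify social and environmental structure in the real data.  Steps
landing outside the arena are replaced by the radially symmetric point
about the boundary circle (r -> 2R - r at the same polar angle); the
heading is unchanged by reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (ArenaGeometry, RecordingMeta, Trajectory, TrialRecording,
                   wrap_angle)
from .preprocess import compute_displacements

#: Displacements below one pixel leave the heading undefined.
MIN_HEADING_DISPLACEMENT_CM = 0.029


@dataclass
class EmpiricalMovementPools:
    """Per-frame speed (cm/frame) and angular-speed (rad/frame) draws
    harvested from cleaned trajectories."""

    speeds: np.ndarray
    angular_speeds: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.angular_speeds = np.asarray(self.angular_speeds, dtype=float)
        if self.speeds.size == 0 or self.angular_speeds.size == 0:
            raise ValueError("empirical pools must be non-empty")
        if (self.speeds < 0).any():
            raise ValueError("speeds must be >= 0")


@dataclass
class SimulationConfig:
    """Null-model run parameters (defaults match the experimental design)."""

    n_fish: int = 10
    duration_frames: int = 90_000
    frame_rate: float = 25.0
    n_replicates: int = 26
    seed: int = 0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    reflect_heading: bool = False

    def __post_init__(self) -> None:
        if min(self.n_fish, self.duration_frames, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")


def harvest_pools(trials: Iterable[TrialRecording],
                  min_heading_displacement_cm: float = MIN_HEADING_DISPLACEMENT_CM
                  ) -> EmpiricalMovementPools:
    """Pool per-frame speeds and heading changes across all fish and trials.

    Headings are atan2 of successive displacements; a frame contributes an
    angular speed only when both the incoming and outgoing displacement are
    at least ``min_heading_displacement_cm`` (sub-pixel moves have no
    defined direction).
    """
    v_pool: List[np.ndarray] = []
    w_pool: List[np.ndarray] = []
    provenance = []
    for trial in trials:
        provenance.append(trial.trial_id)
        for tr in trial.trajectories:
            d = compute_displacements(tr)
            v_pool.append(d[np.isfinite(d)])
            dx = np.diff(tr.x)
            dy = np.diff(tr.y)
            disp = np.hypot(dx, dy)
            heading = np.arctan2(dy, dx)
            defined = np.isfinite(disp) & (disp >= min_heading_displacement_cm)
            ok = defined[:-1] & defined[1:]
            w = wrap_angle(heading[1:] - heading[:-1])
            w_pool.append(np.asarray(w)[ok])
    if not v_pool:
        raise ValueError("no trials supplied")
    speeds = np.concatenate(v_pool)
    omegas = np.concatenate(w_pool)
    if speeds.size == 0 or omegas.size == 0:
        raise ValueError("empirical pools are empty after filtering")
    return EmpiricalMovementPools(speeds=speeds, angular_speeds=omegas,
                                  provenance=provenance)


def reflect_into_arena(point: Sequence[float], arena: ArenaGeometry
                       ) -> Tuple[float, float]:
    """Mirror a point about the boundary circle: r -> 2R - r, same angle.

    Points at r <= R are returned unchanged.  A point beyond 2R cannot be
    mirrored inside; it is clamped to the centre (logged) — unreachable
    when every pooled speed is below the arena radius.
    """
    x, y = float(point[0]), float(point[1])
    R = arena.radius_cm
    r = np.hypot(x, y)
    if r <= R:
        return x, y
    r_new = 2 * R - r
    if r_new < 0:
        warnings.warn("point beyond 2R clamped to arena centre", stacklevel=2)
        r_new = 0.0
    f = r_new / r
    return x * f, y * f


def _reflect_array(pos: np.ndarray, R: float) -> np.ndarray:
    """Vectorised radial mirror for an (n, 2) position block (in place)."""
    r = np.hypot(pos[:, 0], pos[:, 1])
    out = r > R
    if out.any():
        r_new = np.maximum(2 * R - r[out], 0.0)
        with np.errstate(invalid="ignore"):
            f = np.where(r[out] > 0, r_new / r[out], 0.0)
        pos[out] *= f[:, None]
    return pos


def step_agent(state: Tuple[float, float, float], v: float, omega: float,
               arena: ArenaGeometry) -> Tuple[float, float, float]:
    """Advance one agent one frame; returns (x, y, theta)."""
    x, y, theta = state
    theta_new = float(wrap_angle(theta + omega))
    nx = x + v * np.cos(theta_new)
    ny = y + v * np.sin(theta_new)
    nx, ny = reflect_into_arena((nx, ny), arena)
    return nx, ny, theta_new


def _simulate_replicate(pools: EmpiricalMovementPools,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """One replicate: (T, n_fish, 2) positions, all inside the arena."""
    n, T, R = config.n_fish, config.duration_frames, config.arena.radius_cm
    # initial conditions: uniform in the disc, uniform headings
    r0 = R * np.sqrt(rng.uniform(size=n))
    a0 = rng.uniform(-np.pi, np.pi, size=n)
    pos = np.stack([r0 * np.cos(a0), r0 * np.sin(a0)], axis=1)
    theta0 = rng.uniform(-np.pi, np.pi, size=n)

    v = pools.speeds[rng.integers(pools.speeds.size, size=(T - 1, n))]
    w = pools.angular_speeds[
        rng.integers(pools.angular_speeds.size, size=(T - 1, n))]

    out = np.empty((T, n, 2))
    out[0] = pos
    if not config.reflect_heading:
        # heading never depends on position: precompute all steps at once
        theta = wrap_angle(theta0[None, :] + np.cumsum(w, axis=0))
        steps = np.stack([v * np.cos(theta), v * np.sin(theta)], axis=2)
        for t in range(1, T):
            pos = pos + steps[t - 1]
            pos = _reflect_array(pos, R)
            out[t] = pos
    else:
        theta = theta0.copy()
        for t in range(1, T):
            theta = np.asarray(wrap_angle(theta + w[t - 1]))
            cand = pos + np.stack([v[t - 1] * np.cos(theta),
                                   v[t - 1] * np.sin(theta)], axis=1)
            r = np.hypot(cand[:, 0], cand[:, 1])
            hit = r > R
            cand = _reflect_array(cand, R)
            if hit.any():
                # reflected fish face their mirrored direction of travel
                theta[hit] = np.arctan2(cand[hit, 1] - pos[hit, 1],
                                        cand[hit, 0] - pos[hit, 0])
            pos = cand
            out[t] = pos
    return out


def run_null_model(config: SimulationConfig,
                   pools: EmpiricalMovementPools) -> List[TrialRecording]:
    """Run ``config.n_replicates`` independent null-model trials.

    Reproducible: a single master seed spawns one substream per replicate.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    trials = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pos = _simulate_replicate(pools, config, rng)
        meta = RecordingMeta(frame_rate=config.frame_rate,
                             duration_frames=config.duration_frames,
                             condition="simulated",
                             batch_id=f"sim{k // 3}",
                             pixel_scale=config.arena.pixel_scale)
        trial_id = f"sim{k + 1:02d}"
        trajs = [Trajectory(pos[:, i, 0], pos[:, i, 1],
                            fish_id=f"{trial_id}/f{i+1}", meta=meta)
                 for i in range(config.n_fish)]
        trials.append(TrialRecording(trajectories=trajs, meta=meta,
                                     trial_id=trial_id))
    return trials


#: Variables compared between real and simulated fish — exactly those not
#: used to build the simulation (speed and stillness are coded into it).
COMPARED_VARIABLES = (
    "prop_near_edge",
    "time_to_explore_10pct",
    "pct_arena_explored",
    "mean_local_neighbour_prop",
    "median_nn_distance",
)


def compare_real_vs_sim(real_profiles, sim_profiles,
                        impute_missing_time: bool = True) -> pd.DataFrame:
    """Linear models of each non-coded variable on data type, plus a
    variance-homogeneity (Brown–Forsythe/Levene) test per variable.

    The factor codes real = 1 against simulated = 0, so a positive
    estimate means the value is higher in real fish.  Fish that never
    reached the 10% exploration threshold have their time imputed as the
    trial duration (censoring at the recording length).
    """
    import statsmodels.api as sm
    from scipy import stats as sps

    from .io_trajectories import profiles_to_frame

    real = profiles_to_frame(real_profiles)
    sim = profiles_to_frame(sim_profiles)
    rows = []
    for var in COMPARED_VARIABLES:
        a = real[var].to_numpy(dtype=float).copy()
        b = sim[var].to_numpy(dtype=float).copy()
        if var == "time_to_explore_10pct" and impute_missing_time:
            a[~np.isfinite(a)] = real["duration_s"][~np.isfinite(a)]
            b[~np.isfinite(b)] = sim["duration_s"][~np.isfinite(b)]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        y = np.concatenate([a, b])
        g = np.concatenate([np.ones(a.size), np.zeros(b.size)])
        X = sm.add_constant(g)
        fit = sm.OLS(y, X).fit()
        lev = sps.levene(a, b, center="median")
        rows.append(dict(variable=var,
                         estimate=fit.params[1], se=fit.bse[1],
                         t=fit.tvalues[1], p=fit.pvalues[1],
                         levene_stat=lev.statistic, levene_p=lev.pvalue,
                         var_real=float(np.var(a, ddof=1)),
                         var_sim=float(np.var(b, ddof=1)),
                         n_real=a.size, n_sim=b.size))
    return pd.DataFrame(rows)
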