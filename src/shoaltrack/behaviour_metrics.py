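"""The seven behavioural variables for shoaling fish in a circular arena.

Activity: median instantaneous speed; proportion of time still (movement of
less than one pixel between frames, ~0.7 cm/s at 25 Hz).  Reaction to the
arena: proportion of time in the edge zone (thigmotaxis); time to explore
10% of the arena; overall fraction of the arena explored, on a grid of
1 x 1 cm squares.  Social: median nearest-neighbour distance, and the mean
proportion of the group within the local-neighbour radius (dataset-wide
median inter-fish distance; 6.9 cm in the original dataset).

Frames where a fish is missing are excluded from that fish's denominators;
fish pairs with a missing member are excluded from distance pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .core import (ArenaGeometry, BehaviouralProfile, Trajectory,
                   TrialRecording)
from .preprocess import compute_displacements, compute_instantaneous_speeds

#: Local-neighbour radius of the original dataset (cm): the pooled median
#: inter-fish distance.  Used as the documented default when no trials are
#: available to pool.
DEFAULT_NEIGHBOUR_RADIUS_CM = 6.9

#: One pixel of displacement per frame, in cm — the stillness cutoff.
DEFAULT_STILL_THRESHOLD_CM = 0.029


@dataclass
class MetricsConfig:
    """Tunable parameters of the metric stage (all logged into outputs)."""

    still_threshold_cm: float = DEFAULT_STILL_THRESHOLD_CM
    neighbour_radius_cm: float | None = None   # None -> pooled median
    explore_fraction: float = 0.10
    per_trial: bool = False                    # aggregate to one profile/trial


@dataclass
class ExplorationGrid:
    """The set of 1 x 1 cm (by default) squares that make up the arena.

    Cells are indexed by their lower-left corner in units of
    ``cell_size``; the grid is corner-aligned on the arena centre.  Under
    the default ``intersects_disc`` convention a cell belongs to the arena
    when the nearest point of the square lies strictly inside the disc.
    """

    cell_size: float
    cells: set = field(default_factory=set)
    convention: str = "intersects_disc"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Integer (i, j) cell indices of points (vectorised)."""
        i = np.floor(x / self.cell_size).astype(int)
        j = np.floor(y / self.cell_size).astype(int)
        return np.stack([i, j], axis=-1)


@dataclass
class NeighbourContext:
    """Missing-aware pairwise geometry of one trial.

    ``distances`` has shape (n_frames, n_fish, n_fish) with NaN on the
    diagonal-excluded entries involving a missing fish;
    ``nn_distance`` is each fish's per-frame distance to its closest
    group-mate.
    """

    distances: np.ndarray
    nn_distance: np.ndarray
    median_interfish_cm: float
    radius_cm: float | None = None


def median_speed(traj: Trajectory, frame_rate: float | None = None) -> float:
    """Median of valid instantaneous speeds, cm/s (NaN + warning if none)."""
    s = compute_instantaneous_speeds(traj, frame_rate)
    s = s[np.isfinite(s)]
    if s.size == 0:
        warnings.warn(f"{traj.fish_id}: no valid speeds", stacklevel=2)
        return float("nan")
    return float(np.median(s))


def proportion_still(traj: Trajectory,
                     still_threshold_cm: float = DEFAULT_STILL_THRESHOLD_CM
                     ) -> float:
    """Fraction of valid frame pairs with sub-pixel displacement."""
    d = compute_displacements(traj)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    return float((d < still_threshold_cm).mean())


def proportion_near_edge(traj: Trajectory, arena: ArenaGeometry) -> float:
    """Fraction of valid frames inside the thigmotaxis band at the wall."""
    r = traj.r[traj.valid]
    if r.size == 0:
        return float("nan")
    return float((r > arena.radius_cm - arena.edge_zone_width_cm).mean())


def build_exploration_grid(arena: ArenaGeometry) -> ExplorationGrid:
    """Enumerate the grid cells covering the arena disc.

    ``intersects_disc``: a cell counts when its nearest point to the centre
    is strictly closer than the radius.  ``centre_in_disc``: the cell's
    centre must lie strictly inside.
    """
    c = arena.grid_cell_cm
    R = arena.radius_cm
    m = int(np.ceil(R / c))
    cells = set()
    for i in range(-m, m):
        for j in range(-m, m):
            x0, x1 = i * c, (i + 1) * c
            y0, y1 = j * c, (j + 1) * c
            if arena.grid_convention == "centre_in_disc":
                d = np.hypot((x0 + x1) / 2, (y0 + y1) / 2)
            else:
                nx = x0 if x0 > 0 else (x1 if x1 < 0 else 0.0)
                ny = y0 if y0 > 0 else (y1 if y1 < 0 else 0.0)
                d = np.hypot(nx, ny)
            if d < R:
                cells.add((i, j))
    return ExplorationGrid(cell_size=c, cells=cells,
                           convention=arena.grid_convention)


def exploration_stats(traj: Trajectory, grid: ExplorationGrid,
                      frame_rate: float | None = None,
                      explore_fraction: float = 0.10
                      ) -> Tuple[float, float]:
    """(time to explore ``explore_fraction`` of the arena in s, final
    fraction explored).

    The time is the first frame at which the number of distinct visited
    cells reaches ``ceil(explore_fraction * n_cells)``, converted to
    seconds; NaN when never reached.
    """
    if frame_rate is None:
        frame_rate = traj.meta.frame_rate if traj.meta else 25.0
    valid = traj.valid
    frames = np.flatnonzero(valid)
    if frames.size == 0:
        return float("nan"), 0.0
    ij = grid.cell_of(traj.x[frames], traj.y[frames])
    # keep only points whose cell is in the grid (boundary-contact points
    # clamped exactly to R can fall in an excluded tangent cell)
    keys = [tuple(p) for p in ij]
    in_grid = np.array([k in grid.cells for k in keys])
    frames = frames[in_grid]
    keys = [k for k, ok in zip(keys, in_grid) if ok]
    if not keys:
        return float("nan"), 0.0
    seen: set = set()
    threshold = int(np.ceil(explore_fraction * grid.n_cells))
    t_reach = float("nan")
    for f, k in zip(frames, keys):
        if k not in seen:
            seen.add(k)
            if np.isnan(t_reach) and len(seen) >= threshold:
                t_reach = f / frame_rate
    return t_reach, len(seen) / grid.n_cells


def pairwise_distance_stats(trial: TrialRecording) -> NeighbourContext:
    """All-pairs inter-fish distances, per-frame nearest neighbours, and
    the trial's median inter-fish distance."""
    pos = trial.positions()                      # (T, n, 2)
    n = trial.n_fish
    if n < 2:
        raise ValueError("need at least 2 fish for pairwise distances")
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])  # NaN if a member missing
    ii = np.arange(n)
    dist[:, ii, ii] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        nn = np.nanmin(dist, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    pool = dist[:, iu, ju].ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no frame has two co-visible fish")
    return NeighbourContext(distances=dist, nn_distance=nn,
                            median_interfish_cm=float(np.median(pool)))


def dataset_neighbour_radius(trials: Iterable[TrialRecording]) -> float:
    """Median of all pairwise inter-fish distances pooled over all frames,
    pairs and trials — the local-neighbour radius."""
    pools = []
    for trial in trials:
        dist = pairwise_distance_stats(trial).distances
        iu, ju = np.triu_indices(trial.n_fish, k=1)
        p = dist[:, iu, ju].ravel()
        pools.append(p[np.isfinite(p)])
    if not pools:
        raise ValueError("no trials supplied")
    return float(np.median(np.concatenate(pools)))


def mean_local_neighbour_prop(trial: TrialRecording,
                              radius_cm: float = DEFAULT_NEIGHBOUR_RADIUS_CM,
                              context: NeighbourContext | None = None
                              ) -> np.ndarray:
    """Per fish: mean over its valid frames of the proportion of the group
    (out of n-1) within ``radius_cm``."""
    if radius_cm <= 0:
        raise ValueError("radius_cm must be > 0")
    if context is None:
        context = pairwise_distance_stats(trial)
    dist = context.distances
    n = trial.n_fish
    within = (dist < radius_cm)          # NaN -> False: missing don't count
    counts = within.sum(axis=2) / (n - 1)
    out = np.empty(n)
    for i, tr in enumerate(trial.trajectories):
        v = tr.valid
        out[i] = counts[v, i].mean() if v.any() else np.nan
    return out


def build_behavioural_profile(trial: TrialRecording, arena: ArenaGeometry,
                              config: MetricsConfig | None = None,
                              grid: ExplorationGrid | None = None
                              ) -> List[BehaviouralProfile]:
    """Assemble the seven variables for every fish in a trial (or, with
    ``config.per_trial``, a single trial-level profile using medians of
    speed/NND pooled across fish and means of the per-fish values for the
    remaining variables)."""
    config = config or MetricsConfig()
    if grid is None:
        grid = build_exploration_grid(arena)
    meta = trial.meta
    ctx = pairwise_distance_stats(trial)
    radius = config.neighbour_radius_cm or ctx.median_interfish_cm
    ctx.radius_cm = radius
    local_prop = mean_local_neighbour_prop(trial, radius, context=ctx)
    duration_s = trial.n_frames / meta.frame_rate

    profiles = []
    for i, tr in enumerate(trial.trajectories):
        try:
            t10, pct = exploration_stats(tr, grid, meta.frame_rate,
                                         config.explore_fraction)
            nnd = ctx.nn_distance[tr.valid, i]
            nnd = nnd[np.isfinite(nnd)]
            profiles.append(BehaviouralProfile(
                median_speed=median_speed(tr, meta.frame_rate),
                prop_still=proportion_still(tr, config.still_threshold_cm),
                prop_near_edge=proportion_near_edge(tr, arena),
                time_to_explore_10pct=t10,
                pct_arena_explored=pct,
                median_nn_distance=float(np.median(nnd)) if nnd.size else float("nan"),
                mean_local_neighbour_prop=float(local_prop[i]),
                unit_id=tr.fish_id,
                condition=meta.condition,
                batch_id=meta.batch_id,
                duration_s=duration_s))
        except ValueError as err:
            raise ValueError(f"fish {tr.fish_id}: {err}") from err

    if not config.per_trial:
        return profiles

    df = {k: np.array([getattr(p, k) for p in profiles])
          for k in ("median_speed", "prop_still", "prop_near_edge",
                    "time_to_explore_10pct", "pct_arena_explored",
                    "mean_local_neighbour_prop")}
    nn_pool = ctx.nn_distance[np.isfinite(ctx.nn_distance)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = BehaviouralProfile(
            median_speed=float(np.nanmedian(df["median_speed"])),
            prop_still=float(np.nanmean(df["prop_still"])),
            prop_near_edge=float(np.nanmean(df["prop_near_edge"])),
            time_to_explore_10pct=float(np.nanmean(df["time_to_explore_10pct"])),
            pct_arena_explored=float(np.nanmean(df["pct_arena_explored"])),
            median_nn_distance=float(np.median(nn_pool)) if nn_pool.size else float("nan"),
            mean_local_neighbour_prop=float(np.nanmean(df["mean_local_neighbour_prop"])),
            unit_id=trial.trial_id,
            condition=meta.condition,
            batch_id=meta.batch_id,
            duration_s=duration_s)
    return [agg]
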