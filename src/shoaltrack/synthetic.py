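"""Synthetic schooling-fish trials with known latent behaviour parameters.

No trajectory data ship with this package, so every pipeline stage is
exercised on generated trials.  The motion kernel extends the null-model
correlated random walk with two steering terms:

* **attraction** — each fish turns towards the group centroid
  (sociability latent);
* **wall bias** — each fish turns towards the tangent at the nearest
  wall point, blended with an outward component that fades as it nears
  the wall (thigmotaxis / boldness latent);

plus wrapped-normal heading noise.  Per-frame speed is zero with the
stillness probability, otherwise exponential with mean ``speed_scale``
(capped below the physiological speed filter), so activity is a third
independent latent.  The kernel is deliberately minimal: it produces the
qualitative social / boldness / activity contrasts the analysis must
detect, not a validated schooling model.

:func:`inject_tracking_artifacts` corrupts a clean trial the way video
trackers do — missing-detection gaps, mirror-reflection spikes outside
the arena, and identity swaps — while a ledger records the exact ground
truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (ArenaGeometry, RawTrackTable, RecordingMeta, Trajectory,
                   TrialRecording, wrap_angle)
from .null_model import _reflect_array

#: Per-frame speed cap (cm/frame): keeps clean kinematics below the
#: 91 cm/s cleaning threshold (3.64 cm/frame at 25 Hz).
SPEED_CAP_CM_PER_FRAME = 3.5


@dataclass
class SchoolLatents:
    """Per-trial latent behaviour parameters of the synthetic kernel."""

    attraction_strength: float = 0.02   # rad of turn per rad of bearing error
    wall_bias: float = 0.12
    stillness_prob: float = 0.30
    speed_scale: float = 0.18           # cm/frame (~4.5 cm/s at 25 Hz)
    turn_sigma: float = 0.60            # rad/frame heading noise
    #: preferred distance from the wall (cm): the thigmotaxis target ring
    #: sits at arena radius minus this inset
    wall_preference_inset_cm: float = 1.5

    def __post_init__(self) -> None:
        if self.attraction_strength < 0 or self.wall_bias < 0:
            raise ValueError("steering gains must be >= 0")
        if not 0.0 <= self.stillness_prob <= 1.0:
            raise ValueError("stillness_prob must be in [0, 1]")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be > 0")


@dataclass
class SyntheticCohortConfig:
    """Study-scale defaults: 26 trials (9 + 9 + 8 across three condition
    labels), 10 fish, 25 Hz.  Test-scale duration (9 000 frames = 6 min)
    keeps suites fast; the full 90 000-frame hour is one parameter away.
    """

    n_trials: int = 26
    n_fish: int = 10
    duration_frames: int = 9_000
    frame_rate: float = 25.0
    seed: int = 0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    conditions: tuple = ("ambient", "OA", "ambient_in_OA")
    condition_sizes: tuple = (9, 9, 8)
    #: additive shifts applied to latents per condition, e.g.
    #: {"OA": {"attraction_strength": 0.1}}; empty -> true null cohort
    condition_effects: dict = field(default_factory=dict)
    #: across-trial latent s.d. around the SchoolLatents defaults
    latent_sd: dict = field(default_factory=lambda: dict(
        attraction_strength=0.008, wall_bias=0.04,
        stillness_prob=0.06, speed_scale=0.03))
    base_latents: SchoolLatents = field(default_factory=SchoolLatents)
    gap_rate: float = 0.0
    spike_rate: float = 0.0
    swap_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials != sum(self.condition_sizes):
            raise ValueError("condition_sizes must sum to n_trials")
        if self.duration_frames < 2:
            raise ValueError("duration_frames must be >= 2")
        for r in (self.gap_rate, self.spike_rate, self.swap_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("artifact rates must be in [0, 1)")


@dataclass
class GroundTruthLedger:
    """Exact record of what was generated and what was corrupted."""

    latents: Optional[SchoolLatents] = None
    gaps: List[Tuple[int, int, int]] = field(default_factory=list)    # fish, start, length
    spikes: List[Tuple[int, int]] = field(default_factory=list)       # fish, frame
    swaps: List[Tuple[int, int, int, int]] = field(default_factory=list)  # fishA, fishB, start, length

    @property
    def n_gap_frames(self) -> int:
        return sum(g[2] for g in self.gaps)


#: Radial error is expressed in units of this band width and clipped.
WALL_RING_BAND_CM = 2.0


def _wall_heading_error(pos: np.ndarray, theta: np.ndarray, R: float,
                        inset_cm: float = 1.5) -> np.ndarray:
    """Signed heading error towards the thigmotaxis target direction.

    The target blends the wall tangent (in whichever sense is closer to
    the current heading) with a radial correction towards a preference
    ring just inside the wall: interior fish steer outwards, fish beyond
    the ring steer back in, and fish on the ring follow it.  Steering
    only turns the heading, so boldness leaves the speed distribution
    untouched.
    """
    x, y = pos[:, 0], pos[:, 1]
    r = np.hypot(x, y)
    safe = r > 1e-9
    phi = np.arctan2(y, x)
    # tangent sense closest to current heading
    tx, ty = -np.sin(phi), np.cos(phi)
    s = np.where(np.cos(theta) * tx + np.sin(theta) * ty >= 0, 1.0, -1.0)
    rad = np.clip((R - inset_cm - r) / WALL_RING_BAND_CM, -1.5, 1.5)
    vx = s * tx + rad * np.cos(phi)
    vy = s * ty + rad * np.sin(phi)
    err = wrap_angle(np.arctan2(vy, vx) - theta)
    return np.where(safe, err, 0.0)


def generate_school(latents: SchoolLatents, rng: np.random.Generator,
                    n_fish: int = 10, duration_frames: int = 9_000,
                    frame_rate: float = 25.0,
                    arena: ArenaGeometry | None = None,
                    condition: str = "synthetic", batch_id: str = "0",
                    trial_id: str = "synth") -> Tuple[TrialRecording,
                                                      GroundTruthLedger]:
    """Simulate one group trial of interacting synthetic fish."""
    arena = arena or ArenaGeometry()
    R = arena.radius_cm
    n, T = n_fish, duration_frames

    r0 = R * np.sqrt(rng.uniform(size=n))   # uniform over the disc
    a0 = rng.uniform(-np.pi, np.pi, size=n)
    pos = np.stack([r0 * np.cos(a0), r0 * np.sin(a0)], axis=1)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    noise = rng.normal(0.0, latents.turn_sigma, size=(T - 1, n))
    still = rng.uniform(size=(T - 1, n)) < latents.stillness_prob
    v = np.minimum(rng.exponential(latents.speed_scale, size=(T - 1, n)),
                   SPEED_CAP_CM_PER_FRAME)
    v[still] = 0.0

    out = np.empty((T, n, 2))
    out[0] = pos
    for t in range(1, T):
        centroid = pos.mean(axis=0)
        err_c = wrap_angle(np.arctan2(centroid[1] - pos[:, 1],
                                      centroid[0] - pos[:, 0]) - theta)
        err_w = _wall_heading_error(pos, theta, R,
                                    latents.wall_preference_inset_cm)
        omega = (noise[t - 1]
                 + latents.attraction_strength * err_c
                 + latents.wall_bias * err_w)
        theta = np.asarray(wrap_angle(theta + omega))
        step = np.stack([v[t - 1] * np.cos(theta),
                         v[t - 1] * np.sin(theta)], axis=1)
        pos = _reflect_array(pos + step, R)
        out[t] = pos

    meta = RecordingMeta(frame_rate=frame_rate, duration_frames=T,
                         condition=condition, batch_id=batch_id,
                         pixel_scale=arena.pixel_scale)
    trajs = [Trajectory(out[:, i, 0], out[:, i, 1],
                        fish_id=f"{trial_id}/f{i+1}", meta=meta)
             for i in range(n)]
    trial = TrialRecording(trajectories=trajs, meta=meta, trial_id=trial_id)
    return trial, GroundTruthLedger(latents=latents)


def _draw_trial_latents(config: SyntheticCohortConfig, condition: str,
                        rng: np.random.Generator) -> SchoolLatents:
    base = config.base_latents
    sd = config.latent_sd
    eff = config.condition_effects.get(condition, {})

    def draw(name, lo, hi):
        v = getattr(base, name) + rng.normal(0.0, sd.get(name, 0.0))
        v += eff.get(name, 0.0)
        return float(np.clip(v, lo, hi))

    return SchoolLatents(
        attraction_strength=draw("attraction_strength", 0.0, 1.0),
        wall_bias=draw("wall_bias", 0.0, 1.0),
        stillness_prob=draw("stillness_prob", 0.0, 0.95),
        speed_scale=draw("speed_scale", 0.02, 1.0),
        turn_sigma=base.turn_sigma)


def generate_cohort(config: SyntheticCohortConfig
                    ) -> List[Tuple[TrialRecording, GroundTruthLedger]]:
    """Generate a full cohort of clean trials: condition labels assigned
    9 + 9 + 8, batches of three trials recorded together (experiment
    number), reproducible from the config seed."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    conditions = [c for c, k in zip(config.conditions, config.condition_sizes)
                  for _ in range(k)]
    # interleave conditions so batches of 3 mix conditions where possible
    order = np.argsort(np.tile(np.arange(max(config.condition_sizes)),
                               len(config.conditions))[:config.n_trials],
                       kind="stable")
    conditions = [conditions[i] for i in order]
    out = []
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        lat = _draw_trial_latents(config, conditions[t], rng)
        trial, ledger = generate_school(
            lat, rng, n_fish=config.n_fish,
            duration_frames=config.duration_frames,
            frame_rate=config.frame_rate, arena=config.arena,
            condition=conditions[t], batch_id=f"b{t // 3}",
            trial_id=f"synth{t + 1:02d}")
        out.append((trial, ledger))
    return out


def inject_tracking_artifacts(trial: TrialRecording,
                              rng: np.random.Generator,
                              arena: ArenaGeometry | None = None,
                              gap_rate: float = 0.0,
                              spike_rate: float = 0.0,
                              swap_rate: float = 0.0,
                              centre_px: Tuple[float, float] = (512.0, 512.0),
                              max_gap_frames: int = 40,
                              swap_len_range: Tuple[int, int] = (25, 250),
                              ledger: GroundTruthLedger | None = None
                              ) -> Tuple[RawTrackTable, GroundTruthLedger]:
    """Corrupt a clean trial into tracker-style raw pixel output.

    * gaps: with probability ``gap_rate`` per fish-frame a run of 1–40
      frames is blanked (missed detections);
    * spikes: with probability ``spike_rate`` a detection is replaced by a
      mirror-reflection point at radius (R, 1.2 R] outside the arena;
    * swaps: with probability ``swap_rate`` per frame two fish exchange
      identities for 25–250 frames (teleports at both ends).

    All rates zero returns the input coordinates unchanged (in pixels).
    The returned ledger exactly describes the corruption.
    """
    arena = arena or ArenaGeometry()
    ledger = ledger or GroundTruthLedger()
    scale = arena.pixel_scale
    R_px = arena.radius_cm / scale
    cx, cy = centre_px
    pos = trial.positions() / scale
    pos[:, :, 0] += cx
    pos[:, :, 1] += cy
    T, n = pos.shape[0], pos.shape[1]

    if gap_rate > 0:
        for i in range(n):
            starts = np.flatnonzero(rng.uniform(size=T) < gap_rate)
            for s in starts:
                if np.isnan(pos[s, i, 0]):
                    continue  # already inside an earlier gap
                length = int(min(rng.integers(1, max_gap_frames + 1), T - s))
                pos[s:s + length, i, :] = np.nan
                ledger.gaps.append((i, int(s), length))

    if spike_rate > 0:
        for i in range(n):
            hits = np.flatnonzero((rng.uniform(size=T) < spike_rate)
                                  & ~np.isnan(pos[:, i, 0]))
            for f in hits:
                rr = R_px * rng.uniform(1.001, 1.2)
                aa = rng.uniform(-np.pi, np.pi)
                pos[f, i, 0] = cx + rr * np.cos(aa)
                pos[f, i, 1] = cy + rr * np.sin(aa)
                ledger.spikes.append((i, int(f)))

    if swap_rate > 0 and n >= 2:
        starts = np.flatnonzero(rng.uniform(size=T) < swap_rate)
        for s in starts:
            a, b = rng.choice(n, size=2, replace=False)
            length = int(min(rng.integers(*swap_len_range), T - s))
            block = pos[s:s + length, a, :].copy()
            pos[s:s + length, a, :] = pos[s:s + length, b, :]
            pos[s:s + length, b, :] = block
            ledger.swaps.append((int(a), int(b), int(s), length))

    raw = RawTrackTable(positions=pos, source_id=trial.trial_id)
    return raw, ledger


#: Across-trial latent spread representative of real groups of fish, which
#: differ in cohesion, wall affinity and activity from group to group.
#: Used for real-vs-null comparisons, where the heterogeneity of real
#: groups (against the homogeneous null model) is the point.
HETEROGENEOUS_LATENT_SD = dict(attraction_strength=0.012, wall_bias=0.06,
                               stillness_prob=0.08, speed_scale=0.04)

#: Latent ranges for the planted three-factor cohort.  Each trial draws
#: three independent uniform latents — sociability, boldness, activity —
#: mapped to kernel parameters so that each behavioural block is dominated
#: by exactly one latent axis.
PCA_LATENT_RANGES = dict(
    attraction=(0.03, 0.12),        # sociability axis
    wall_inset_cm=(5.5, 2.0),       # boldness axis: preferred wall offset,
    #                                 bolder trials prefer a ring nearer the
    #                                 wall (steering gain held fixed below)
    wall_gain=0.25,
    speed_scale=(0.14, 0.16),       # activity axis ...
    stillness=(0.34, 0.30),         # ... high activity -> little stillness
)


def _orthogonal_latin_latents(n: int, k: int, rng: np.random.Generator,
                              n_sweeps: int = 200) -> np.ndarray:
    """Stratified uniform latent design with near-zero sample correlation.

    Latin-hypercube draws (one stratum per trial per axis, independently
    permuted) followed by greedy pairwise swaps that shrink the absolute
    column correlations — the usual correlation-reduced LHS, so the
    planted axes are varied independently *in-sample*, not just in
    expectation.
    """
    strata = (np.arange(n)[:, None] + rng.uniform(size=(n, k))) / n
    lat = np.stack([strata[rng.permutation(n), j] for j in range(k)], axis=1)
    for _ in range(n_sweeps):
        corr = np.corrcoef(lat, rowvar=False)
        j = int(np.abs(np.triu(corr, 1)).max(axis=0).argmax())
        if np.abs(np.triu(corr, 1)).max() < 0.02:
            break
        a, b = rng.integers(n, size=2)
        cand = lat.copy()
        cand[[a, b], j] = cand[[b, a], j]
        if np.abs(np.triu(np.corrcoef(cand, rowvar=False), 1)).sum() < \
           np.abs(np.triu(corr, 1)).sum():
            lat = cand
    return lat


def generate_cohort_for_pca(config: SyntheticCohortConfig
                            ) -> Tuple[List[TrialRecording], np.ndarray]:
    """Cohort with three independent planted latent axes.

    Returns the clean trials plus the (n_trials, 3) matrix of latent
    draws (sociability, boldness, activity) for recovery checks.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    rngs = [np.random.default_rng(s) for s in streams]
    lat_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(config.n_trials + 1)[-1])
    latents = _orthogonal_latin_latents(config.n_trials, 3, lat_rng)
    rg = PCA_LATENT_RANGES
    trials = []
    conditions = [c for c, k in zip(config.conditions, config.condition_sizes)
                  for _ in range(k)]
    for t in range(config.n_trials):
        soc, bold, act = latents[t]
        lat = SchoolLatents(
            attraction_strength=rg["attraction"][0]
            + soc * (rg["attraction"][1] - rg["attraction"][0]),
            wall_bias=rg["wall_gain"],
            wall_preference_inset_cm=rg["wall_inset_cm"][0]
            + bold * (rg["wall_inset_cm"][1] - rg["wall_inset_cm"][0]),
            speed_scale=rg["speed_scale"][0]
            + act * (rg["speed_scale"][1] - rg["speed_scale"][0]),
            stillness_prob=rg["stillness"][0]
            + act * (rg["stillness"][1] - rg["stillness"][0]),
            turn_sigma=config.base_latents.turn_sigma)
        trial, _ = generate_school(
            lat, rngs[t], n_fish=config.n_fish,
            duration_frames=config.duration_frames,
            frame_rate=config.frame_rate, arena=config.arena,
            condition=conditions[t], batch_id=f"b{t // 3}",
            trial_id=f"pca{t + 1:02d}")
        trials.append(trial)
    return trials, latents
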