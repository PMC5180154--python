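"""Core data containers shared across the pipeline.

Coordinates follow two frames of reference: raw tracker output is in pixels
(arbitrary origin), cleaned trajectories are in centimetres with the arena
centre at (0, 0).  Missing detections are NaN throughout; they are never
silently imputed outside the documented interpolation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical order of the seven behavioural variables.
PROFILE_FIELDS = (
    "median_speed",
    "prop_still",
    "prop_near_edge",
    "time_to_explore_10pct",
    "pct_arena_explored",
    "median_nn_distance",
    "mean_local_neighbour_prop",
)

#: Human-readable variable names used in printed tables.
PROFILE_LABELS = {
    "median_speed": "median speed",
    "prop_still": "proportion of time spent still",
    "prop_near_edge": "proportion of time near the arena edge",
    "time_to_explore_10pct": "time taken to explore 10% of the arena",
    "pct_arena_explored": "overall % of the arena explored",
    "median_nn_distance": "median distance to nearest neighbour",
    "mean_local_neighbour_prop": "mean proportion of local neighbours",
}

CONDITIONS = ("ambient", "OA", "ambient_in_OA", "simulated", "synthetic")


@dataclass
class RecordingMeta:
    """Metadata for one group trial.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in Hz.
    duration_frames : int
        Number of frames in the recording.
    condition : str
        Experimental condition label (one of :data:`CONDITIONS`).
    batch_id : str
        Experiment number; trials recorded simultaneously share a batch.
    pixel_scale : float
        Centimetres per pixel of the (normalised) video.
    """

    frame_rate: float = 25.0
    duration_frames: int = 90_000
    condition: str = "ambient"
    batch_id: str = "0"
    pixel_scale: float = 0.029

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration_frames <= 0:
            raise ValueError("duration_frames must be > 0")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )


@dataclass
class RawTrackTable:
    """Tracker output for one trial: per-frame, per-fish pixel positions.

    ``positions`` has shape (n_frames, n_fish, 2); missing detections are NaN.
    Frame index is implicit row order (0-based).
    """

    positions: np.ndarray
    source_id: str = "trial"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_fish, 2)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def n_missing(self) -> int:
        """Number of (frame, fish) slots with a missing detection."""
        return int(np.isnan(self.positions).any(axis=2).sum())


@dataclass
class ArenaGeometry:
    """Circular test arena, centred at (0, 0) in cm coordinates.

    The default radius follows the 29 cm / 1000 px normalisation
    (pixel_scale 0.029 cm/px).  ``edge_zone_width_cm`` is the thigmotaxis
    band (20% of the radius); the exploration grid is ``grid_cell_cm``
    squares, corner-aligned on the centre.
    """

    radius_cm: float = 14.5
    pixel_scale: float = 0.029
    edge_zone_width_cm: float = 3.0
    grid_cell_cm: float = 1.0
    grid_convention: str = "intersects_disc"

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("radius_cm must be > 0")
        if not 0 < self.edge_zone_width_cm < self.radius_cm:
            raise ValueError("edge_zone_width_cm must be in (0, radius_cm)")
        if self.grid_cell_cm <= 0:
            raise ValueError("grid_cell_cm must be > 0")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.grid_convention not in ("intersects_disc", "centre_in_disc"):
            raise ValueError("unknown grid_convention")


@dataclass
class Trajectory:
    """One fish's path in arena coordinates (cm), NaN where missing."""

    x: np.ndarray
    y: np.ndarray
    fish_id: str = "fish"
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frames with a detection."""
        return ~(np.isnan(self.x) | np.isnan(self.y))

    @property
    def r(self) -> np.ndarray:
        """Radial distance from the arena centre, NaN where missing."""
        return np.hypot(self.x, self.y)

    def copy(self) -> "Trajectory":
        return Trajectory(self.x.copy(), self.y.copy(), self.fish_id, self.meta)


@dataclass
class TrialRecording:
    """A group trial: one Trajectory per fish plus shared metadata."""

    trajectories: list
    meta: RecordingMeta
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("a trial needs at least one trajectory")
        n = len(self.trajectories[0])
        if any(len(t) != n for t in self.trajectories):
            raise ValueError("all trajectories must have equal length")

    @property
    def n_fish(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return len(self.trajectories[0])

    def positions(self) -> np.ndarray:
        """Stack to an (n_frames, n_fish, 2) array."""
        xs = np.stack([t.x for t in self.trajectories], axis=1)
        ys = np.stack([t.y for t in self.trajectories], axis=1)
        return np.stack([xs, ys], axis=2)


@dataclass
class CleaningReport:
    """Bookkeeping for the cleaning chain of one trial."""

    n_points_deleted_outside: int = 0
    n_points_deleted_speed: int = 0
    n_points_interpolated: int = 0
    fraction_frames_complete: float = 0.0
    v_max_cm_s: float = 91.0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_points_deleted_outside", "n_points_deleted_speed",
                     "n_points_interpolated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_frames_complete <= 1.0:
            raise ValueError("fraction_frames_complete must be in [0, 1]")


@dataclass
class BehaviouralProfile:
    """The seven behavioural variables for one analysis unit (fish or trial).

    ``time_to_explore_10pct`` is in seconds and NaN if the 10% coverage
    threshold was never reached; proportions are in [0, 1]; speeds in cm/s;
    distances in cm.
    """

    median_speed: float
    prop_still: float
    prop_near_edge: float
    time_to_explore_10pct: float
    pct_arena_explored: float
    median_nn_distance: float
    mean_local_neighbour_prop: float
    unit_id: str = "unit"
    condition: str = "ambient"
    batch_id: str = "0"
    duration_s: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("prop_still", "prop_near_edge", "pct_arena_explored",
                     "mean_local_neighbour_prop"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if np.isfinite(self.median_speed) and self.median_speed < 0:
            raise ValueError("median_speed must be >= 0")
        t = self.time_to_explore_10pct
        if np.isfinite(t) and t <= 0:
            raise ValueError("time_to_explore_10pct must be > 0 when present")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PROFILE_FIELDS}
        d.update(unit_id=self.unit_id, condition=self.condition,
                 batch_id=self.batch_id, duration_s=self.duration_s)
        return d


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.angle(np.exp(1j * a))
    return w if w.ndim else float(w)
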