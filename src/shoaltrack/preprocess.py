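"""Trajectory cleaning: scaling, impossible-point deletion, gap interpolation.

The chain mirrors the standard post-processing of arena tracking data:

1. normalise pixel coordinates to centimetres with the arena centre at (0, 0);
2. delete detections outside the arena disc (mirror-reflection artifacts);
3. delete detections arriving faster than a physiological maximum speed
   (identity-swap teleports); the later point of the offending pair is
   removed and speeds recomputed, so one bad detection cannot take its
   neighbours with it;
4. fill short, well-flanked gaps by a least-squares cubic fitted to the
   five known frames on each side (exact for straight-line and cubic
   paths); filled points are radially clamped to the arena boundary.

Steps run in this order; downstream metrics ignore whatever is still
missing afterwards rather than imputing further.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from numpy.polynomial import polynomial as P

from .core import (ArenaGeometry, CleaningReport, RawTrackTable,
                   RecordingMeta, Trajectory, TrialRecording)

DEFAULT_V_MAX_CM_S = 91.0   # fastest manually-tracked juvenile sea bass


def normalize_coordinates(raw: RawTrackTable, arena: ArenaGeometry,
                          centre_px: Tuple[float, float] = (0.0, 0.0),
                          radius_px: float | None = None,
                          meta: RecordingMeta | None = None,
                          ) -> List[Trajectory]:
    """Convert pixel positions to cm with the arena centre at (0, 0).

    Calibration: ``centre_px`` is the arena centre in the image; the scale
    is ``arena.radius_cm / radius_px`` when a pixel radius is supplied,
    otherwise ``arena.pixel_scale``.
    """
    if radius_px is not None:
        if radius_px <= 0:
            raise ValueError("calibration radius_px must be > 0")
        scale = arena.radius_cm / radius_px
    else:
        scale = arena.pixel_scale
    cx, cy = centre_px
    out = []
    for i in range(raw.n_fish):
        x = (raw.positions[:, i, 0] - cx) * scale
        y = (raw.positions[:, i, 1] - cy) * scale
        out.append(Trajectory(x, y, fish_id=f"{raw.source_id}/f{i+1}",
                              meta=meta))
    return out


def denormalize_coordinates(trial: TrialRecording, arena: ArenaGeometry,
                            centre_px: Tuple[float, float] = (0.0, 0.0),
                            ) -> RawTrackTable:
    """Inverse of :func:`normalize_coordinates` (cm back to pixels)."""
    cx, cy = centre_px
    pos = trial.positions() / arena.pixel_scale
    pos[:, :, 0] += cx
    pos[:, :, 1] += cy
    return RawTrackTable(positions=pos, source_id=trial.trial_id)


def delete_out_of_arena(traj: Trajectory, arena: ArenaGeometry
                        ) -> Tuple[Trajectory, int]:
    """Mark points with radial distance > arena radius as missing."""
    out = traj.copy()
    bad = out.r > arena.radius_cm   # NaN compares False
    out.x[bad] = np.nan
    out.y[bad] = np.nan
    return out, int(bad.sum())


def compute_displacements(traj: Trajectory) -> np.ndarray:
    """Per-frame displacement in cm (length n; element t is the move from
    frame t-1 to t; NaN at t=0 and wherever either endpoint is missing)."""
    d = np.full(len(traj), np.nan)
    d[1:] = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return d


def compute_instantaneous_speeds(traj: Trajectory,
                                 frame_rate: float | None = None
                                 ) -> np.ndarray:
    """Instantaneous speed s_t in cm/s: per-frame displacement x frame rate."""
    if frame_rate is None:
        frame_rate = traj.meta.frame_rate if traj.meta else 25.0
    if len(traj) < 2:
        raise ValueError("need at least 2 frames to compute speeds")
    return compute_displacements(traj) * frame_rate


def delete_speed_violations(traj: Trajectory,
                            v_max_cm_s: float = DEFAULT_V_MAX_CM_S,
                            frame_rate: float | None = None
                            ) -> Tuple[Trajectory, int]:
    """Delete points arriving faster than ``v_max_cm_s``.

    A point t is removed when frames t-1 and t are both present and the
    displacement between them exceeds ``v_max / frame_rate``.  Deletion is
    sequential: once t is gone the (t, t+1) pair no longer exists, so a
    single teleport removes exactly one point.
    """
    if v_max_cm_s <= 0:
        raise ValueError("v_max_cm_s must be > 0")
    if frame_rate is None:
        frame_rate = traj.meta.frame_rate if traj.meta else 25.0
    max_disp = v_max_cm_s / frame_rate
    out = traj.copy()
    disp = compute_displacements(out)
    candidates = np.flatnonzero(disp > max_disp)  # NaN disp never triggers
    deleted = np.zeros(len(out), dtype=bool)
    count = 0
    for t in candidates:
        if deleted[t - 1]:
            continue  # pair broken by an earlier deletion; speed undefined
        out.x[t] = np.nan
        out.y[t] = np.nan
        deleted[t] = True
        count += 1
    return out, count


def find_gaps(valid: np.ndarray) -> List[Tuple[int, int]]:
    """Runs of missing frames as (start, length) pairs."""
    gaps = []
    n = valid.size
    t = 0
    while t < n:
        if not valid[t]:
            s = t
            while t < n and not valid[t]:
                t += 1
            gaps.append((s, t - s))
        else:
            t += 1
    return gaps


def eligible_gaps(valid: np.ndarray, max_gap_frames: int,
                  context_frames: int) -> List[Tuple[int, int]]:
    """Gaps strictly shorter than ``max_gap_frames`` with ``context_frames``
    valid frames immediately before and after."""
    out = []
    n = valid.size
    for s, length in find_gaps(valid):
        if length >= max_gap_frames:
            continue
        lo, hi = s - context_frames, s + length + context_frames
        if lo < 0 or hi > n:
            continue
        if valid[lo:s].all() and valid[s + length:hi].all():
            out.append((s, length))
    return out


def interpolate_gaps(traj: Trajectory, frame_rate: float | None = None,
                     max_gap_s: float = 1.0, context_frames: int = 5,
                     arena: ArenaGeometry | None = None
                     ) -> Tuple[Trajectory, int]:
    """Fill short, well-flanked gaps with a least-squares cubic.

    A gap qualifies when it is strictly shorter than ``max_gap_s`` (in
    frames: fewer than ``frame_rate * max_gap_s``) and the
    ``context_frames`` frames on each side are all present.  x and y are
    fitted independently against frame index over the 2 x context_frames
    flanking points; filled points outside the arena are radially clamped
    to the boundary.  Returns the filled trajectory and the number of
    points determined.
    """
    if context_frames < 2:
        raise ValueError("context_frames must be >= 2 (cubic underdetermined)")
    if frame_rate is None:
        frame_rate = traj.meta.frame_rate if traj.meta else 25.0
    max_gap_frames = int(round(max_gap_s * frame_rate))
    out = traj.copy()
    n_filled = 0
    for s, length in eligible_gaps(out.valid, max_gap_frames, context_frames):
        idx = np.r_[np.arange(s - context_frames, s),
                    np.arange(s + length, s + length + context_frames)]
        t0 = float(idx.mean())                 # centre for conditioning
        tt = idx - t0
        tg = np.arange(s, s + length) - t0
        deg = min(3, idx.size - 1)
        cx = P.polyfit(tt, out.x[idx], deg)
        cy = P.polyfit(tt, out.y[idx], deg)
        gx = P.polyval(tg, cx)
        gy = P.polyval(tg, cy)
        if arena is not None:
            r = np.hypot(gx, gy)
            over = r > arena.radius_cm
            if over.any():
                f = arena.radius_cm / r[over]
                gx[over] *= f
                gy[over] *= f
        out.x[s:s + length] = gx
        out.y[s:s + length] = gy
        n_filled += length
    return out, n_filled


def completeness_report(trial: Sequence[Trajectory],
                        n_deleted_outside: int = 0,
                        n_deleted_speed: int = 0,
                        n_interpolated: int = 0,
                        v_max_cm_s: float = DEFAULT_V_MAX_CM_S,
                        config: dict | None = None) -> CleaningReport:
    """Summarise a cleaned trial: counts plus the fraction of frames in
    which every fish is present."""
    valid = np.column_stack([t.valid for t in trial])
    frac = float(valid.all(axis=1).mean()) if valid.size else 0.0
    return CleaningReport(
        n_points_deleted_outside=n_deleted_outside,
        n_points_deleted_speed=n_deleted_speed,
        n_points_interpolated=n_interpolated,
        fraction_frames_complete=frac,
        v_max_cm_s=v_max_cm_s,
        config=config or {})


def clean_trial(raw: RawTrackTable, arena: ArenaGeometry,
                meta: RecordingMeta,
                centre_px: Tuple[float, float] = (0.0, 0.0),
                radius_px: float | None = None,
                v_max_cm_s: float = DEFAULT_V_MAX_CM_S,
                max_gap_s: float = 1.0, context_frames: int = 5,
                trial_id: str | None = None
                ) -> Tuple[TrialRecording, CleaningReport]:
    """Run the full cleaning chain on one raw trial."""
    trajs = normalize_coordinates(raw, arena, centre_px=centre_px,
                                  radius_px=radius_px, meta=meta)
    n_out = n_speed = n_interp = 0
    cleaned = []
    for tr in trajs:
        tr, c1 = delete_out_of_arena(tr, arena)
        tr, c2 = delete_speed_violations(tr, v_max_cm_s, meta.frame_rate)
        tr, c3 = interpolate_gaps(tr, meta.frame_rate, max_gap_s,
                                  context_frames, arena)
        n_out += c1
        n_speed += c2
        n_interp += c3
        cleaned.append(tr)
    report = completeness_report(
        cleaned, n_out, n_speed, n_interp, v_max_cm_s,
        config=dict(radius_cm=arena.radius_cm, pixel_scale=arena.pixel_scale,
                    v_max_cm_s=v_max_cm_s, max_gap_s=max_gap_s,
                    context_frames=context_frames))
    trial = TrialRecording(trajectories=cleaned, meta=meta,
                           trial_id=trial_id or raw.source_id)
    return trial, report
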