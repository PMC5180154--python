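"""Analytic design constants of the study, recomputed from primitives.

Everything here is arithmetic on the experiment's design parameters —
recording length, frame rate, video normalisation, arena size, group
counts — kept in one place so tests and reports derive them rather than
hard-coding magic numbers.
"""

from __future__ import annotations

ARENA_DIAMETER_CM = 29.0      # normalised video: 1000 px across the arena
ARENA_DIAMETER_PX = 1000
NOMINAL_RADIUS_CM = 15.0      # physical arena: 30 cm diameter
TRIAL_MINUTES = 60
FRAME_RATE_HZ = 25
GROUP_SIZE = 10
GROUPS_PER_CONDITION = (9, 9, 8)      # ambient, OA, ambient tested in OA
FISH_COLLECTED = (180, 90)            # ambient-reared, OA-reared


def frames_per_trial(minutes: float = TRIAL_MINUTES,
                     frame_rate: float = FRAME_RATE_HZ) -> int:
    """Recording length in frames (60 min at 25 Hz -> 90 000)."""
    return int(round(minutes * 60 * frame_rate))


def pixel_scale_cm(diameter_cm: float = ARENA_DIAMETER_CM,
                   diameter_px: int = ARENA_DIAMETER_PX) -> float:
    """Centimetres per pixel of the normalised video (0.029)."""
    return diameter_cm / diameter_px


def stillness_speed_cm_s(pixel_scale: float | None = None,
                         frame_rate: float = FRAME_RATE_HZ) -> float:
    """Speed equivalent of a one-pixel-per-frame movement (0.725 cm/s,
    conventionally quoted as 0.7)."""
    if pixel_scale is None:
        pixel_scale = pixel_scale_cm()
    return pixel_scale * frame_rate


def edge_zone_width_cm(radius_cm: float = NOMINAL_RADIUS_CM,
                       fraction: float = 0.20) -> float:
    """Thigmotaxis band width: 20% of the arena radius (3 cm)."""
    return fraction * radius_cm


def n_replicate_trials(groups=GROUPS_PER_CONDITION) -> int:
    """Total group trials across the three conditions (26)."""
    return sum(groups)


def n_fish_collected(batches=FISH_COLLECTED) -> int:
    """Total fish taken from the rearing systems (270)."""
    return sum(batches)
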