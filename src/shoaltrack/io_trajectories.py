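"""Reading and writing tracker coordinate tables and result tables.

The on-disk trajectory format is the plain-text table emitted by
multi-animal video trackers in the idTracker family: one row per frame,
two columns per individual (x1, y1, x2, y2, ...), values in pixels, blank
or ``NaN`` fields marking missed detections.  Dialects vary, so the reader
tolerates comma or whitespace delimiters, an optional header row, and an
optional leading frame-index column.
"""

from __future__ import annotations

import os
from typing import Iterable, List

import numpy as np
import pandas as pd
import yaml

from .core import BehaviouralProfile, RawTrackTable, RecordingMeta, PROFILE_FIELDS

_MISSING_TOKENS = {"", "nan", "NaN", "NAN", "na", "NA"}


def _parse_token(tok: str) -> float:
    tok = tok.strip()
    if tok in _MISSING_TOKENS:
        return np.nan
    return float(tok)


def _split_row(line: str) -> List[str]:
    line = line.rstrip("\n\r")
    if "," in line or "\t" in line:
        # Delimited dialect: empty fields are meaningful (missing detections).
        sep = "," if "," in line else "\t"
        return line.split(sep)
    return line.split()


def read_track_table(path: str, meta: RecordingMeta | None = None,
                     source_id: str | None = None) -> RawTrackTable:
    """Read an idTracker-style coordinate table.

    Parameters
    ----------
    path : str
        File with one row per frame and columns ``x1, y1, ..., xN, yN``
        (an optional leading integer frame column is detected and dropped).
    meta : RecordingMeta, optional
        Used only for sanity messages; the table itself defines its size.

    Returns
    -------
    RawTrackTable
        Positions in pixels, NaN where the tracker lost a fish.
    """
    rows: List[List[float]] = []
    header_skipped = False
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = _split_row(line)
            try:
                vals = [_parse_token(t) for t in toks]
            except ValueError:
                if not rows and not header_skipped:
                    header_skipped = True  # row 1 did not parse -> header
                    continue
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {line.strip()!r}"
                ) from None
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(vals)} columns, "
                    f"expected {ncols}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] % 2 == 1:
        # Odd column count: leading frame-index column.
        first = arr[:, 0]
        if not np.all(np.diff(first) > 0):
            raise ValueError(
                f"{path}: odd column count but first column is not a "
                "strictly increasing frame index"
            )
        arr = arr[:, 1:]
    n_fish = arr.shape[1] // 2
    positions = arr.reshape(arr.shape[0], n_fish, 2)
    if meta is not None and positions.shape[0] != meta.duration_frames:
        # Tolerated: truncated recordings happen; the table wins.
        pass
    return RawTrackTable(positions=positions,
                         source_id=source_id or os.path.basename(path))


def write_track_table(table: RawTrackTable, path: str,
                      decimals: int = 6) -> None:
    """Write a RawTrackTable as comma-delimited text with an x1,y1,... header."""
    n_fish = table.n_fish
    header = ",".join(f"x{i+1},y{i+1}" for i in range(n_fish))
    flat = table.positions.reshape(table.n_frames, 2 * n_fish)
    fmt = f"%.{decimals}f"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in flat:
            fh.write(",".join("NaN" if np.isnan(v) else fmt % v
                              for v in row) + "\n")


def write_meta(meta: RecordingMeta, path: str) -> None:
    """Write the per-trial metadata sidecar (YAML key-value file)."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            dict(frame_rate=meta.frame_rate,
                 duration_frames=meta.duration_frames,
                 condition=meta.condition,
                 batch_id=meta.batch_id,
                 pixel_scale=meta.pixel_scale),
            fh, sort_keys=False)


def read_meta(path: str) -> RecordingMeta:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return RecordingMeta(frame_rate=float(d["frame_rate"]),
                         duration_frames=int(d["duration_frames"]),
                         condition=str(d["condition"]),
                         batch_id=str(d["batch_id"]),
                         pixel_scale=float(d["pixel_scale"]))


def profiles_to_frame(profiles: Iterable[BehaviouralProfile]) -> pd.DataFrame:
    """Tidy table: one row per analysis unit, one column per variable."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    return pd.DataFrame([p.to_dict() for p in profiles])


def write_profiles(profiles: Iterable[BehaviouralProfile], path: str) -> None:
    """Write behavioural profiles as tidy CSV (loss-free to ~1e-10)."""
    df = profiles_to_frame(profiles)
    df.to_csv(path, index=False, float_format="%.10g")


def read_profiles(path: str) -> List[BehaviouralProfile]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {k: float(row[k]) for k in PROFILE_FIELDS}
        out.append(BehaviouralProfile(
            unit_id=str(row.get("unit_id", "unit")),
            condition=str(row.get("condition", "ambient")),
            batch_id=str(row.get("batch_id", "0")),
            duration_s=float(row.get("duration_s", np.nan)),
            **kwargs))
    return out
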