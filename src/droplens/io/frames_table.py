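"""Internal wide-table trajectory format (TSV).

One row per (frame, bead) with header
``frame  time_ps  bead_id  x  y  z  box_x  box_y  box_z``.  The table is a
plain-text alternative to concatenated GRO that round-trips coordinates at
full float precision.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from ..errors import ParseError, StructuralError
from ..trajectory import Frame

COLUMNS = ["frame", "time_ps", "bead_id", "x", "y", "z",
           "box_x", "box_y", "box_z"]


def write_frames_table(frames: List[Frame], path) -> None:
    rows = []
    for k, f in enumerate(frames):
        n = f.n_beads
        rows.append(pd.DataFrame({
            "frame": np.full(n, k, dtype=int),
            "time_ps": np.full(n, f.time),
            "bead_id": np.arange(n),
            "x": f.coordinates[:, 0],
            "y": f.coordinates[:, 1],
            "z": f.coordinates[:, 2],
            "box_x": np.full(n, f.box[0]),
            "box_y": np.full(n, f.box[1]),
            "box_z": np.full(n, f.box[2]),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False,
                                              float_format="%.9g")


def read_frames_table(path) -> List[Frame]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise ParseError(f"{path}: cannot parse frames table: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: frames table missing columns {missing}")
    frames = []
    for k, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("bead_id")
        if not np.array_equal(grp["bead_id"].to_numpy(),
                              np.arange(len(grp))):
            raise StructuralError(
                f"frame {k}: bead_id must run 0..N-1 without gaps")
        frames.append(Frame(
            float(grp["time_ps"].iloc[0]),
            grp[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float),
            grp[["x", "y", "z"]].to_numpy(dtype=float)))
    if not frames:
        raise ParseError(f"{path}: empty frames table")
    n = frames[0].n_beads
    for k, f in enumerate(frames):
        if f.n_beads != n:
            raise StructuralError(
                f"frame {k} has {f.n_beads} beads, expected {n}")
    return frames
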