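"""Frames and trajectories.

A :class:`Frame` is one coordinate snapshot (nm) with an orthorhombic box and
a time stamp (ps).  A :class:`Trajectory` stores all frames of a run in one
(F, N, 3) array for speed, exposing light-weight Frame views; times must be
strictly increasing and the bead count constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence

import numpy as np

from .errors import GeometryError, StructuralError
from .system import SystemLayout


@dataclass
class Frame:
    time: float  # ps
    box: np.ndarray  # (3,) nm, orthorhombic
    coordinates: np.ndarray  # (N, 3) nm

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box.shape != (3,):
            raise GeometryError(f"box must be 3 lengths, got {self.box.shape}")
        if not np.all(self.box > 0):
            raise GeometryError(f"box lengths must be positive: {self.box}")
        if self.time < 0:
            raise StructuralError(f"negative frame time {self.time}")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError(
                f"coordinates must be (N, 3), got {self.coordinates.shape}")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Ordered frames over one system layout."""

    def __init__(self, system: SystemLayout,
                 coordinates: np.ndarray,
                 times: Sequence[float],
                 boxes: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        times = np.asarray(times, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise StructuralError("coordinates must be (F, N, 3)")
        F, N, _ = coordinates.shape
        if system.n_beads != N:
            raise StructuralError(
                f"system has {system.n_beads} beads, frames have {N}")
        if times.shape != (F,):
            raise StructuralError("one time per frame required")
        if F > 1 and not np.all(np.diff(times) > 0):
            raise StructuralError("frame times must be strictly increasing")
        if boxes.shape == (3,):
            boxes = np.tile(boxes, (F, 1))
        if boxes.shape != (F, 3):
            raise StructuralError("boxes must be (F, 3) or (3,)")
        if not np.all(boxes > 0):
            raise GeometryError("box lengths must be positive")
        self.system = system
        self.coordinates = coordinates
        self.times = times
        self.boxes = boxes

    @classmethod
    def from_frames(cls, system: SystemLayout,
                    frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise StructuralError("empty trajectory")
        n = frames[0].n_beads
        for k, f in enumerate(frames):
            if f.n_beads != n:
                raise StructuralError(
                    f"frame {k} has {f.n_beads} beads, expected {n}")
        return cls(system,
                   np.stack([f.coordinates for f in frames]),
                   [f.time for f in frames],
                   np.stack([f.box for f in frames]))

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def __getitem__(self, k: int) -> Frame:
        return Frame(self.times[k], self.boxes[k], self.coordinates[k])

    def __iter__(self) -> Iterator[Frame]:
        for k in range(len(self)):
            yield self[k]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def frame_interval_ps(self) -> float:
        """Median spacing between consecutive frame times (ps)."""
        if len(self) < 2:
            raise StructuralError("frame interval undefined for < 2 frames")
        return float(np.median(np.diff(self.times)))

    def window(self, analysis_window: float) -> "Trajectory":
        """Trajectory tail containing the final `analysis_window` fraction."""
        n = len(self)
        start = n - max(1, int(round(analysis_window * n)))
        return Trajectory(self.system, self.coordinates[start:],
                          self.times[start:], self.boxes[start:])
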