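"""Trajectory reading/writing across the two supported text formats."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Union

from ..errors import StructuralError
from ..system import SystemLayout
from ..topology import SpeciesRegistry
from ..trajectory import Frame, Trajectory
from .frames_table import read_frames_table, write_frames_table
from .gro import read_gro_frames, _write_frame


def _is_table(path: Path) -> bool:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("frame\t")


def read_trajectory(paths: Union[str, Path, Sequence[Union[str, Path]]],
                    registry: Optional[SpeciesRegistry] = None,
                    system: Optional[SystemLayout] = None,
                    labelled_residues=None) -> Trajectory:
    """Read one or more coordinate files (concatenated GRO or frames TSV).

    All files must share the system layout; frames must be ordered by
    strictly increasing time across the whole concatenation.  For TSV input
    a ``system`` must be supplied (the table carries no chemistry).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: List[Frame] = []
    for p in paths:
        p = Path(p)
        if _is_table(p):
            if system is None:
                raise StructuralError(
                    f"{p}: frames table input requires an explicit system "
                    "layout (pass system=... or a layout file)")
            frames.extend(read_frames_table(p))
        else:
            sys_p, fr = read_gro_frames(p, registry, labelled_residues)
            if system is None:
                system = sys_p
            elif sys_p.n_beads != system.n_beads:
                raise StructuralError(
                    f"{p}: bead count {sys_p.n_beads} differs from "
                    f"{system.n_beads}")
            frames.extend(fr)
    return Trajectory.from_frames(system, frames)


def write_trajectory(traj: Trajectory, path: Union[str, Path],
                     fmt: Optional[str] = None) -> None:
    """Write a trajectory as concatenated GRO or frames TSV (by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "gro"
    if fmt == "tsv":
        write_frames_table(list(traj), path)
    elif fmt == "gro":
        with open(path, "w") as fh:
            for f in traj:
                _write_frame(fh, traj.system, f)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
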