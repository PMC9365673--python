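"""Residue-lipid contact occupancy and dual-cutoff residence times.

Occupancy counts the fraction of frames in which a residue lies within the
contact cutoff (default 0.6 nm) of any bead of a lipid — optionally resolved
by the lipid's bead chemical groups, which is how ester-specific binding
shows up.  Residence times use a dual cutoff: a binding event opens when the
residue-lipid minimum distance drops below the lower cutoff and closes only
when it exceeds the upper one, suppressing boundary flicker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import StructuralError
from .geometry import min_set_distance, pairwise_min_image_distances
from .system import SystemLayout
from .trajectory import Frame, Trajectory


@dataclass
class OccupancyRecord:
    residue: str
    protomer: int
    species: str
    occupancy: float
    chemical_group: Optional[str] = None
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidenceEventList:
    """Binding events of one (residue, lipid molecule) pair."""

    residue: str
    protomer: int
    mol_id: int
    #: event table: start_frame, n_frames, duration_ns, censored
    events: pd.DataFrame
    frame_interval_ps: float

    def durations(self, include_censored: bool = False) -> np.ndarray:
        ev = self.events
        if not include_censored:
            ev = ev[~ev["censored"]]
        return ev["n_frames"].to_numpy(dtype=float)

    def median_frames(self, include_censored: bool = False) -> float:
        d = self.durations(include_censored)
        return float(np.median(d)) if d.size else float("nan")

    def iqr_frames(self, include_censored: bool = False) -> Tuple[float, float]:
        d = self.durations(include_censored)
        if not d.size:
            return (float("nan"), float("nan"))
        return tuple(np.percentile(d, [25, 75]))


def residue_lipid_min_distance(frame: Frame,
                               residue_beads: np.ndarray,
                               lipid_beads: np.ndarray) -> float:
    """Minimum over all bead pairs of the minimum-image distance (nm)."""
    return min_set_distance(frame.coordinates[np.asarray(residue_beads)],
                            frame.coordinates[np.asarray(lipid_beads)],
                            frame.box)


def _min_distance_series(traj: Trajectory, residue_beads: np.ndarray,
                         lipid_beads: np.ndarray) -> np.ndarray:
    res = np.asarray(residue_beads, dtype=int)
    lip = np.asarray(lipid_beads, dtype=int)
    out = np.empty(len(traj))
    for f in range(len(traj)):
        out[f] = pairwise_min_image_distances(
            traj.coordinates[f, res], traj.coordinates[f, lip],
            traj.boxes[f]).min()
    return out


def residue_occupancy(traj: Trajectory, cfg: AnalysisConfig,
                      residue: str, species: str,
                      by_group: bool = False,
                      replicate: Optional[str] = None
                      ) -> List[OccupancyRecord]:
    """Per-protomer contact occupancy of one residue by one lipid species.

    Occupancy is the fraction of analysis-window frames in which any bead of
    any molecule of the species lies within the contact cutoff of any bead
    of the residue.  With ``by_group`` the count is resolved per bead
    chemical group of the species (e.g. carboxyl esters vs acyl chains).
    """
    system = traj.system
    if system.protein is None:
        raise StructuralError("occupancy analysis requires a protein")
    per_protomer = system.protein.residue_beads(residue)
    mols = system.molecules_of(species)
    if not mols:
        raise ValueError(f"species {species!r} absent from the system")
    topo = system.topologies[species]
    sub = traj.window(cfg.analysis_window)

    if by_group:
        groups = sorted({b.chemical_group.value for b in topo.beads})
        group_beads = {
            g: np.concatenate([
                m.start + np.asarray(topo.indices_of_group(g))
                for m in mols])
            for g in groups}
    else:
        groups = [None]
        group_beads = {None: np.concatenate(
            [np.arange(m.start, m.stop) for m in mols])}

    records: List[OccupancyRecord] = []
    for p, res_beads in enumerate(per_protomer):
        for g in groups:
            lip = group_beads[g]
            hits = 0
            for f in range(len(sub)):
                d = pairwise_min_image_distances(
                    sub.coordinates[f, res_beads],
                    sub.coordinates[f, lip], sub.boxes[f]).min()
                if d < cfg.contact_cutoff:
                    hits += 1
            records.append(OccupancyRecord(
                residue, p, species, hits / len(sub),
                chemical_group=g, replicate=replicate))
    return records


def aggregate_occupancy(records: Sequence[OccupancyRecord]) -> pd.DataFrame:
    """Min / median / max occupancy across protomers x replicates,
    per (residue, species, chemical group)."""
    df = pd.DataFrame([{
        "residue": r.residue, "species": r.species,
        "group": r.chemical_group, "occupancy": r.occupancy,
    } for r in records])
    agg = (df.groupby(["residue", "species", "group"], dropna=False)
             ["occupancy"].agg(["min", "median", "max", "count"])
             .reset_index())
    return agg


def segment_dual_cutoff(series: np.ndarray, lower: float, upper: float
                        ) -> List[Tuple[int, int, bool]]:
    """Segment a distance series into (start, n_frames, censored) events.

    An event opens at the first frame with d < lower while no event is open
    and closes at the first subsequent frame with d > upper; its duration is
    the number of frames in [open, close).  An event still open at the end
    of the series is censored.
    """
    if lower > upper:
        raise ValueError("lower cutoff must not exceed upper cutoff")
    events: List[Tuple[int, int, bool]] = []
    open_at: Optional[int] = None
    for f, d in enumerate(series):
        if open_at is None:
            if d < lower:
                open_at = f
        elif d > upper:
            events.append((open_at, f - open_at, False))
            open_at = None
    if open_at is not None:
        events.append((open_at, len(series) - open_at, True))
    return events


def residence_times_dual_cutoff(traj: Trajectory, cfg: AnalysisConfig,
                                residue: str, mol_id: int,
                                protomer: Optional[int] = None
                                ) -> List[ResidenceEventList]:
    """Dual-cutoff residence events of one lipid molecule at one residue.

    Returns one event list per protomer (or only the requested one).
    Durations are reported in frames and in ns via the frame interval.
    """
    system = traj.system
    if system.protein is None:
        raise StructuralError("residence analysis requires a protein")
    if len(traj) > 1 and not np.all(np.diff(traj.times) > 0):
        raise StructuralError("frame times must be strictly increasing")
    mol = next((m for m in system.molecules if m.mol_id == mol_id), None)
    if mol is None:
        raise ValueError(f"no molecule with id {mol_id}")
    lip = np.arange(mol.start, mol.stop)
    dt_ps = traj.frame_interval_ps() if len(traj) > 1 else 0.0

    out: List[ResidenceEventList] = []
    per_protomer = system.protein.residue_beads(residue)
    protomers = range(len(per_protomer)) if protomer is None else [protomer]
    for p in protomers:
        series = _min_distance_series(traj, per_protomer[p], lip)
        segs = segment_dual_cutoff(series, cfg.residence_lower,
                                   cfg.residence_upper)
        events = pd.DataFrame(segs, columns=["start_frame", "n_frames",
                                             "censored"])
        if events.empty:
            events = pd.DataFrame(columns=["start_frame", "n_frames",
                                           "censored"]).astype(
                {"start_frame": int, "n_frames": int, "censored": bool})
        events["duration_ns"] = events["n_frames"] * dt_ps / 1000.0
        out.append(ResidenceEventList(residue, p, mol_id, events, dt_ps))
    return out


def compare_species_binding(traj: Trajectory, cfg: AnalysisConfig,
                            species: Sequence[str],
                            residues: Optional[Sequence[str]] = None,
                            mol_ids: Optional[Dict[str, Sequence[int]]] = None
                            ) -> pd.DataFrame:
    """Pooled binding-duration comparison across lipid species.

    Events are pooled over the labelled residues (default: the protein's
    ``labelled_residues``) and all protomers, for every molecule of each
    species (or an explicit ``mol_ids`` subset).  Returns one row per
    species with median / IQR (frames and ns) and a rank by median duration
    (rank 1 = longest binder); species with zero events get count 0 and no
    rank.
    """
    if len(species) < 1:
        raise ValueError("at least one species required")
    system = traj.system
    if system.protein is None:
        raise StructuralError("binding comparison requires a protein")
    residues = list(residues) if residues is not None \
        else sorted(system.protein.labelled_residues)

    rows = []
    for sp in species:
        mols = system.molecules_of(sp)
        if mol_ids is not None and sp in mol_ids:
            wanted = set(mol_ids[sp])
            mols = [m for m in mols if m.mol_id in wanted]
        durations: List[float] = []
        for res in residues:
            for m in mols:
                for ev in residence_times_dual_cutoff(traj, cfg, res,
                                                      m.mol_id):
                    durations.extend(ev.durations())
        durations = np.asarray(durations)
        dt_ps = traj.frame_interval_ps() if len(traj) > 1 else 0.0
        if durations.size:
            q25, q75 = np.percentile(durations, [25, 75])
            rows.append(dict(species=sp, n_events=int(durations.size),
                             median_frames=float(np.median(durations)),
                             iqr_low=float(q25), iqr_high=float(q75),
                             median_ns=float(np.median(durations)
                                             * dt_ps / 1000.0)))
        else:
            rows.append(dict(species=sp, n_events=0,
                             median_frames=np.nan, iqr_low=np.nan,
                             iqr_high=np.nan, median_ns=np.nan))
    df = pd.DataFrame(rows)
    ranked = df[df["n_events"] > 0].sort_values(
        "median_frames", ascending=False)
    df["rank"] = pd.Series(dtype="Int64")
    df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    return df
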