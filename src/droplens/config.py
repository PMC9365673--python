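"""Analysis configuration.

One dataclass holds every numeric analysis parameter used across the
trajectory and imaging pipelines, so a run can be reproduced from a single
config snapshot.  Lengths on the trajectory side are nm; the imaging side is
µm.  Defaults follow the conventions of ring-protein / lipid-droplet studies:
a 6 nm ring radius for occupancy counting, a 0.6 nm bead contact cutoff, a
0.55/1.0 nm dual cutoff for residence times, cluster cutoff 0.6 nm evaluated
on the trajectory tail, and ImageJ-style particle filters (area >= 0.01 µm²,
circularity 0.8-1.0) with 0.05 µm histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class AnalysisConfig:
    #: lateral radius (nm) defining "inside the protein ring"
    ring_radius: float = 6.0
    #: residue-lipid contact cutoff (nm) for occupancy counting
    contact_cutoff: float = 0.6
    #: dual-cutoff residence-time thresholds (nm): enter below lower,
    #: leave only above upper
    residence_lower: float = 0.55
    residence_upper: float = 1.0
    #: single-linkage clustering cutoff (nm)
    cluster_cutoff: float = 0.6
    #: fraction of the trajectory tail used for time averages
    #: (0.6 = the final 3/5 of the run)
    analysis_window: float = 0.6
    #: z-density histogram bin width (nm)
    z_bin: float = 0.1
    #: droplet-diameter histogram bin width (µm)
    diameter_bin: float = 0.05
    #: particle circularity acceptance interval
    circularity_range: Tuple[float, float] = (0.8, 1.0)
    #: minimum particle area (µm²)
    min_particle_area: float = 0.01

    def __post_init__(self) -> None:
        if self.residence_lower > self.residence_upper:
            raise ValueError(
                "residence_lower must not exceed residence_upper "
                f"({self.residence_lower} > {self.residence_upper})"
            )
        for name in ("ring_radius", "contact_cutoff", "residence_lower",
                     "residence_upper", "cluster_cutoff", "z_bin",
                     "diameter_bin", "min_particle_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.analysis_window <= 1:
            raise ValueError("analysis_window must be in (0, 1]")
        lo, hi = self.circularity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("circularity_range must be within [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "circularity_range" in d:
            d["circularity_range"] = tuple(d["circularity_range"])
        return cls(**d)

    def window_slice(self, n_frames: int) -> slice:
        """Frame slice of the analysis window (the trajectory tail)."""
        if n_frames <= 0:
            raise ValueError("empty trajectory")
        start = n_frames - max(1, int(round(self.analysis_window * n_frames)))
        return slice(start, n_frames)
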