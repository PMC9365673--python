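"""Ring enrichment: per-species lipid occupancy inside the protein ring.

The statistic is the fraction of a species' molecules whose lateral
centre-of-geometry lies within the ring radius of the protein complex's
centre of geometry, averaged over the analysis window.  Its null is the
ring's share of the membrane area, pi r^2 / (Lx Ly); the ratio of the two is
the enrichment (ratio > 1: concentrated inside the ring, < 1: excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import GeometryError, StructuralError
from .geometry import (center_of_geometry, lateral_distance_to_point,
                       minimum_image_displacement)
from .trajectory import Frame, Trajectory


@dataclass
class EnrichmentResult:
    species: str
    fraction: float              # mean inside fraction over the window
    per_frame: np.ndarray        # per-window-frame inside fractions
    null_fraction: float         # ring area fraction
    ratio: float                 # fraction / null_fraction
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"inside fraction {self.fraction} outside [0,1]")
        if not (0.0 < self.null_fraction < 1.0):
            raise ValueError("null fraction must lie in (0, 1)")
        if abs(self.ratio - self.fraction / self.null_fraction) > 1e-12:
            raise ValueError("ratio must equal fraction / null")

    def to_row(self) -> dict:
        return {"species": self.species, "fraction": self.fraction,
                "null": self.null_fraction, "ratio": self.ratio,
                "replicate": self.replicate}


def ring_area_null(frame: Frame, cfg: AnalysisConfig,
                   radius: Optional[float] = None) -> float:
    """Fraction of the membrane area occupied by the ring: pi r^2/(Lx Ly).

    ``radius`` overrides the configured ring radius (r = 0 is the degenerate
    zero-area ring)."""
    r = cfg.ring_radius if radius is None else radius
    if r < 0:
        raise GeometryError("ring radius must be non-negative")
    lx, ly = frame.box[0], frame.box[1]
    if 2.0 * r > min(lx, ly):
        raise GeometryError(
            f"ring diameter {2 * r} nm exceeds the box ({lx} x {ly} nm)")
    return float(np.pi * r ** 2 / (lx * ly))


def _protein_center(frame: Frame, traj: Trajectory) -> np.ndarray:
    if traj.system.protein is None:
        raise StructuralError("enrichment analysis requires a protein")
    idx = traj.system.protein.all_bead_indices()
    return center_of_geometry(frame, idx, pbc_aware=True)


def ring_occupancy_fraction(traj: Trajectory, cfg: AnalysisConfig,
                            species: str,
                            mode: str = "cog",
                            lateral: bool = True,
                            replicate: Optional[str] = None,
                            use_window: bool = True) -> EnrichmentResult:
    """Fraction of `species` molecules inside the ring, averaged over frames.

    ``mode="cog"`` counts a molecule as inside when its centre of geometry
    is within the ring radius of the protein centre; ``mode="any-bead"``
    counts it when any of its beads is (sensitivity mode).  ``lateral``
    restricts the distance to xy (the membrane-area null is 2D); a 3D mode
    exists behind the flag.
    """
    mols = traj.system.molecules_of(species)
    if not mols:
        raise ValueError(f"species {species!r} absent from the system")
    sub = traj.window(cfg.analysis_window) if use_window else traj
    if traj.system.protein is None:
        raise StructuralError("enrichment analysis requires a protein")
    prot_idx = traj.system.protein.all_bead_indices()

    # (F, n_mols, beads_per_mol) coordinate gather; molecules of one species
    # share a bead count, so the index matrix is rectangular
    idx = np.stack([np.arange(m.start, m.stop) for m in mols])
    F = len(sub)
    boxes = sub.boxes
    axes = (0, 1, 2) if not lateral else (0, 1)

    # PBC-aware per-axis circular means (vectorised over frames x molecules)
    def circ_mean(x, L):  # x: (..., beads), L: (F, 1) or (F, 1, 1)
        theta = 2.0 * np.pi * x / L
        ang = np.arctan2(np.sin(theta).mean(axis=-1),
                         np.cos(theta).mean(axis=-1))
        Lr = L[..., 0]
        return (ang / (2.0 * np.pi) * Lr) % Lr

    if mode == "cog":
        d2 = np.zeros((F, len(mols)))
    elif mode == "any-bead":
        d2 = np.zeros((F,) + idx.shape)
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    for ax in axes:
        L = boxes[:, ax][:, None]
        prot_ax = circ_mean(sub.coordinates[:, prot_idx, ax], L)  # (F,)
        if mode == "cog":
            mol_ax = circ_mean(sub.coordinates[:, idx, ax],
                               L[:, :, None])  # (F, n_mols)
            delta = mol_ax - prot_ax[:, None]
            L2 = boxes[:, ax][:, None]
            delta -= L2 * np.round(delta / L2)
            d2 += delta ** 2
        else:
            delta = sub.coordinates[:, idx, ax] - prot_ax[:, None, None]
            L3 = boxes[:, ax][:, None, None]
            delta -= L3 * np.round(delta / L3)
            d2 += delta ** 2
    if mode == "cog":
        per_frame = (np.sqrt(d2) < cfg.ring_radius).mean(axis=1)
    else:
        per_frame = (np.sqrt(d2) < cfg.ring_radius).any(axis=2).mean(axis=1)

    null = ring_area_null(sub[0], cfg)
    frac = float(per_frame.mean())
    return EnrichmentResult(species, frac, per_frame, null, frac / null,
                            replicate)


def enrichment_summary(results: List[EnrichmentResult]) -> pd.DataFrame:
    """Tidy summary table (one row per species x replicate)."""
    return pd.DataFrame([r.to_row() for r in results])


def depletion_check(result: EnrichmentResult,
                    delta: float = 0.25) -> str:
    """Classify a species as 'enriched', 'depleted' or 'neutral'.

    Enriched when the enrichment ratio exceeds 1 + delta, depleted when it
    falls below 1 - delta."""
    if result.ratio > 1.0 + delta:
        return "enriched"
    if result.ratio < 1.0 - delta:
        return "depleted"
    return "neutral"
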