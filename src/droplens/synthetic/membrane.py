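"""Synthetic bilayer + ring-protein system construction.

Builds the geometry the trajectory analyses operate on: phospholipids in two
leaflets, neutral lipids between them near the midplane, and an oligomeric
protein ring whose protomers carry labelled hydrophobic-helix residues at a
configurable membrane depth.  No force field is involved — coordinates are
placed, not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..errors import PackingError
from ..system import MoleculeInstance, ProteinComplex, SystemLayout
from ..topology import (ChemicalGroup, MoleculeCategory, SpeciesRegistry,
                        builtin_registry)
from ..trajectory import Frame

#: minimal area per lipid per leaflet (nm^2) before the box counts as overfilled
MIN_AREA_PER_LIPID = 0.40

#: default residues modelled per protomer (hydrophobic helix segment)
DEFAULT_RESIDUES: Tuple[str, ...] = ("L159", "L162", "V163", "S165", "S166")

#: initial z offset (nm, upper leaflet) per chemical group
_Z0 = {
    ChemicalGroup.PL_HEADGROUP.value: 2.1,
    ChemicalGroup.PL_PHOSPHATE.value: 1.9,
    ChemicalGroup.PL_GLYCEROL_ESTER.value: 1.5,
    ChemicalGroup.ACYL_CHAIN.value: 0.8,
    ChemicalGroup.ACYL_TIP.value: 0.1,
    ChemicalGroup.CARBOXYL_FREE.value: 1.7,
}


@dataclass
class RingSpec:
    """Geometry of the synthetic protein ring."""

    protomer_count: int = 11
    ring_radius: float = 3.0  # nm, protomer centres sit on this circle
    helix_depth: float = 0.0  # nm relative to the bilayer midplane
    residues: Tuple[str, ...] = DEFAULT_RESIDUES
    beads_per_residue: int = 2  # backbone + sidechain
    labelled_residues: frozenset = frozenset({"S165", "S166"})

    def __post_init__(self) -> None:
        if self.protomer_count < 1:
            raise ValueError("protomer_count must be >= 1")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")


def _largest_remainder_counts(composition: Dict[str, float],
                              n_lipids: int) -> Dict[str, int]:
    total = sum(composition.values())
    if abs(total - 100.0) > 0.01:
        raise ValueError(
            f"composition percentages must sum to 100 (got {total})")
    exact = {s: pct / 100.0 * n_lipids for s, pct in composition.items()}
    counts = {s: int(np.floor(v)) for s, v in exact.items()}
    short = n_lipids - sum(counts.values())
    for s in sorted(exact, key=lambda s: exact[s] - counts[s],
                    reverse=True)[:short]:
        counts[s] += 1
    return counts


def build_membrane_system(composition: Dict[str, float],
                          n_lipids: int,
                          box: Sequence[float],
                          protein: Optional[RingSpec] = RingSpec(),
                          registry: Optional[SpeciesRegistry] = None,
                          seed: int = 0) -> Tuple[SystemLayout, Frame]:
    """Build a bilayer system with an optional protein ring.

    Parameters
    ----------
    composition:
        Per-species percentages of the `n_lipids` lipid molecules; must sum
        to 100 (e.g. ``{"TAG": 1, "SE": 3, "POPC": 96}``).
    box:
        Orthorhombic box lengths (nm).
    protein:
        Ring geometry, or ``None`` for a protein-free membrane.

    Deterministic for a fixed seed.
    """
    registry = registry or builtin_registry()
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(composition, n_lipids)

    if protein is not None and 2 * protein.ring_radius > min(box[0], box[1]):
        raise PackingError("protein ring does not fit in the box")
    per_leaflet = int(np.ceil(n_lipids / 2))
    if box[0] * box[1] / max(per_leaflet, 1) < MIN_AREA_PER_LIPID:
        raise PackingError(
            f"area per lipid below {MIN_AREA_PER_LIPID} nm^2: box too small "
            f"for {n_lipids} lipids")

    z_mid = box[2] / 2.0
    center = np.array([box[0] / 2.0, box[1] / 2.0])

    molecules: List[MoleculeInstance] = []
    coords: List[np.ndarray] = []
    mol_id = 0
    cursor = 0
    leaflet_toggle = 1

    # interleave species deterministically: all molecules of each species in
    # registry order (analysis never depends on ordering)
    for species in sorted(counts):
        topo = registry[species]
        is_leaflet = topo.category in (MoleculeCategory.PHOSPHOLIPID,
                                       MoleculeCategory.FREE_FATTY_ACID)
        for _ in range(counts[species]):
            xy = rng.uniform([0, 0], box[:2])
            sign = leaflet_toggle if is_leaflet else 0
            if is_leaflet:
                leaflet_toggle = -leaflet_toggle
            bead_xyz = np.empty((topo.n_beads, 3))
            for b in topo.beads:
                off = rng.normal(0.0, 0.08, size=2)
                z0 = _Z0.get(b.chemical_group.value, 0.0)
                z = z_mid + (sign * z0 if sign else rng.normal(0.0, 0.3))
                bead_xyz[b.index] = [
                    (xy[0] + off[0]) % box[0],
                    (xy[1] + off[1]) % box[1],
                    np.clip(z, 0.0, box[2]),
                ]
            molecules.append(MoleculeInstance(species, mol_id, cursor,
                                              cursor + topo.n_beads))
            coords.append(bead_xyz)
            cursor += topo.n_beads
            mol_id += 1

    protein_complex = None
    if protein is not None:
        prot_start = cursor
        residues: List[List[Tuple[str, List[int]]]] = []
        n_res = len(protein.residues)
        # tangential residue offsets sum to zero so each protomer's centre of
        # geometry sits exactly on the ring circle
        t_off = (np.arange(n_res) - (n_res - 1) / 2.0) * 0.45
        for p in range(protein.protomer_count):
            theta = 2.0 * np.pi * p / protein.protomer_count
            radial = np.array([np.cos(theta), np.sin(theta)])
            tangent = np.array([-np.sin(theta), np.cos(theta)])
            c_p = center + protein.ring_radius * radial
            protomer: List[Tuple[str, List[int]]] = []
            for r, label in enumerate(protein.residues):
                beads: List[int] = []
                for k in range(protein.beads_per_residue):
                    # backbone slightly outward, sidechain inward; offsets
                    # cancel within the residue
                    sgn = 1.0 if k == 0 else -1.0 / max(
                        protein.beads_per_residue - 1, 1)
                    pos2 = c_p + t_off[r] * tangent + 0.15 * sgn * radial
                    coords.append(np.array([[pos2[0] % box[0],
                                             pos2[1] % box[1],
                                             z_mid + protein.helix_depth]]))
                    beads.append(cursor)
                    cursor += 1
                protomer.append((label, beads))
            residues.append(protomer)
        molecules.append(MoleculeInstance("PROT", mol_id, prot_start, cursor))
        protein_complex = ProteinComplex(
            residues, frozenset(protein.labelled_residues))

    topologies = {s: registry[s] for s in registry.species()}
    system = SystemLayout(molecules, topologies, protein_complex,
                          protein_species="PROT")
    frame = Frame(0.0, box, np.vstack(coords))
    return system, frame
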