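"""System layout: which bead is what.

A :class:`SystemLayout` assigns every global bead index to exactly one
molecule instance (species + molecule id + contiguous index range) and,
optionally, to a ring-forming protein complex whose protomers carry labelled
residues.  All analyses select beads through :func:`select`, which composes
species / category / chemical-group / residue criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SelectionError, StructuralError
from .topology import (ChemicalGroup, MoleculeCategory, MoleculeTopology,
                       SpeciesRegistry)


@dataclass(frozen=True)
class MoleculeInstance:
    species: str
    mol_id: int
    start: int  # global bead index range [start, stop)
    stop: int

    @property
    def n_beads(self) -> int:
        return self.stop - self.start

    @property
    def bead_indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class ProteinComplex:
    """An oligomeric ring protein.

    ``residues`` holds, per protomer, the ordered list of
    (residue label, global bead index list).  ``labelled_residues`` marks the
    hydroxyl-bearing residues whose lipid contacts are analysed
    (default S165/S166).
    """

    residues: List[List[Tuple[str, List[int]]]]
    labelled_residues: frozenset = frozenset({"S165", "S166"})

    def __post_init__(self) -> None:
        seen: set = set()
        for protomer in self.residues:
            for _label, beads in protomer:
                for b in beads:
                    if b in seen:
                        raise StructuralError(
                            f"protein bead {b} belongs to two residues")
                    seen.add(b)
        labels = self.residue_labels()
        missing = set(self.labelled_residues) - labels
        if missing:
            raise StructuralError(
                f"labelled residues {sorted(missing)} not present "
                f"in the complex (labels: {sorted(labels)})")

    @property
    def n_protomers(self) -> int:
        return len(self.residues)

    def residue_labels(self) -> set:
        return {lab for protomer in self.residues for lab, _ in protomer}

    def residue_beads(self, label: str) -> List[np.ndarray]:
        """Per-protomer bead index arrays for one residue label.

        Raises StructuralError if the residue is absent from any protomer.
        """
        out = []
        for p, protomer in enumerate(self.residues):
            hits = [np.asarray(beads, dtype=int)
                    for lab, beads in protomer if lab == label]
            if not hits:
                raise StructuralError(
                    f"residue {label!r} absent from protomer {p}")
            out.append(np.concatenate(hits))
        return out

    def all_bead_indices(self) -> np.ndarray:
        idx = [b for protomer in self.residues
               for _lab, beads in protomer for b in beads]
        return np.asarray(sorted(idx), dtype=int)


@dataclass
class SystemLayout:
    """Molecule instances + optional protein, covering all beads exactly once."""

    molecules: List[MoleculeInstance]
    topologies: Dict[str, MoleculeTopology]
    protein: Optional[ProteinComplex] = None
    #: species of the protein molecule instance, if any
    protein_species: str = "PROT"

    def __post_init__(self) -> None:
        covered = np.zeros(self.n_beads, dtype=bool)
        for m in self.molecules:
            if m.start < 0 or m.stop > self.n_beads or m.start >= m.stop:
                raise StructuralError(f"bad bead range for molecule {m}")
            if covered[m.start:m.stop].any():
                raise StructuralError(
                    f"overlapping bead ranges at molecule {m.mol_id}")
            covered[m.start:m.stop] = True
        if not covered.all():
            raise StructuralError("bead ranges do not cover all beads")
        for m in self.molecules:
            if m.species == self.protein_species:
                continue
            topo = self.topologies.get(m.species)
            if topo is None:
                raise StructuralError(f"no topology for species {m.species!r}")
            if topo.n_beads != m.n_beads:
                raise StructuralError(
                    f"molecule {m.mol_id} ({m.species}) has {m.n_beads} beads, "
                    f"topology declares {topo.n_beads}")

    @property
    def n_beads(self) -> int:
        return max(m.stop for m in self.molecules)

    # ---- per-bead annotation arrays (cached) --------------------------------

    @cached_property
    def bead_species(self) -> np.ndarray:
        arr = np.empty(self.n_beads, dtype=object)
        for m in self.molecules:
            arr[m.start:m.stop] = m.species
        return arr

    @cached_property
    def bead_category(self) -> np.ndarray:
        arr = np.empty(self.n_beads, dtype=object)
        for m in self.molecules:
            if m.species == self.protein_species:
                arr[m.start:m.stop] = MoleculeCategory.PROTEIN.value
            else:
                arr[m.start:m.stop] = \
                    self.topologies[m.species].category.value
        return arr

    @cached_property
    def bead_group(self) -> np.ndarray:
        arr = np.empty(self.n_beads, dtype=object)
        for m in self.molecules:
            if m.species == self.protein_species:
                continue
            topo = self.topologies[m.species]
            arr[m.start:m.stop] = [b.chemical_group.value for b in topo.beads]
        if self.protein is not None:
            # protein bead groups come from residue bead ordering:
            # first bead of a residue is backbone, the rest sidechain
            for protomer in self.protein.residues:
                for _lab, beads in protomer:
                    for k, b in enumerate(beads):
                        arr[b] = (ChemicalGroup.PROTEIN_BACKBONE.value if k == 0
                                  else ChemicalGroup.PROTEIN_SIDECHAIN.value)
        return arr

    @cached_property
    def bead_mol_id(self) -> np.ndarray:
        arr = np.empty(self.n_beads, dtype=int)
        for m in self.molecules:
            arr[m.start:m.stop] = m.mol_id
        return arr

    # ---- convenience --------------------------------------------------------

    def molecules_of(self, species: str) -> List[MoleculeInstance]:
        return [m for m in self.molecules if m.species == species]

    def species_present(self) -> List[str]:
        return sorted({m.species for m in self.molecules})

    def lipid_species(self) -> List[str]:
        cats = {MoleculeCategory.NEUTRAL_LIPID.value,
                MoleculeCategory.PHOSPHOLIPID.value,
                MoleculeCategory.FREE_FATTY_ACID.value}
        out = []
        for s in self.species_present():
            if s == self.protein_species:
                continue
            if self.topologies[s].category.value in cats:
                out.append(s)
        return out


def _as_list(x) -> list:
    if x is None:
        return []
    if isinstance(x, (str, bytes)):
        return [x]
    return list(x)


def select(system: SystemLayout,
           species=None,
           category=None,
           chemical_group=None,
           residue=None,
           exclude: Optional[np.ndarray] = None) -> np.ndarray:
    """Select global bead indices.

    Criteria given together are ANDed; a list of values within one criterion
    is ORed ("species TAG or SE").  NOT and general OR are set algebra on the
    returned arrays (``np.setdiff1d`` / ``np.union1d``) — selections are
    sorted index arrays and therefore compose cleanly.

    Raises
    ------
    SelectionError
        if a referenced label is unknown to the system.
    """
    mask = np.ones(system.n_beads, dtype=bool)

    wanted = _as_list(species)
    if wanted:
        known = set(system.species_present())
        for s in wanted:
            if s not in known:
                raise SelectionError(s, known)
        mask &= np.isin(system.bead_species, wanted)

    wanted = [MoleculeCategory(c).value for c in _as_list(category)]
    if wanted:
        mask &= np.isin(system.bead_category, wanted)

    wanted = [ChemicalGroup(g).value for g in _as_list(chemical_group)]
    if wanted:
        mask &= np.isin(system.bead_group, wanted)

    wanted = _as_list(residue)
    if wanted:
        if system.protein is None:
            raise SelectionError(wanted[0], set())
        known = system.protein.residue_labels()
        res_mask = np.zeros(system.n_beads, dtype=bool)
        for lab in wanted:
            if lab not in known:
                raise SelectionError(lab, known)
            for beads in system.protein.residue_beads(lab):
                res_mask[beads] = True
        mask &= res_mask

    idx = np.flatnonzero(mask)
    if exclude is not None:
        idx = np.setdiff1d(idx, np.asarray(exclude, dtype=int))
    return idx
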