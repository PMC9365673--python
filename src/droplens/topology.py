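"""Molecular species: bead chemistry, bonded topology and the species registry.

A coarse-grained molecule is an ordered list of beads, each tagged with a
chemical group (glycerol backbone, carboxyl ester, acyl chain, sterol body,
isoprene unit, ...).  The group tags are what the contact and density analyses
select on — e.g. "the carboxyl esters of TAG" or "phospholipid acyl-chain
tips".  The built-in registry provides simplified MARTINI-style topologies for
the neutral lipids handled here (TAG, SE, RE, SQL), oleic acid as a free fatty
acid, and POPC as the membrane phospholipid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import yaml

from .errors import StructuralError


class ChemicalGroup(str, enum.Enum):
    GLYCEROL_BACKBONE = "glycerol-backbone"
    CARBOXYL_ESTER = "carboxyl-ester"
    ACYL_CHAIN = "acyl-chain"
    STEROL_BODY = "sterol-body"
    ISOPRENE = "isoprene"
    PL_HEADGROUP = "pl-headgroup"
    PL_PHOSPHATE = "pl-phosphate"
    PL_GLYCEROL_ESTER = "pl-glycerol-ester"
    ACYL_TIP = "acyl-tip"
    CARBOXYL_FREE = "carboxyl-free"
    PROTEIN_BACKBONE = "protein-backbone"
    PROTEIN_SIDECHAIN = "protein-sidechain"
    SOLVENT = "solvent"
    ION = "ion"


class MoleculeCategory(str, enum.Enum):
    NEUTRAL_LIPID = "neutral-lipid"
    PHOSPHOLIPID = "phospholipid"
    FREE_FATTY_ACID = "free-fatty-acid"
    PROTEIN = "protein"
    SOLVENT = "solvent"
    ION = "ion"


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead of a molecule."""

    name: str
    chemical_group: ChemicalGroup
    index: int  # intra-molecule index, 0-based

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("bead name must be nonempty")
        if self.index < 0:
            raise ValueError("bead index must be >= 0")
        # accept plain strings for convenience
        object.__setattr__(
            self, "chemical_group", ChemicalGroup(self.chemical_group)
        )


@dataclass
class MoleculeTopology:
    """Species definition: beads plus bonded structure.

    ``bonds`` are pairs and ``angles`` triples of intra-molecule bead
    indices.  Validation enforces index bounds, no self-bonds and distinct
    angle members.
    """

    species: str
    category: MoleculeCategory
    beads: List[BeadSpec]
    bonds: List[Tuple[int, int]] = field(default_factory=list)
    angles: List[Tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.category = MoleculeCategory(self.category)
        n = len(self.beads)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructuralError(
                    f"{self.species}: bond ({i},{j}) out of range (n={n})")
            if i == j:
                raise StructuralError(f"{self.species}: self-bond on bead {i}")
        for i, j, k in self.angles:
            if not all(0 <= x < n for x in (i, j, k)):
                raise StructuralError(
                    f"{self.species}: angle ({i},{j},{k}) out of range")
            if len({i, j, k}) != 3:
                raise StructuralError(
                    f"{self.species}: angle ({i},{j},{k}) repeats a bead")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead_names(self) -> List[str]:
        return [b.name for b in self.beads]

    def groups(self) -> List[ChemicalGroup]:
        return [b.chemical_group for b in self.beads]

    def indices_of_group(self, group: ChemicalGroup | str) -> List[int]:
        group = ChemicalGroup(group)
        return [b.index for b in self.beads if b.chemical_group == group]


def _chain(species: str, category: MoleculeCategory,
           spec: Sequence[Tuple[str, ChemicalGroup]],
           bonds: Sequence[Tuple[int, int]],
           ) -> MoleculeTopology:
    beads = [BeadSpec(name, grp, i) for i, (name, grp) in enumerate(spec)]
    bonds = [tuple(b) for b in bonds]
    # angles for every pair of bonds sharing a middle bead along chains
    adj: Dict[int, List[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    angles = []
    for mid, nbrs in sorted(adj.items()):
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], mid, nbrs[b]))
    return MoleculeTopology(species, category, beads, list(bonds), angles)


G = ChemicalGroup


def tag_topology() -> MoleculeTopology:
    """Triacylglycerol: glycerol backbone, three carboxyl esters, three
    four-bead acyl chains (trioleoyl-like)."""
    spec = [("GLY", G.GLYCEROL_BACKBONE)]
    bonds = []
    for c, chain in enumerate("ABC"):
        es = len(spec)
        spec.append((f"ES{c + 1}", G.CARBOXYL_ESTER))
        bonds.append((0, es))
        prev = es
        for k in range(1, 5):
            idx = len(spec)
            spec.append((f"C{k}{chain}", G.ACYL_CHAIN))
            bonds.append((prev, idx))
            prev = idx
    return _chain("TAG", MoleculeCategory.NEUTRAL_LIPID, spec, bonds)


def se_topology() -> MoleculeTopology:
    """Cholesteryl-oleate-like steryl ester: one carboxyl ester joining a
    four-bead sterol body to a four-bead acyl chain."""
    spec = ([(f"R{k}", G.STEROL_BODY) for k in range(1, 5)]
            + [("ES1", G.CARBOXYL_ESTER)]
            + [(f"C{k}", G.ACYL_CHAIN) for k in range(1, 5)])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8)]
    return _chain("SE", MoleculeCategory.NEUTRAL_LIPID, spec, bonds)


def re_topology() -> MoleculeTopology:
    """Retinyl-ester-like lipid: three isoprene-derived beads for the retinyl
    moiety, one carboxyl ester, a four-bead acyl chain."""
    spec = ([(f"I{k}", G.ISOPRENE) for k in range(1, 4)]
            + [("ES1", G.CARBOXYL_ESTER)]
            + [(f"C{k}", G.ACYL_CHAIN) for k in range(1, 5)])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7)]
    return _chain("RE", MoleculeCategory.NEUTRAL_LIPID, spec, bonds)


def sql_topology() -> MoleculeTopology:
    """Squalene: six isoprene units mapped one bead each, a linear chain
    (5 bonds, 4 angles)."""
    spec = [(f"I{k}", G.ISOPRENE) for k in range(1, 7)]
    bonds = [(k, k + 1) for k in range(5)]
    return _chain("SQL", MoleculeCategory.NEUTRAL_LIPID, spec, bonds)


def ffa_topology() -> MoleculeTopology:
    """Oleic-acid-like free fatty acid: free carboxyl head + acyl chain."""
    spec = ([("COO", G.CARBOXYL_FREE)]
            + [(f"C{k}", G.ACYL_CHAIN) for k in range(1, 5)])
    bonds = [(k, k + 1) for k in range(4)]
    return _chain("FFA", MoleculeCategory.FREE_FATTY_ACID, spec, bonds)


def popc_topology() -> MoleculeTopology:
    """POPC: choline head, phosphate, two glycerol-ester beads, two four-bead
    acyl chains whose terminal beads are tagged acyl-tip (used to register
    z-density profiles to the bilayer midplane)."""
    spec = [("NC3", G.PL_HEADGROUP), ("PO4", G.PL_PHOSPHATE),
            ("GL1", G.PL_GLYCEROL_ESTER), ("GL2", G.PL_GLYCEROL_ESTER)]
    bonds = [(0, 1), (1, 2), (2, 3)]
    for chain, root in (("A", 2), ("B", 3)):
        prev = root
        for k in range(1, 5):
            idx = len(spec)
            grp = G.ACYL_TIP if k == 4 else G.ACYL_CHAIN
            spec.append((f"C{k}{chain}", grp))
            bonds.append((prev, idx))
            prev = idx
    return _chain("POPC", MoleculeCategory.PHOSPHOLIPID, spec, bonds)


class SpeciesRegistry:
    """Maps GRO residue names to molecule topologies.

    GRO files carry no molecule block; molecules are inferred from runs of
    (residue number, residue name), with the registry supplying each
    species' bead count and chemistry.  Residue names of the form
    ``<letter><digits>`` (S165, L159, ...) that are not registered species
    are interpreted as protein residues.
    """

    def __init__(self, topologies: Dict[str, MoleculeTopology] | None = None):
        self.topologies: Dict[str, MoleculeTopology] = dict(topologies or {})

    def register(self, topo: MoleculeTopology) -> None:
        self.topologies[topo.species] = topo

    def __contains__(self, species: str) -> bool:
        return species in self.topologies

    def __getitem__(self, species: str) -> MoleculeTopology:
        return self.topologies[species]

    def species(self) -> List[str]:
        return sorted(self.topologies)

    @staticmethod
    def is_protein_residue(resname: str) -> bool:
        return (len(resname) >= 2 and resname[0].isalpha()
                and resname[1:].isdigit())

    def to_yaml(self, path) -> None:
        doc = {}
        for name, t in sorted(self.topologies.items()):
            doc[name] = {
                "category": t.category.value,
                "beads": [[b.name, b.chemical_group.value] for b in t.beads],
                "bonds": [list(b) for b in t.bonds],
                "angles": [list(a) for a in t.angles],
            }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        reg = cls()
        for name, spec in doc.items():
            beads = [BeadSpec(n, g, i)
                     for i, (n, g) in enumerate(spec["beads"])]
            reg.register(MoleculeTopology(
                name, spec["category"], beads,
                [tuple(b) for b in spec.get("bonds", [])],
                [tuple(a) for a in spec.get("angles", [])]))
        return reg


def builtin_registry() -> SpeciesRegistry:
    """Registry with the built-in lipid species."""
    reg = SpeciesRegistry()
    for factory in (tag_topology, se_topology, re_topology, sql_topology,
                    ffa_topology, popc_topology):
        reg.register(factory())
    return reg
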