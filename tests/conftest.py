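import numpy as np
import pytest

from droplens.config import AnalysisConfig
from droplens.system import MoleculeInstance, ProteinComplex, SystemLayout
from droplens.topology import (BeadSpec, MoleculeTopology, SpeciesRegistry,
                               builtin_registry)
from droplens.trajectory import Frame, Trajectory


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def registry():
    return builtin_registry()


def make_simple_topology(name, n_beads, category="neutral-lipid",
                         group="acyl-chain"):
    beads = [BeadSpec(f"B{k + 1}", group, k) for k in range(n_beads)]
    bonds = [(k, k + 1) for k in range(n_beads - 1)]
    return MoleculeTopology(name, category, beads, bonds, [])


def make_system(species_counts, topologies, protein_residues=None,
                labelled=frozenset()):
    """Assemble a SystemLayout from (species -> count) plus optional protein.

    ``protein_residues`` is a list of protomers, each a list of
    (label, n_beads).
    """
    molecules = []
    cursor = 0
    mol_id = 0
    for sp, count in species_counts.items():
        topo = topologies[sp]
        for _ in range(count):
            molecules.append(MoleculeInstance(sp, mol_id, cursor,
                                              cursor + topo.n_beads))
            cursor += topo.n_beads
            mol_id += 1
    protein = None
    if protein_residues:
        start = cursor
        protomers = []
        for protomer in protein_residues:
            rows = []
            for label, nb in protomer:
                rows.append((label, list(range(cursor, cursor + nb))))
                cursor += nb
            protomers.append(rows)
        molecules.append(MoleculeInstance("PROT", mol_id, start, cursor))
        protein = ProteinComplex(protomers, frozenset(labelled))
    return SystemLayout(molecules, topologies, protein,
                        protein_species="PROT")


def make_trajectory(system, coords_list, box=(20.0, 20.0, 10.0), dt=1000.0):
    frames = [Frame(k * dt, np.asarray(box), np.asarray(c, dtype=float))
              for k, c in enumerate(coords_list)]
    return Trajectory.from_frames(system, frames)
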