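"""System layout as a structured YAML sidecar.

The frames-table trajectory format carries no chemistry, so pipelines save
the SystemLayout (species runs, topologies, protein residues) next to it.
"""

from __future__ import annotations

from typing import List

import yaml

from ..system import MoleculeInstance, ProteinComplex, SystemLayout
from ..topology import BeadSpec, MoleculeTopology


def layout_to_yaml(system: SystemLayout, path) -> None:
    mols: List[dict] = []
    for m in system.molecules:
        if m.species == system.protein_species:
            mols.append({"protein_block": True,
                         "start": int(m.start), "stop": int(m.stop)})
        else:
            if (mols and not mols[-1].get("protein_block")
                    and mols[-1]["species"] == m.species):
                mols[-1]["count"] += 1
            else:
                mols.append({"species": m.species, "count": 1})
    doc = {"molecules": mols, "topologies": {}}
    for name, t in sorted(system.topologies.items()):
        doc["topologies"][name] = {
            "category": t.category.value,
            "beads": [[b.name, b.chemical_group.value] for b in t.beads],
            "bonds": [list(b) for b in t.bonds],
            "angles": [list(a) for a in t.angles],
        }
    if system.protein is not None:
        doc["protein"] = {
            "labelled": sorted(system.protein.labelled_residues),
            "protomers": [
                [[lab, [int(b) for b in beads]] for lab, beads in protomer]
                for protomer in system.protein.residues
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def layout_from_yaml(path) -> SystemLayout:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    topologies = {}
    for name, spec in doc.get("topologies", {}).items():
        beads = [BeadSpec(n, g, i) for i, (n, g) in enumerate(spec["beads"])]
        topologies[name] = MoleculeTopology(
            name, spec["category"], beads,
            [tuple(b) for b in spec.get("bonds", [])],
            [tuple(a) for a in spec.get("angles", [])])
    molecules: List[MoleculeInstance] = []
    cursor = 0
    mol_id = 0
    for entry in doc["molecules"]:
        if entry.get("protein_block"):
            start, stop = int(entry["start"]), int(entry["stop"])
            molecules.append(MoleculeInstance("PROT", mol_id, start, stop))
            mol_id += 1
            cursor = stop
        else:
            topo = topologies[entry["species"]]
            for _ in range(int(entry["count"])):
                molecules.append(MoleculeInstance(
                    entry["species"], mol_id, cursor, cursor + topo.n_beads))
                cursor += topo.n_beads
                mol_id += 1
    protein = None
    if "protein" in doc:
        protein = ProteinComplex(
            [[(lab, list(beads)) for lab, beads in protomer]
             for protomer in doc["protein"]["protomers"]],
            frozenset(doc["protein"].get("labelled", [])))
    return SystemLayout(molecules, topologies, protein,
                        protein_species="PROT")
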