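"""Fixed-column GRO coordinate I/O with molecule inference.

The dialect read and written here is the classic fixed-width layout:
title line (optionally carrying ``t= <ps>``), atom count, atom records
``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` (velocities, if present, are ignored), and
a box line.  Only orthorhombic boxes are accepted.

GRO has no molecule block, so molecules are inferred from runs of
(residue number, residue name): residue names found in the species registry
become lipid/solvent molecules with the registry's bead count; residue names
of the form letter+digits (S165, L159, ...) are protein residues.
Consecutive protein residues are grouped into protomers by detecting the
minimal repeating unit of the residue-label sequence.
"""

from __future__ import annotations

import re
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import GeometryError, ParseError, StructuralError
from ..system import MoleculeInstance, ProteinComplex, SystemLayout
from ..topology import SpeciesRegistry, builtin_registry
from ..trajectory import Frame

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")

PROTEIN_SPECIES = "PROT"


# ---------------------------------------------------------------------------
# writing

def write_coordinates(system: SystemLayout, frame: Frame, path,
                      title: Optional[str] = None) -> None:
    """Write one frame as GRO text (positions rounded to 3 decimals, nm)."""
    fh = open(path, "w") if not hasattr(path, "write") else path
    try:
        _write_frame(fh, system, frame, title)
    finally:
        if fh is not path:
            fh.close()


def _write_frame(fh, system: SystemLayout, frame: Frame,
                 title: Optional[str] = None) -> None:
    if frame.n_beads != system.n_beads:
        raise StructuralError(
            f"frame has {frame.n_beads} beads, system {system.n_beads}")
    if not np.all(np.isfinite(frame.coordinates)):
        raise ValueError("coordinates contain non-finite values")
    fh.write((title or f"droplens t= {frame.time:.3f}") + "\n")
    fh.write(f"{frame.n_beads:5d}\n")
    atom_id = 0
    res_id = 0
    for m in system.molecules:
        if m.species == system.protein_species and system.protein is not None:
            for protomer in system.protein.residues:
                for label, beads in protomer:
                    res_id += 1
                    for k, b in enumerate(beads):
                        name = "BB" if k == 0 else f"SC{k}"
                        atom_id += 1
                        _write_atom(fh, res_id, label, name, atom_id,
                                    frame.coordinates[b])
        else:
            topo = system.topologies[m.species]
            res_id += 1
            for k, b in enumerate(range(m.start, m.stop)):
                atom_id += 1
                _write_atom(fh, res_id, m.species, topo.beads[k].name,
                            atom_id, frame.coordinates[b])
    fh.write("{:10.5f}{:10.5f}{:10.5f}\n".format(*frame.box))


def _write_atom(fh, res_id, resname, atomname, atom_id, xyz) -> None:
    fh.write("{:5d}{:<5s}{:>5s}{:5d}{:8.3f}{:8.3f}{:8.3f}\n".format(
        res_id % 100000, resname[:5], atomname[:5], atom_id % 100000,
        xyz[0], xyz[1], xyz[2]))


# ---------------------------------------------------------------------------
# reading

def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 44:
        raise ParseError(f"line {lineno}: atom record too short "
                         f"({len(line.rstrip())} < 44 columns)")
    try:
        res_id = int(line[0:5])
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed atom record: {exc}") from exc
    if not resname or not atomname:
        raise ParseError(f"line {lineno}: empty residue or atom name")
    return res_id, resname, atomname, (x, y, z)


def _parse_box_line(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed box line") from exc
    if len(vals) < 3:
        raise ParseError(f"line {lineno}: box line needs >= 3 numbers")
    if len(vals) > 3 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise GeometryError(
            f"line {lineno}: triclinic box not supported "
            "(off-diagonal box vectors present)")
    box = np.asarray(vals[:3], dtype=float)
    if not np.all(box > 0):
        raise GeometryError(f"line {lineno}: non-positive box length")
    return box


def _minimal_period(labels: Sequence[str]) -> int:
    n = len(labels)
    for p in range(1, n + 1):
        if n % p == 0 and list(labels) == list(labels[:p]) * (n // p):
            return p
    return n


def _infer_layout(records, registry: SpeciesRegistry,
                  labelled_residues=None) -> SystemLayout:
    """Build a SystemLayout from parsed atom records of one frame."""
    # group into runs of (res_id, resname)
    runs: List[Tuple[str, int, int]] = []  # (resname, start, stop)
    prev_key = None
    for k, (res_id, resname, _an, _xyz) in enumerate(records):
        key = (res_id, resname)
        if key != prev_key:
            runs.append((resname, k, k + 1))
            prev_key = key
        else:
            name, start, _ = runs[-1]
            runs[-1] = (name, start, k + 1)

    molecules: List[MoleculeInstance] = []
    protein_res: List[Tuple[str, List[int]]] = []
    protein_range: Optional[Tuple[int, int]] = None
    mol_id = 0

    def flush_protein():
        nonlocal mol_id, protein_range
        if not protein_res:
            return None
        labels = [lab for lab, _ in protein_res]
        period = _minimal_period(labels)
        protomers = [protein_res[i:i + period]
                     for i in range(0, len(protein_res), period)]
        start, stop = protein_range
        molecules.append(MoleculeInstance(PROTEIN_SPECIES, mol_id, start, stop))
        mol_id += 1
        labels_set = {lab for lab, _ in protein_res}
        lab = (frozenset(labelled_residues) if labelled_residues is not None
               else frozenset({"S165", "S166"} & labels_set))
        return ProteinComplex([list(p) for p in protomers], lab)

    protein: Optional[ProteinComplex] = None
    for resname, start, stop in runs:
        if resname in registry:
            if protein_res:
                protein = flush_protein()
                protein_res.clear()
                protein_range = None
            topo = registry[resname]
            if stop - start != topo.n_beads:
                raise StructuralError(
                    f"residue {resname!r}: {stop - start} atoms, topology "
                    f"declares {topo.n_beads} beads")
            molecules.append(MoleculeInstance(resname, mol_id, start, stop))
            mol_id += 1
        elif SpeciesRegistry.is_protein_residue(resname):
            protein_res.append((resname, list(range(start, stop))))
            protein_range = ((protein_range[0] if protein_range else start),
                             stop)
        else:
            raise StructuralError(
                f"residue name {resname!r} not in the species registry "
                "and not a protein residue label")
    if protein_res:
        protein = flush_protein()

    topos = {s: registry[s] for s in registry.species()}
    return SystemLayout(molecules, topos, protein,
                        protein_species=PROTEIN_SPECIES)


def _read_one_frame(fh, lineno: int, default_time: float):
    title = fh.readline()
    if not title:
        return None, lineno
    lineno += 1
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else default_time

    count_line = fh.readline()
    if not count_line:
        raise ParseError(f"line {lineno + 1}: missing atom count")
    lineno += 1
    try:
        n_atoms = int(count_line.strip())
    except ValueError as exc:
        raise ParseError(
            f"line {lineno}: atom count is not an integer: "
            f"{count_line.strip()!r}") from exc

    records = []
    for _ in range(n_atoms):
        line = fh.readline()
        lineno += 1
        if not line or not line.strip():
            raise StructuralError(
                f"line {lineno}: file declares {n_atoms} atoms but record "
                f"{len(records) + 1} is missing")
        # a premature box line (3 floats, short record) is an atom shortfall
        if len(line.rstrip("\n")) < 44 and len(line.split()) == 3:
            raise StructuralError(
                f"line {lineno}: file declares {n_atoms} atoms but only "
                f"{len(records)} records found before the box line")
        records.append(_parse_atom_line(line, lineno))

    box_line = fh.readline()
    lineno += 1
    if not box_line or not box_line.strip():
        raise StructuralError(f"line {lineno}: missing box line")
    box = _parse_box_line(box_line, lineno)
    return (time, records, box), lineno


def read_coordinates(path, registry: Optional[SpeciesRegistry] = None,
                     labelled_residues=None
                     ) -> Tuple[SystemLayout, Frame]:
    """Read a single-frame GRO file -> (SystemLayout, Frame)."""
    registry = registry or builtin_registry()
    with open(path) as fh:
        parsed, _ = _read_one_frame(fh, 0, default_time=0.0)
    if parsed is None:
        raise ParseError(f"{path}: empty file")
    time, records, box = parsed
    system = _infer_layout(records, registry, labelled_residues)
    coords = np.asarray([xyz for _r, _n, _a, xyz in records], dtype=float)
    return system, Frame(time, box, coords)


def read_gro_frames(path, registry: Optional[SpeciesRegistry] = None,
                    labelled_residues=None
                    ) -> Tuple[SystemLayout, List[Frame]]:
    """Read a (possibly concatenated multi-frame) GRO file."""
    registry = registry or builtin_registry()
    frames: List[Frame] = []
    system: Optional[SystemLayout] = None
    lineno = 0
    with open(path) as fh:
        k = 0
        while True:
            parsed, lineno = _read_one_frame(fh, lineno, default_time=float(k))
            if parsed is None:
                break
            time, records, box = parsed
            if system is None:
                system = _infer_layout(records, registry, labelled_residues)
            elif len(records) != system.n_beads:
                raise StructuralError(
                    f"frame {k}: {len(records)} beads, expected "
                    f"{system.n_beads}")
            coords = np.asarray([xyz for *_x, xyz in records], dtype=float)
            frames.append(Frame(time, box, coords))
            k += 1
    if system is None or not frames:
        raise ParseError(f"{path}: no frames found")
    return system, frames
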