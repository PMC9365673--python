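"""Coordinate I/O: GRO dialect, frames tables, layouts, round trips."""

import numpy as np
import pytest

from droplens.errors import GeometryError, ParseError, StructuralError
from droplens.io import (layout_from_yaml, layout_to_yaml, read_coordinates,
                         read_trajectory, write_coordinates,
                         write_trajectory)
from droplens.topology import SpeciesRegistry
from droplens.trajectory import Frame, Trajectory
from droplens.synthetic import RingSpec, build_membrane_system

from conftest import make_simple_topology, make_system, make_trajectory

THREE_BEAD_GRO = """\
hand-written fixture t= 0.0
    3
    1XXX     B1    1   1.000   2.000   3.000
    1XXX     B2    2   1.500   2.500   3.500
    1XXX     B3    3   4.000   5.000   6.000
  10.00000  10.00000  10.00000
"""


@pytest.fixture
def toy_registry():
    reg = SpeciesRegistry()
    reg.register(make_simple_topology("XXX", 3))
    return reg


def test_hand_written_fixture_reads_exactly(tmp_path, toy_registry):
    p = tmp_path / "three.gro"
    p.write_text(THREE_BEAD_GRO)
    system, frame = read_coordinates(p, toy_registry)
    assert frame.n_beads == 3
    np.testing.assert_allclose(frame.coordinates,
                               [[1.0, 2.0, 3.0], [1.5, 2.5, 3.5],
                                [4.0, 5.0, 6.0]])
    np.testing.assert_allclose(frame.box, [10, 10, 10])
    assert len(system.molecules) == 1
    assert system.molecules[0].species == "XXX"


def test_atom_count_mismatch_is_structural_error(tmp_path, toy_registry):
    bad = THREE_BEAD_GRO.replace("    3\n", "    5\n")
    p = tmp_path / "bad.gro"
    p.write_text(bad)
    with pytest.raises(StructuralError):
        read_coordinates(p, toy_registry)


def test_malformed_column_error_names_line(tmp_path, toy_registry):
    lines = THREE_BEAD_GRO.splitlines()
    lines[3] = "    1XXX     B2    2   xxx     2.500   3.500"
    p = tmp_path / "mal.gro"
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParseError, match="line 4"):
        read_coordinates(p, toy_registry)


def test_triclinic_box_rejected(tmp_path, toy_registry):
    tric = THREE_BEAD_GRO.replace(
        "  10.00000  10.00000  10.00000",
        "  10.00000  10.00000  10.00000  0.0  0.0  5.0  0.0  0.0  0.0")
    p = tmp_path / "tric.gro"
    p.write_text(tric)
    with pytest.raises(GeometryError):
        read_coordinates(p, toy_registry)


def _small_membrane(seed=3):
    return build_membrane_system({"TAG": 10, "POPC": 90}, 40,
                                 (20.0, 20.0, 10.0), RingSpec(ring_radius=3),
                                 seed=seed)


def test_write_read_round_trip(tmp_path):
    system, frame = _small_membrane()
    p = tmp_path / "membrane.gro"
    write_coordinates(system, frame, p)
    system2, frame2 = read_coordinates(p)
    assert system2.n_beads == system.n_beads
    assert list(system2.bead_species) == list(system.bead_species)
    # coordinates round-trip to the printed precision (3 decimals)
    np.testing.assert_allclose(frame2.coordinates, frame.coordinates,
                               atol=5.1e-4)
    assert system2.protein is not None
    assert system2.protein.n_protomers == system.protein.n_protomers
    assert system2.protein.labelled_residues == \
        system.protein.labelled_residues


def test_written_gro_format_details(tmp_path, toy_registry):
    topo = make_simple_topology("XXX", 1)
    reg = SpeciesRegistry({"XXX": topo})
    system = make_system({"XXX": 1}, {"XXX": topo})
    frame = Frame(0.0, [10, 10, 10], [[0.0, 0.0, 0.0]])
    p = tmp_path / "one.gro"
    write_coordinates(system, frame, p)
    text = p.read_text().splitlines()
    assert "0.000   0.000   0.000" in text[2]
    assert text[3].split() == ["10.00000", "10.00000", "10.00000"]


def test_nonfinite_coordinates_rejected(tmp_path):
    topo = make_simple_topology("XXX", 1)
    system = make_system({"XXX": 1}, {"XXX": topo})
    frame = Frame(0.0, [10, 10, 10], [[np.nan, 0.0, 0.0]])
    with pytest.raises(ValueError):
        write_coordinates(system, frame, tmp_path / "nan.gro")


def test_concatenated_gro_and_tsv_cross_format(tmp_path):
    system, frame0 = _small_membrane()
    rng = np.random.default_rng(0)
    coords = np.stack([frame0.coordinates,
                       (frame0.coordinates + rng.normal(0, 0.1,
                        frame0.coordinates.shape)) % 20.0])
    traj = Trajectory(system, coords, [0.0, 1000.0],
                      np.tile(frame0.box, (2, 1)))
    gro_p = tmp_path / "traj.gro"
    tsv_p = tmp_path / "traj.tsv"
    write_trajectory(traj, gro_p)
    write_trajectory(traj, tsv_p)

    t_gro = read_trajectory(gro_p)
    assert len(t_gro) == 2
    assert np.all(np.diff(t_gro.times) > 0)
    t_tsv = read_trajectory(tsv_p, system=system)
    # both formats agree to the GRO printed precision
    np.testing.assert_allclose(t_gro.coordinates, t_tsv.coordinates,
                               atol=5.1e-4)
    # TSV round-trips at full float precision
    np.testing.assert_allclose(t_tsv.coordinates, traj.coordinates,
                               atol=1e-9)


def test_decreasing_time_rejected(tmp_path):
    system, frame0 = _small_membrane()
    f1 = Frame(1000.0, frame0.box, frame0.coordinates)
    f0 = Frame(0.0, frame0.box, frame0.coordinates)
    with pytest.raises(StructuralError):
        Trajectory.from_frames(system, [f1, f0])


def test_layout_yaml_round_trip(tmp_path):
    system, _ = _small_membrane()
    p = tmp_path / "layout.yaml"
    layout_to_yaml(system, p)
    system2 = layout_from_yaml(p)
    assert system2.n_beads == system.n_beads
    assert list(system2.bead_species) == list(system.bead_species)
    assert list(system2.bead_group) == list(system.bead_group)
    assert system2.protein.n_protomers == system.protein.n_protomers


def test_mdanalysis_reads_our_gro(tmp_path):
    """Independent reader oracle: MDAnalysis agrees with our writer."""
    mda = pytest.importorskip("MDAnalysis")
    system, frame = _small_membrane()
    p = tmp_path / "membrane.gro"
    write_coordinates(system, frame, p)
    u = mda.Universe(str(p))
    assert len(u.atoms) == system.n_beads
    np.testing.assert_allclose(u.atoms.positions / 10.0,  # Angstrom -> nm
                               frame.coordinates, atol=5.1e-4)
    np.testing.assert_allclose(u.dimensions[:3] / 10.0, frame.box,
                               atol=1e-3)
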