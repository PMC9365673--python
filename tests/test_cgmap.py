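"""Bead mapping, bonded-parameter extraction and Boltzmann inversion."""

import numpy as np
import pytest

from droplens.cgmap import (KB, BeadMapping, BondedParameters, MappedBead,
                            atomize_chain, bond_angle_deg, boltzmann_invert,
                            distribution_overlap, emit_parameter_file,
                            extract_bonded_distributions, map_to_beads,
                            parameters_from_distributions,
                            parse_parameter_file, sample_cg_bonded,
                            sample_chain_conformations, squalene_mapping)
from droplens.errors import StructuralError
from droplens.topology import sql_topology


# ---------------------------------------------------------------------------
# mapping

def test_equal_mass_midpoint():
    mapping = BeadMapping([MappedBead("B1", (0, 1), (1.0, 1.0))])
    coords = np.array([[0, 0, 0], [2, 0, 0]], dtype=float)
    np.testing.assert_allclose(map_to_beads(coords, mapping), [[1, 0, 0]])


def test_mass_weighted_centroid():
    mapping = BeadMapping([MappedBead("B1", (0, 1), (12.0, 1.0))])
    coords = np.array([[0, 0, 0], [1.3, 0, 0]])
    x = map_to_beads(coords, mapping)[0, 0]
    assert x == pytest.approx(0.1, abs=1e-12)


def test_squalene_maps_six_beads_five_bonds_four_angles():
    mapping, topo = squalene_mapping()
    assert mapping.n_beads == 6
    assert len(topo.bonds) == 5
    assert len(topo.angles) == 4
    assert sum(len(b.atom_indices) for b in mapping.beads) == 30


def test_atom_in_two_beads_rejected():
    with pytest.raises(StructuralError):
        BeadMapping([MappedBead("B1", (0, 1), (1.0, 1.0)),
                     MappedBead("B2", (1, 2), (1.0, 1.0))])


def test_mapping_commutes_with_rigid_motion():
    rng = np.random.default_rng(0)
    mapping, topo = squalene_mapping()
    coords = rng.normal(0, 1, size=(30, 3))
    beads = map_to_beads(coords, mapping)
    # rotation about z + translation
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    t = np.array([1.0, -2.0, 0.5])
    beads2 = map_to_beads(coords @ R.T + t, mapping)
    np.testing.assert_allclose(beads2, beads @ R.T + t, atol=1e-12)


# ---------------------------------------------------------------------------
# extraction

def test_rigid_molecule_zero_variance():
    mapping, topo = squalene_mapping()
    rng = np.random.default_rng(1)
    one = rng.normal(0, 1, size=(30, 3))
    coords = np.tile(one, (12, 1, 1))
    dists = extract_bonded_distributions(coords, mapping, topo)
    for st in list(dists.bonds.values()) + list(dists.angles.values()):
        assert st.variance == pytest.approx(0.0, abs=1e-24)


def test_colinear_angle_is_180():
    coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    assert bond_angle_deg(coords, 0, 1, 2) == pytest.approx(180.0)


def test_gaussian_bond_mean_recovered():
    rng = np.random.default_rng(2)
    n = 10_000
    lengths = rng.normal(0.47, 0.02, size=n)
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = lengths
    topo = sql_topology()
    from droplens.topology import BeadSpec, MoleculeTopology
    two = MoleculeTopology("DUO", "neutral-lipid",
                           [BeadSpec("I1", "isoprene", 0),
                            BeadSpec("I2", "isoprene", 1)], [(0, 1)], [])
    dists = extract_bonded_distributions(coords, None, two)
    assert dists.bonds[(0, 1)].mean == pytest.approx(lengths.mean(),
                                                     abs=1e-12)
    assert abs(dists.bonds[(0, 1)].mean - 0.47) < 0.001


def test_few_frames_warns():
    mapping, topo = squalene_mapping()
    coords = np.random.default_rng(3).normal(0, 1, size=(5, 30, 3))
    with pytest.warns(UserWarning, match="frames"):
        extract_bonded_distributions(coords, mapping, topo)


# ---------------------------------------------------------------------------
# Boltzmann inversion

def test_worked_force_constant_value():
    k = boltzmann_invert(0.01, 323.0, "bond")
    assert k == pytest.approx(0.0083145 * 323.0 / 0.01)
    assert k == pytest.approx(268.56, abs=0.005)


def test_zero_variance_rejected():
    with pytest.raises(ValueError):
        boltzmann_invert(0.0, 323.0, "bond")


def test_invert_sample_reinvert_round_trip():
    """k -> harmonic samples -> re-inverted k agrees within 5% at n=1e5."""
    params = BondedParameters({(0, 1): (0.47, 1250.0)},
                              {(0, 1, 2): (120.0, 25.0)}, 323.0)
    samples = sample_cg_bonded(params, 100_000, seed=4)
    var_b = samples["bonds"][(0, 1)].var(ddof=1)
    k = boltzmann_invert(var_b, 323.0, "bond")
    assert abs(k / 1250.0 - 1) < 0.05
    var_a = np.radians(samples["angles"][(0, 1, 2)]).var(ddof=1)
    kt = boltzmann_invert(var_a, 323.0, "angle")
    assert abs(kt / 25.0 - 1) < 0.05


def test_sampler_reproducible_and_centred():
    params = BondedParameters({(0, 1): (0.47, 1250.0)}, {}, 323.0)
    a = sample_cg_bonded(params, 5000, seed=5)["bonds"][(0, 1)]
    b = sample_cg_bonded(params, 5000, seed=5)["bonds"][(0, 1)]
    np.testing.assert_array_equal(a, b)
    se = np.sqrt(KB * 323.0 / 1250.0) / np.sqrt(5000)
    assert abs(a.mean() - 0.47) < 3 * se
    assert sample_cg_bonded(params, 0, seed=1)["bonds"][(0, 1)].size == 0


# ---------------------------------------------------------------------------
# overlap

def test_overlap_identical_and_disjoint():
    p = np.array([1.0, 2.0, 3.0])
    assert distribution_overlap(p, p) == pytest.approx(1.0)
    q = np.array([0.0, 0.0, 0.0, 5.0])
    with pytest.raises(ValueError):
        distribution_overlap(p, q)
    assert distribution_overlap(np.array([1.0, 0.0]),
                                np.array([0.0, 1.0])) == 0.0


def test_overlap_of_unit_gaussians_one_sd_apart():
    x = np.linspace(-8, 9, 3400)
    from scipy.stats import norm
    p = norm.pdf(x, 0, 1)
    q = norm.pdf(x, 1, 1)
    got = distribution_overlap(p, q)
    assert got == pytest.approx(0.617, abs=0.002)  # 2*Phi(-1/2)


# ---------------------------------------------------------------------------
# parameter file

def _chain_params():
    bonds = {(k, k + 1): (0.47 + 0.01 * k, 1000.0 + 50 * k)
             for k in range(5)}
    angles = {(k, k + 1, k + 2): (130.0 + 5 * k, 20.0 + k)
              for k in range(4)}
    return BondedParameters(bonds, angles, 323.0)


def test_emitted_block_has_chain_combinatorics():
    text = emit_parameter_file(_chain_params(), "SQL")
    section = None
    counts = {"bonds": 0, "angles": 0}
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("["):
            section = s.strip("[] ")
        elif s and not s.startswith(";") and section in counts:
            counts[section] += 1
    assert counts["bonds"] == 5
    assert counts["angles"] == 4


def test_parameter_file_round_trip():
    params = _chain_params()
    text = emit_parameter_file(params, "SQL")
    name, parsed = parse_parameter_file(text, temperature=323.0)
    assert name == "SQL"
    for pair, (r0, k) in params.bonds.items():
        assert parsed.bonds[pair][0] == pytest.approx(r0, abs=1e-4)
        assert parsed.bonds[pair][1] == pytest.approx(k, abs=0.01)
    for triple, (t0, kt) in params.angles.items():
        assert parsed.angles[triple][0] == pytest.approx(t0, abs=1e-3)


def test_empty_topology_rejected():
    with pytest.raises(ValueError):
        emit_parameter_file(BondedParameters({}, {}, 300.0), "SQL")


# ---------------------------------------------------------------------------
# full extract -> invert round trip through 3D conformations

def test_full_round_trip_through_conformations():
    """Chain conformations at planted (r0, theta0, k) -> mapped atoms ->
    extraction -> inversion recovers the plant within 5%."""
    params = BondedParameters(
        {(0, 1): (0.47, 1250.0), (1, 2): (0.50, 900.0)},
        {(0, 1, 2): (130.0, 30.0)}, 323.0)
    bead_traj = sample_chain_conformations(params, 8000, seed=6)
    coords, mapping = atomize_chain(bead_traj, atoms_per_bead=4, seed=7)
    from droplens.topology import BeadSpec, MoleculeTopology
    topo = MoleculeTopology(
        "TRI", "neutral-lipid",
        [BeadSpec(f"I{k + 1}", "isoprene", k) for k in range(3)],
        [(0, 1), (1, 2)], [(0, 1, 2)])
    dists = extract_bonded_distributions(coords, mapping, topo)
    got = parameters_from_distributions(dists, 323.0)
    for pair in params.bonds:
        r0, k = params.bonds[pair]
        assert got.bonds[pair][0] == pytest.approx(r0, rel=0.01)
        assert got.bonds[pair][1] == pytest.approx(k, rel=0.05)
    t0, kt = params.angles[(0, 1, 2)]
    assert got.angles[(0, 1, 2)][0] == pytest.approx(t0, rel=0.01)
    assert got.angles[(0, 1, 2)][1] == pytest.approx(kt, rel=0.05)
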