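"""z-density registration and single-linkage clustering."""

import numpy as np
import pytest

from droplens.config import AnalysisConfig
from droplens.errors import FitError
from droplens.spatial import (ClusterSummary, cluster_sizes, cluster_summary,
                              clustering_vs_concentration,
                              five_parameter_logistic, z_density_profile)
from droplens.system import select
from droplens.synthetic import (PlantedStatistics, RingSpec, ZLaw,
                                build_membrane_system,
                                simulate_planted_trajectory)
from droplens.synthetic.dynamics import default_z_laws
from droplens.trajectory import Frame, Trajectory

from conftest import make_simple_topology, make_system, make_trajectory


# ---------------------------------------------------------------------------
# clustering

def _bead_frame(points, box=(10.0, 10.0, 10.0)):
    return Frame(0.0, np.asarray(box), np.asarray(points, dtype=float))


def test_two_close_beads_one_cluster(cfg):
    f = _bead_frame([[1, 1, 1], [1.5, 1, 1]])
    assert cluster_sizes(f, cfg, [0, 1], by="beads") == [2]


def test_grid_beyond_cutoff_all_singletons(cfg):
    xs = np.arange(0, 3.5, 0.7)
    pts = [[x, y, 5.0] for x in xs for y in xs]
    f = _bead_frame(pts)
    sizes = cluster_sizes(f, cfg, range(len(pts)), by="beads")
    assert sizes == [1] * len(pts)


def brute_force_partition(points, box, cutoff):
    n = len(points)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = points[j] - points[i]
            d -= box * np.round(d / box)
            adj[i, j] = np.linalg.norm(d) < cutoff
    # transitive closure
    reach = adj.copy()
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    labels = -np.ones(n, dtype=int)
    next_label = 0
    for i in range(n):
        if labels[i] < 0:
            labels[reach[i]] = next_label
            next_label += 1
    return sorted(np.bincount(labels).tolist(), reverse=True)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_union_find_matches_transitive_closure(cfg, seed):
    rng = np.random.default_rng(seed)
    box = np.array([6.0, 6.0, 6.0])
    pts = rng.uniform(0, box, size=(50, 3))
    f = Frame(0.0, box, pts)
    got = cluster_sizes(f, cfg, range(50), by="beads")
    assert got == brute_force_partition(pts, box, cfg.cluster_cutoff)


def test_partition_refines_as_cutoff_decreases():
    rng = np.random.default_rng(9)
    box = np.array([8.0, 8.0, 8.0])
    pts = rng.uniform(0, box, size=(80, 3))
    f = Frame(0.0, box, pts)

    def labels_at(cutoff):
        cfg = AnalysisConfig(cluster_cutoff=cutoff)
        from droplens.spatial import UnionFind
        from scipy.spatial import cKDTree
        tree = cKDTree(pts, boxsize=box)
        uf = UnionFind(80)
        for i, j in tree.query_pairs(cutoff):
            uf.union(i, j)
        return uf.labels()

    coarse = labels_at(1.2)
    fine = labels_at(0.6)
    # every fine cluster lies inside one coarse cluster
    for lab in np.unique(fine):
        members = np.flatnonzero(fine == lab)
        assert len(np.unique(coarse[members])) == 1


def test_molecule_level_counts_molecules(cfg):
    # two 2-bead molecules bridged by a bead contact -> one 2-molecule cluster
    topo = make_simple_topology("NL", 2)
    system = make_system({"NL": 2}, {"NL": topo})
    f = _bead_frame([[1, 1, 1], [1.4, 1, 1], [1.8, 1, 1], [2.2, 1, 1]])
    sel = select(system, species="NL")
    sizes = cluster_sizes(f, cfg, sel, mol_ids=system.bead_mol_id[sel])
    assert sizes == [2]


# ---------------------------------------------------------------------------
# clustering vs concentration

def _summaries(fractions, concs):
    return [ClusterSummary(c, [[1]], f) for c, f in zip(concs, fractions)]


def test_step_response_midpoint_recovered():
    concs = [1, 2, 3, 4, 5, 6]
    y = [0.1, 0.1, 0.1, 0.8, 0.8, 0.8]  # threshold between 3 and 4
    fit = clustering_vs_concentration(_summaries(y, concs))
    assert 2.5 <= fit.midpoint <= 4.5  # within one concentration step


def test_constant_response_rejected():
    with pytest.raises(FitError):
        clustering_vs_concentration(_summaries([0.3] * 5, range(5)))


def test_monotone_plant_gives_monotone_fit():
    concs = np.array([1, 2, 4, 8, 16], dtype=float)
    y = [0.05, 0.1, 0.4, 0.7, 0.8]
    fit = clustering_vs_concentration(_summaries(y, concs))
    dense = five_parameter_logistic(np.linspace(1, 16, 50),
                                    *[fit.params[k] for k in "adcbg"])
    assert np.all(np.diff(dense) >= -1e-9)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        clustering_vs_concentration(_summaries([0.1, 0.5, 0.9], [1, 2, 3]))


# ---------------------------------------------------------------------------
# z-density profiles

def _density_system(n_frames=30, seed=2, probe_law=ZLaw(1.5, 0.3)):
    system, f0 = build_membrane_system({"TAG": 10, "POPC": 90}, 300,
                                       (30, 30, 14), None, seed=seed)
    z_laws = default_z_laws()
    z_laws[("TAG", "carboxyl-ester")] = probe_law
    plant = PlantedStatistics(z_laws=z_laws)
    traj, _ = simulate_planted_trajectory(system, f0, plant, n_frames,
                                          seed=seed + 1)
    return system, traj


def test_planted_gaussian_peak_recovered():
    system, traj = _density_system()
    sel = {"tag-esters": select(system, species="TAG",
                                chemical_group="carboxyl-ester")}
    prof = z_density_profile(traj, AnalysisConfig(), sel)[0]
    assert prof.density.max() == pytest.approx(1.0)
    assert prof.peak_z() == pytest.approx(1.5, abs=0.05)


def test_registration_translation_invariance():
    """Shifting every frame by a constant z leaves registered profiles
    unchanged."""
    system, traj = _density_system(n_frames=15)
    sel = {"probe": select(system, species="TAG",
                           chemical_group="carboxyl-ester")}
    cfg = AnalysisConfig()
    p0 = z_density_profile(traj, cfg, sel)[0]
    coords = traj.coordinates.copy()
    coords[:, :, 2] = (coords[:, :, 2] + 3.7) % traj.boxes[0, 2]
    traj2 = Trajectory(traj.system, coords, traj.times, traj.boxes)
    p1 = z_density_profile(traj2, cfg, sel)[0]
    assert p1.peak_z() == pytest.approx(p0.peak_z(), abs=cfg.z_bin + 1e-9)
    # identical up to single samples crossing a bin edge at the wrap
    np.testing.assert_allclose(p1.density, p0.density, atol=0.05)


def test_identical_plants_give_identical_profiles():
    system, traj = _density_system(n_frames=40)
    sel = {"a": select(system, species="POPC", chemical_group="acyl-tip"),
           "b": select(system, species="POPC", chemical_group="acyl-tip")}
    pa, pb = z_density_profile(traj, AnalysisConfig(), sel)
    np.testing.assert_allclose(pa.density, pb.density)


def test_empty_selection_rejected():
    system, traj = _density_system(n_frames=5)
    with pytest.raises(ValueError):
        z_density_profile(traj, AnalysisConfig(),
                          {"none": np.array([], dtype=int)})
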