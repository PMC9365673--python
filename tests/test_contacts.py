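"""Contact occupancy and dual-cutoff residence times."""

import numpy as np
import pytest

from droplens.config import AnalysisConfig
from droplens.contacts import (aggregate_occupancy, compare_species_binding,
                               residence_times_dual_cutoff,
                               residue_lipid_min_distance, residue_occupancy,
                               segment_dual_cutoff)
from droplens.geometry import pairwise_min_image_distances
from droplens.synthetic import (ContactKinetics, PlantedStatistics, RingSpec,
                                build_membrane_system,
                                simulate_planted_trajectory)
from droplens.trajectory import Frame, Trajectory

from conftest import make_simple_topology, make_system, make_trajectory


# ---------------------------------------------------------------------------
# the distance primitive

def test_min_distance_is_minimum_over_beads():
    f = Frame(0, [10, 10, 10],
              [[0, 0, 0], [0.4, 0, 0], [0.9, 0, 0]])
    assert residue_lipid_min_distance(f, [0], [1, 2]) == pytest.approx(0.4)
    assert residue_lipid_min_distance(f, [0, 1], [0, 1]) == 0.0


def test_min_distance_across_boundary_matches_brute_force():
    rng = np.random.default_rng(3)
    box = np.array([5.0, 7.0, 6.0])
    a = rng.uniform(0, box, size=(4, 3))
    b = rng.uniform(0, box, size=(5, 3))
    b[0] = [4.9, 0.05, 5.9]  # straddles the corner
    f = Frame(0, box, np.vstack([a, b]))
    got = residue_lipid_min_distance(f, range(4), range(4, 9))
    best = np.inf
    for i in range(4):
        for j in range(5):
            for img in np.ndindex(3, 3, 3):
                shift = (np.array(img) - 1) * box
                best = min(best, np.linalg.norm(b[j] + shift - a[i]))
    assert got == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# a hand-controllable single-residue system

def _distance_system(distances, box=(20.0, 20.0, 10.0), dt=1000.0):
    """One 1-bead lipid at prescribed distances from a 1-bead residue."""
    topo = make_simple_topology("LIP", 1)
    system = make_system({"LIP": 1}, {"LIP": topo},
                         protein_residues=[[("S165", 1)]],
                         labelled={"S165"})
    coords = []
    for d in distances:
        c = np.zeros((2, 3))
        c[0] = [10.0 + d, 10.0, 5.0]  # lipid
        c[1] = [10.0, 10.0, 5.0]      # residue bead
        coords.append(c)
    return system, make_trajectory(system, coords, box, dt)


def test_hand_counted_occupancy():
    """Contact in frames {2, 3, 6, 9} of 10 -> occupancy 0.4."""
    d = [2.0] * 10
    for k in (2, 3, 6, 9):
        d[k] = 0.5
    system, traj = _distance_system(d)
    cfg = AnalysisConfig(analysis_window=1.0)
    recs = residue_occupancy(traj, cfg, "S165", "LIP")
    assert len(recs) == 1
    assert recs[0].occupancy == pytest.approx(0.4)


def test_always_in_contact_occupancy_one():
    system, traj = _distance_system([0.3] * 5)
    recs = residue_occupancy(traj, AnalysisConfig(analysis_window=1.0),
                             "S165", "LIP")
    assert recs[0].occupancy == 1.0


def test_dual_cutoff_hand_trace():
    """d = [0.50, 0.60, 0.90, 1.20] with (0.55, 1.0) -> one 3-frame event."""
    events = segment_dual_cutoff(np.array([0.50, 0.60, 0.90, 1.20]),
                                 0.55, 1.0)
    assert events == [(0, 3, False)]


def test_dual_cutoff_full_pipeline_hand_trace():
    system, traj = _distance_system([0.50, 0.60, 0.90, 1.20])
    out = residence_times_dual_cutoff(traj, AnalysisConfig(), "S165", 0)
    ev = out[0].events
    assert len(ev) == 1
    assert ev.iloc[0]["n_frames"] == 3
    assert not ev.iloc[0]["censored"]
    assert ev.iloc[0]["duration_ns"] == pytest.approx(3.0)  # 1 ns frames


def test_equal_cutoffs_reduce_to_run_lengths():
    rng = np.random.default_rng(0)
    d = rng.uniform(0.2, 1.4, size=200)
    c = 0.7
    events = segment_dual_cutoff(d, c, c)
    runs = []
    n = 0
    for v in d:
        if v < c:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    assert [e[1] for e in events] == runs


def test_censoring_flag_at_trajectory_end():
    events = segment_dual_cutoff(np.array([0.5, 0.6, 0.7]), 0.55, 1.0)
    assert events == [(0, 3, True)]


def test_dual_events_dominate_single_cutoff_events():
    """Each dual-cutoff event contains >= 1 single-cutoff event and is at
    least as long (stochastic dominance per series)."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        d = rng.uniform(0.3, 1.3, size=300)
        dual = segment_dual_cutoff(d, 0.55, 1.0)
        single = segment_dual_cutoff(d, 0.55, 0.55)
        for start, length, _c in dual:
            inner = [s for s in single
                     if start <= s[0] < start + length]
            assert inner
            assert length >= max(s[1] for s in inner)


def test_occupancy_monotone_in_cutoff():
    rng = np.random.default_rng(5)
    d = rng.uniform(0.1, 2.0, size=60)
    system, traj = _distance_system(d)
    occs = []
    for cutoff in (1.2, 0.9, 0.6, 0.3):
        cfg = AnalysisConfig(contact_cutoff=cutoff, analysis_window=1.0)
        occs.append(residue_occupancy(traj, cfg, "S165", "LIP")[0].occupancy)
    assert all(a >= b for a, b in zip(occs, occs[1:]))


# ---------------------------------------------------------------------------
# group-resolved occupancy on the planted generator

def _kinetic_traj(n_frames=80, seed=4):
    system, f0 = build_membrane_system(
        {"TAG": 10, "SQL": 10, "POPC": 80}, 100, (24, 24, 10),
        RingSpec(protomer_count=3), seed=seed)
    plant = PlantedStatistics(contact_kinetics={
        ("S165", "TAG"): ContactKinetics(0.5, 0.02),
        ("S165", "SQL"): ContactKinetics(0.5, 0.5),
    })
    traj, gt = simulate_planted_trajectory(system, f0, plant, n_frames,
                                           seed=seed + 1)
    return system, traj, gt


def test_group_decomposition_consistency():
    """Whole-lipid contact (any bead) equals the OR over chemical groups,
    so the sum of group indicators bounds it from above, per frame."""
    system, traj, _ = _kinetic_traj()
    cfg = AnalysisConfig(analysis_window=1.0)
    whole = residue_occupancy(traj, cfg, "S165", "TAG")
    by_group = residue_occupancy(traj, cfg, "S165", "TAG", by_group=True)
    for p in range(3):
        w = [r.occupancy for r in whole if r.protomer == p][0]
        gs = [r.occupancy for r in by_group if r.protomer == p]
        assert max(gs) <= w + 1e-12
        assert sum(gs) >= w - 1e-12


def test_aggregate_reports_min_median_max():
    system, traj, _ = _kinetic_traj(n_frames=30)
    recs = residue_occupancy(traj, AnalysisConfig(), "S165", "TAG")
    agg = aggregate_occupancy(recs)
    assert set(["min", "median", "max"]).issubset(agg.columns)
    assert (agg["min"] <= agg["median"]).all()
    assert (agg["median"] <= agg["max"]).all()


def test_species_binding_ranking_follows_planted_dwell():
    """Planted mean dwells 50 vs 2 frames -> TAG outranks SQL."""
    system, traj, gt = _kinetic_traj(n_frames=300, seed=8)
    cfg = AnalysisConfig()
    kin_ids = {sp: gt.contact_pairs.loc[gt.contact_pairs["species"] == sp,
                                        "mol_id"].tolist()
               for sp in ("TAG", "SQL")}
    df = compare_species_binding(traj, cfg, ["TAG", "SQL"],
                                 residues=["S165"], mol_ids=kin_ids)
    tag = df[df["species"] == "TAG"].iloc[0]
    sql = df[df["species"] == "SQL"].iloc[0]
    assert tag["median_frames"] > sql["median_frames"]
    assert tag["rank"] == 1


def test_single_species_ranking():
    system, traj, gt = _kinetic_traj(n_frames=60)
    df = compare_species_binding(traj, AnalysisConfig(), ["TAG"],
                                 residues=["S165"])
    assert len(df) == 1
    row = df.iloc[0]
    assert row["n_events"] == 0 or row["rank"] == 1


def test_residue_absent_from_protomer_is_structural_error():
    from droplens.errors import StructuralError
    system, traj = _distance_system([0.5, 0.6])
    with pytest.raises((StructuralError, KeyError)):
        residue_occupancy(traj, AnalysisConfig(analysis_window=1.0),
                          "S999", "LIP")
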