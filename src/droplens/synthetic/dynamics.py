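"""Planted-statistics trajectory generator.

The generator endows a synthetic trajectory with exactly the statistics the
analysis layer measures, without any molecular dynamics:

* **Ring enrichment** — lipid molecules perform a lateral random walk whose
  Metropolis acceptance plants a stationary inside-ring density such that
  the inside fraction equals ``E_s`` times the ring's membrane-area
  fraction (``E_s`` is the enrichment ratio the analysis reports).
* **z-distributions** — every bead's z-coordinate is resampled each frame
  from its chemical group's Gaussian law about the bilayer midplane
  (leaflet-mirrored for phospholipids).
* **Contact kinetics** — designated (labelled residue, lipid) pairs follow a
  two-state Markov chain; bound frames place the lipid below the lower
  residence cutoff, unbound frames above the upper one, so the dual-cutoff
  segmentation of ground truth is unambiguous.
* **Clustering** — a species can be planted with a target largest-cluster
  fraction: that fraction of its molecules is kept chain-linked below the
  cluster cutoff, the rest dispersed beyond it.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from ..config import AnalysisConfig
from ..errors import PlantError
from ..geometry import lateral_distance_to_point
from ..system import SystemLayout
from ..topology import ChemicalGroup, MoleculeCategory
from ..trajectory import Frame, Trajectory

G = ChemicalGroup


@dataclass(frozen=True)
class ZLaw:
    """Gaussian z law (nm) about the bilayer midplane.

    ``mirror`` laws are applied with the molecule's leaflet sign (suitable
    for phospholipid groups present in both leaflets)."""
    mean: float
    sd: float
    mirror: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise PlantError("z-law SD must be positive")


@dataclass(frozen=True)
class ContactKinetics:
    """Per-frame two-state Markov rates for a (residue, species) pair."""
    p_on: float
    p_off: float

    def __post_init__(self) -> None:
        if not (0 < self.p_on <= 1 and 0 < self.p_off <= 1):
            raise PlantError("contact rates must lie in (0, 1]")

    @property
    def mean_dwell_frames(self) -> float:
        return 1.0 / self.p_off


ZKey = Union[str, Tuple[str, str]]  # group, or (species, group)


def default_z_laws() -> Dict[ZKey, ZLaw]:
    """Built-in z laws: interfacial PL groups mirrored into both leaflets,
    acyl tips and neutral-lipid groups near the midplane."""
    laws: Dict[ZKey, ZLaw] = {
        G.PL_HEADGROUP.value: ZLaw(2.1, 0.10, mirror=True),
        G.PL_PHOSPHATE.value: ZLaw(1.9, 0.10, mirror=True),
        G.PL_GLYCEROL_ESTER.value: ZLaw(1.5, 0.12, mirror=True),
        G.ACYL_CHAIN.value: ZLaw(0.8, 0.25, mirror=True),
        G.ACYL_TIP.value: ZLaw(0.0, 0.15),
        G.CARBOXYL_FREE.value: ZLaw(1.7, 0.15, mirror=True),
    }
    for species in ("TAG", "SE", "RE", "SQL"):
        for group in (G.GLYCEROL_BACKBONE, G.CARBOXYL_ESTER, G.ACYL_CHAIN,
                      G.STEROL_BODY, G.ISOPRENE):
            laws[(species, group.value)] = ZLaw(0.0, 0.40)
    return laws


@dataclass
class PlantedStatistics:
    """Ground-truth parameters the generator embeds.

    ``enrichment`` maps species to the planted enrichment ratio E_s
    (inside-ring fraction = E_s x ring area fraction; E_s = 1 is the uniform
    null, E_s < 1 depletion).  ``contact_kinetics`` maps
    (residue label, species) to per-frame on/off rates.  ``cluster_fractions``
    maps species to the planted largest-cluster fraction of its molecules.
    """

    enrichment: Dict[str, float] = field(default_factory=dict)
    contact_kinetics: Dict[Tuple[str, str], ContactKinetics] = \
        field(default_factory=dict)
    z_laws: Dict[ZKey, ZLaw] = field(default_factory=default_z_laws)
    cluster_fractions: Dict[str, float] = field(default_factory=dict)
    frame_interval_ps: float = 1000.0
    #: lateral random-walk step SD (nm) per substep
    step_sigma: float = 0.5
    #: Metropolis substeps between saved frames (emulates sparse frame saving)
    n_substeps: int = 25

    def __post_init__(self) -> None:
        for s, e in self.enrichment.items():
            if e < 0:
                raise PlantError(f"enrichment E_{s} must be >= 0")
        for s, f in self.cluster_fractions.items():
            if not 0 < f <= 1:
                raise PlantError(f"cluster fraction for {s} must be in (0,1]")
        if self.frame_interval_ps <= 0:
            raise PlantError("frame interval must be positive")

    def z_law_for(self, species: str, group: Optional[str]) -> ZLaw:
        if group is None:
            return ZLaw(0.0, 0.3)
        return (self.z_laws.get((species, group))
                or self.z_laws.get(group)
                or ZLaw(0.0, 0.3))


@dataclass
class TrajectoryGroundTruth:
    """What the generator planted, molecule by molecule and frame by frame."""

    #: one row per lipid molecule: mol_id, species, mode (walk/kinetic/cluster)
    lipids: pd.DataFrame
    #: (n_lipid_molecules, n_frames) inside-ring flags, row order = lipids rows
    inside_ring: np.ndarray
    #: one row per kinetic pair: residue, protomer, mol_id, species, p_on, p_off
    contact_pairs: pd.DataFrame
    #: (n_pairs, n_frames) bound-state flags
    contact_states: np.ndarray
    #: (n_pairs, n_frames) planted anchor distances (nm)
    contact_distances: np.ndarray
    seed: int = 0

    def inside_fraction(self, species: str) -> float:
        rows = self.lipids["species"] == species
        return float(self.inside_ring[rows.to_numpy()].mean())

    def to_csv(self, prefix) -> None:
        self.lipids.to_csv(f"{prefix}_lipids.csv", index=False)
        self.contact_pairs.to_csv(f"{prefix}_contact_pairs.csv", index=False)
        pd.DataFrame(self.contact_states.astype(int)).to_csv(
            f"{prefix}_contact_states.csv", index=False)
        pd.DataFrame(self.inside_ring.astype(int)).to_csv(
            f"{prefix}_inside_ring.csv", index=False)


def _stationary_weight(E: float, area_frac: float) -> float:
    """Inside/outside density ratio that yields inside fraction E * a."""
    if E * area_frac >= 0.98:
        raise PlantError(
            f"planted enrichment E={E} exceeds ring capacity at area "
            f"fraction {area_frac:.3f} (E*a must stay below 1)")
    if E == 0.0:
        return 0.0
    return E * (1.0 - area_frac) / (1.0 - E * area_frac)


def simulate_planted_trajectory(system: SystemLayout,
                                frame0: Frame,
                                plant: PlantedStatistics,
                                n_frames: int,
                                seed: int = 0,
                                cfg: Optional[AnalysisConfig] = None,
                                ) -> Tuple[Trajectory, TrajectoryGroundTruth]:
    """Generate a trajectory whose statistics match the plant.

    ``frame0`` supplies the box and the (static) protein coordinates; lipid
    positions are (re)initialised from the planted stationary law, so no
    burn-in is needed.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    box = frame0.box.copy()
    r_ring = cfg.ring_radius
    area_frac = np.pi * r_ring ** 2 / (box[0] * box[1])

    for sp in plant.enrichment:
        if not system.molecules_of(sp):
            raise PlantError(f"planted species {sp!r} absent from the system")
    for (_lab, sp) in plant.contact_kinetics:
        if not system.molecules_of(sp):
            raise PlantError(f"kinetics species {sp!r} absent from the system")

    # --- static protein -----------------------------------------------------
    if system.protein is not None:
        prot_idx = system.protein.all_bead_indices()
        prot_xyz = frame0.coordinates[prot_idx]
        ring_center = np.array([
            prot_xyz[:, 0].mean(), prot_xyz[:, 1].mean()])
    else:
        prot_idx = np.array([], dtype=int)
        prot_xyz = np.empty((0, 3))
        ring_center = box[:2] / 2.0

    lipid_species = system.lipid_species()
    lipid_mols = [m for m in system.molecules if m.species in lipid_species]
    n_mols = len(lipid_mols)
    mol_index = {m.mol_id: k for k, m in enumerate(lipid_mols)}

    # --- assign modes -------------------------------------------------------
    mode = np.array(["walk"] * n_mols, dtype=object)
    kin_pairs: List[dict] = []
    if plant.contact_kinetics and system.protein is None:
        raise PlantError("contact kinetics require a protein")
    for (label, sp), kin in sorted(plant.contact_kinetics.items()):
        per_protomer = system.protein.residue_beads(label)
        candidates = [m for m in system.molecules_of(sp)
                      if mode[mol_index[m.mol_id]] == "walk"]
        if not candidates:
            raise PlantError(
                f"no free {sp} molecules left for kinetics at {label}")
        for p, res_beads in enumerate(per_protomer):
            if not candidates:
                break
            mol = candidates.pop(0)
            mode[mol_index[mol.mol_id]] = "kinetic"
            # anchor on the residue bead farthest from the ring centre, and
            # place the lipid radially outward: the anchor is then the
            # nearest residue bead, so the planted distance IS the
            # residue-lipid minimum distance
            res_xyz = frame0.coordinates[res_beads]
            radial_d = np.linalg.norm(res_xyz[:, :2] - ring_center, axis=1)
            anchor = res_xyz[int(np.argmax(radial_d))].copy()
            kin_pairs.append(dict(residue=label, protomer=p,
                                  mol_id=mol.mol_id, species=sp,
                                  kin=kin, anchor=anchor, mol=mol))

    cluster_members: Dict[str, np.ndarray] = {}
    for sp, frac in sorted(plant.cluster_fractions.items()):
        mols = [m for m in system.molecules_of(sp)
                if mode[mol_index[m.mol_id]] == "walk"]
        if not mols:
            raise PlantError(f"no free {sp} molecules for cluster plant")
        k = max(1, int(round(frac * len(mols))))
        for m in mols[:k]:
            mode[mol_index[m.mol_id]] = "cluster"
        for m in mols[k:]:
            mode[mol_index[m.mol_id]] = "dispersed"
        cluster_members[sp] = np.array([mol_index[m.mol_id]
                                        for m in mols[:k]])

    # --- per-molecule constants --------------------------------------------
    w_in = np.ones(n_mols)
    for k, m in enumerate(lipid_mols):
        E = plant.enrichment.get(m.species, 1.0)
        w_in[k] = _stationary_weight(E, area_frac)

    # fixed intra-molecule lateral offsets (zero-mean so COG = centre)
    offsets: List[np.ndarray] = []
    z_params: List[np.ndarray] = []  # per bead: mean, sd, mirror flag
    leaflet_sign = np.ones(n_mols)
    toggle = 1
    for k, m in enumerate(lipid_mols):
        topo = system.topologies[m.species]
        scale = 0.001 if mode[k] in ("kinetic", "cluster", "dispersed") \
            else 0.08
        off = rng.normal(0.0, scale, size=(m.n_beads, 2))
        off -= off.mean(axis=0)
        offsets.append(off)
        zp = np.empty((m.n_beads, 3))
        for b in topo.beads:
            law = plant.z_law_for(m.species, b.chemical_group.value)
            zp[b.index] = [law.mean, law.sd, 1.0 if law.mirror else 0.0]
        z_params.append(zp)
        if topo.category in (MoleculeCategory.PHOSPHOLIPID,
                             MoleculeCategory.FREE_FATTY_ACID):
            leaflet_sign[k] = toggle
            toggle = -toggle

    # --- initial lateral centres from the stationary law --------------------
    centers = np.empty((n_mols, 2))
    walk_mask = mode == "walk"
    for k in range(n_mols):
        if not walk_mask[k]:
            centers[k] = rng.uniform([0, 0], box[:2])
            continue
        E = plant.enrichment.get(lipid_mols[k].species, 1.0)
        if rng.random() < E * area_frac:
            rr = r_ring * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            centers[k] = (ring_center + rr * np.array(
                [np.cos(th), np.sin(th)])) % box[:2]
        else:
            while True:
                xy = rng.uniform([0, 0], box[:2])
                if lateral_distance_to_point(
                        np.array([[xy[0], xy[1], 0.0]]),
                        np.array([ring_center[0], ring_center[1], 0.0]),
                        box)[0] >= r_ring:
                    centers[k] = xy
                    break

    # --- kinetic pair state -------------------------------------------------
    n_pairs = len(kin_pairs)
    states = np.zeros((n_pairs, n_frames), dtype=bool)
    distances = np.zeros((n_pairs, n_frames))
    cur_state = np.zeros(n_pairs, dtype=bool)
    for j, pair in enumerate(kin_pairs):
        kin = pair["kin"]
        cur_state[j] = rng.random() < kin.p_on / (kin.p_on + kin.p_off)

    lo, up = cfg.residence_lower, cfg.residence_upper
    blob_centers = {sp: rng.uniform([0, 0], box[:2])
                    for sp in cluster_members}

    n_beads = system.n_beads
    coords = np.empty((n_frames, n_beads, 3))
    times = np.arange(n_frames) * plant.frame_interval_ps
    inside = np.zeros((n_mols, n_frames), dtype=bool)

    walk_idx = np.flatnonzero(walk_mask)
    w_walk = w_in[walk_idx]
    ring_c3 = np.array([ring_center[0], ring_center[1], 0.0])

    def in_ring(xy: np.ndarray) -> np.ndarray:
        pts = np.column_stack([xy, np.zeros(len(xy))])
        return lateral_distance_to_point(pts, ring_c3, box) < r_ring

    # flattened per-bead arrays over all lipid molecules (fast assembly)
    lip_beads = np.concatenate([np.arange(m.start, m.stop)
                                for m in lipid_mols])
    bead_mol = np.concatenate([np.full(m.n_beads, k)
                               for k, m in enumerate(lipid_mols)])
    off_xy = np.vstack(offsets)
    z_mid = box[2] / 2.0
    z_mean = np.empty(len(lip_beads))
    z_sd = np.empty(len(lip_beads))
    kin_anchor_z = {mol_index[p["mol_id"]]: p["anchor"][2]
                    for p in kin_pairs}
    pos = 0
    for k, m in enumerate(lipid_mols):
        nb = m.n_beads
        if k in kin_anchor_z:
            z_mean[pos:pos + nb] = kin_anchor_z[k]
            z_sd[pos:pos + nb] = 0.001
        elif mode[k] in ("cluster", "dispersed"):
            z_mean[pos:pos + nb] = z_mid
            z_sd[pos:pos + nb] = 0.05
        else:
            zp = z_params[k]
            z_mean[pos:pos + nb] = z_mid + np.where(
                zp[:, 2] > 0, zp[:, 0] * leaflet_sign[k], zp[:, 0])
            z_sd[pos:pos + nb] = zp[:, 1]
        pos += nb

    for f in range(n_frames):
        # Metropolis walk with substeps (RNG draws batched per frame)
        if walk_idx.size:
            cur = centers[walk_idx]
            cur_in = in_ring(cur)
            steps = rng.normal(0.0, plant.step_sigma,
                               size=(plant.n_substeps,) + cur.shape)
            us = rng.random((plant.n_substeps, len(cur)))
            for s in range(plant.n_substeps):
                prop = (cur + steps[s]) % box[:2]
                prop_in = in_ring(prop)
                w_cur = np.where(cur_in, w_walk, 1.0)
                w_prop = np.where(prop_in, w_walk, 1.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(w_cur > 0, w_prop / w_cur,
                                     np.where(w_prop > 0, np.inf, 1.0))
                accept = us[s] < np.minimum(ratio, 1.0)
                cur[accept] = prop[accept]
                cur_in[accept] = prop_in[accept]
            centers[walk_idx] = cur

        # kinetic pairs: Markov update + placement
        for j, pair in enumerate(kin_pairs):
            kin = pair["kin"]
            if cur_state[j]:
                if rng.random() < kin.p_off:
                    cur_state[j] = False
            else:
                if rng.random() < kin.p_on:
                    cur_state[j] = True
            states[j, f] = cur_state[j]
            anchor = pair["anchor"]
            u = anchor[:2] - ring_c3[:2]
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-9 else np.array([1.0, 0.0])
            if cur_state[j]:
                d = rng.uniform(0.70 * lo, 0.99 * lo)
            else:
                d = rng.uniform(1.02 * up, 2.0 * up)
            distances[j, f] = d
            k = mol_index[pair["mol_id"]]
            centers[k] = (anchor[:2] + u * d) % box[:2]

        # cluster plants: chain-linked members, dispersed singletons
        for sp, members in cluster_members.items():
            c = (blob_centers[sp]
                 + rng.normal(0.0, plant.step_sigma, size=2)) % box[:2]
            blob_centers[sp] = c
            prev = c
            placed: List[np.ndarray] = []
            for k in members:
                th = rng.uniform(0, 2 * np.pi)
                step = rng.uniform(0.5 * cfg.cluster_cutoff,
                                   0.75 * cfg.cluster_cutoff)
                pos = (prev + step * np.array([np.cos(th), np.sin(th)])) \
                    % box[:2]
                centers[k] = pos
                placed.append(pos)
                prev = pos
            # dispersed molecules: rejection sampling away from everything
            disp = [k for k, m in enumerate(lipid_mols)
                    if mode[k] == "dispersed" and m.species == sp]
            sep = 1.5 * cfg.cluster_cutoff
            anchors = placed.copy()
            for k in disp:
                for _try in range(400):
                    xy = rng.uniform([0, 0], box[:2])
                    pts = np.column_stack([np.array(anchors),
                                           np.zeros(len(anchors))]) \
                        if anchors else np.empty((0, 3))
                    if len(pts) == 0 or lateral_distance_to_point(
                            pts, np.array([xy[0], xy[1], 0.0]), box
                            ).min() >= sep:
                        break
                else:
                    raise PlantError(
                        f"cannot disperse {sp} molecules at separation "
                        f"{sep} nm; box too crowded")
                centers[k] = xy
                anchors.append(xy)

        # assemble bead coordinates (vectorised over all lipid beads)
        frame_xyz = coords[f]
        if prot_idx.size:
            frame_xyz[prot_idx] = prot_xyz
        xy = (centers[bead_mol] + off_xy) % box[:2]
        frame_xyz[lip_beads, 0] = xy[:, 0]
        frame_xyz[lip_beads, 1] = xy[:, 1]
        frame_xyz[lip_beads, 2] = np.clip(
            rng.normal(z_mean, z_sd), 0.0, box[2])
        inside[:, f] = in_ring(centers)

    traj = Trajectory(system, coords, times, np.tile(box, (n_frames, 1)))
    lipids_df = pd.DataFrame({
        "mol_id": [m.mol_id for m in lipid_mols],
        "species": [m.species for m in lipid_mols],
        "mode": list(mode),
    })
    pairs_df = pd.DataFrame({
        "residue": [p["residue"] for p in kin_pairs],
        "protomer": [p["protomer"] for p in kin_pairs],
        "mol_id": [p["mol_id"] for p in kin_pairs],
        "species": [p["species"] for p in kin_pairs],
        "p_on": [p["kin"].p_on for p in kin_pairs],
        "p_off": [p["kin"].p_off for p in kin_pairs],
    })
    gt = TrajectoryGroundTruth(lipids_df, inside, pairs_df, states,
                               distances, seed=seed)
    return traj, gt
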