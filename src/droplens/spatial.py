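"""Spatial statistics: z-density profiles and neutral-lipid clustering.

z-density profiles are histogrammed along the bilayer normal relative to the
phospholipid midplane, registered so the PL acyl-chain-tip peak defines
z = 0, and normalised to unit maximum.  Clustering is single-linkage under a
minimum-image distance cutoff (molecule-level: beads of one molecule are
pre-merged), the same statistic classic cluster-size tools compute, with a
five-parameter logistic describing its concentration dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .errors import FitError, RegistrationError
from .geometry import circular_mean_axis
from .trajectory import Frame, Trajectory


# ---------------------------------------------------------------------------
# union-find

class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=int)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]

    def labels(self) -> np.ndarray:
        return np.array([self.find(i) for i in range(len(self.parent))])


# ---------------------------------------------------------------------------
# clustering

def cluster_sizes(frame: Frame, cfg: AnalysisConfig,
                  selection: np.ndarray,
                  mol_ids: Optional[np.ndarray] = None,
                  by: str = "molecules") -> List[int]:
    """Single-linkage cluster sizes of selected beads under the cutoff.

    Two beads are linked when their minimum-image distance is below the
    cluster cutoff; with ``by="molecules"`` beads of one molecule are
    pre-merged and sizes are counted in molecules.  Sizes partition the
    selection.  Periodic neighbour search uses a kd-tree on the wrapped
    coordinates.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    pts = frame.coordinates[sel] % frame.box
    # cKDTree with boxsize requires points strictly inside [0, box)
    pts = np.where(pts >= frame.box, 0.0, pts)
    tree = cKDTree(pts, boxsize=frame.box)
    pairs = tree.query_pairs(cfg.cluster_cutoff, output_type="ndarray")

    uf = UnionFind(sel.size)
    for i, j in pairs:
        uf.union(int(i), int(j))
    if by == "molecules":
        if mol_ids is None:
            raise ValueError("molecule-level clustering needs mol_ids")
        mids = np.asarray(mol_ids)
        first_of: Dict[int, int] = {}
        for k, mid in enumerate(mids):
            if mid in first_of:
                uf.union(first_of[mid], k)
            else:
                first_of[mid] = k
        labels = uf.labels()
        sizes = [len(set(mids[labels == lab]))
                 for lab in np.unique(labels)]
    elif by == "beads":
        labels = uf.labels()
        sizes = list(np.unique(labels, return_counts=True)[1])
    else:
        raise ValueError(f"unknown clustering unit {by!r}")
    return sorted((int(s) for s in sizes), reverse=True)


@dataclass
class ClusterSummary:
    """Per-trajectory clustering statistics of one selection."""

    concentration: float          # NL concentration (% of lipids)
    per_frame_sizes: List[List[int]]
    largest_fraction: float       # time-averaged largest cluster / n molecules

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, sizes in enumerate(self.per_frame_sizes):
            for cid, s in enumerate(sizes):
                rows.append({"frame": f, "cluster_id": cid, "size": s})
        return pd.DataFrame(rows)


def cluster_summary(traj: Trajectory, cfg: AnalysisConfig,
                    species: Union[str, Sequence[str]],
                    concentration: float = float("nan")) -> ClusterSummary:
    """Time-averaged largest-cluster fraction of NL species over the window."""
    from .system import select
    sel = select(traj.system, species=species)
    mids = traj.system.bead_mol_id[sel]
    n_mols = len(np.unique(mids))
    sub = traj.window(cfg.analysis_window)
    per_frame = []
    largest = []
    for frame in sub:
        sizes = cluster_sizes(frame, cfg, sel, mol_ids=mids)
        per_frame.append(sizes)
        largest.append(sizes[0] / n_mols)
    return ClusterSummary(concentration, per_frame, float(np.mean(largest)))


def five_parameter_logistic(x, a, d, c, b, g):
    """5PL (asymmetric Hill): y = d + (a - d) / (1 + (x/c)^b)^g."""
    return d + (a - d) / (1.0 + (np.asarray(x, dtype=float) / c) ** b) ** g


@dataclass
class ClusterCurveFit:
    concentrations: np.ndarray
    fractions: np.ndarray
    params: Dict[str, float]       # a, d, c, b, g
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def midpoint(self) -> float:
        """Concentration of half response (the c parameter)."""
        return self.params["c"]


def clustering_vs_concentration(
        summaries: Sequence[ClusterSummary]) -> ClusterCurveFit:
    """Fit the largest-cluster fraction vs NL concentration with a 5PL.

    Needs >= 4 concentration points; strictly constant responses are
    rejected (a logistic carries no information there).
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 concentration points")
    x = np.array([s.concentration for s in summaries], dtype=float)
    y = np.array([s.largest_fraction for s in summaries], dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.ptp(y) < 1e-12:
        raise FitError("largest-cluster fraction is constant across "
                       "concentrations; fit a null (constant) model instead")
    a0, d0 = float(y[0]), float(y[-1])
    c0 = float(x[len(x) // 2])
    p0 = [a0, d0, max(c0, 1e-6), 4.0, 1.0]
    bounds = ([-0.5, -0.5, 1e-9, 0.01, 0.01], [1.5, 1.5, 1e6, 100.0, 100.0])
    try:
        popt, _ = curve_fit(five_parameter_logistic, x, y, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"5PL fit did not converge: {exc}") from exc
    fitted = five_parameter_logistic(x, *popt)
    return ClusterCurveFit(x, y, dict(zip("adcbg", popt)), fitted, y - fitted)


# ---------------------------------------------------------------------------
# z-density profiles

@dataclass
class DensityProfile:
    label: str
    bin_centers: np.ndarray       # nm, relative to registered origin
    density: np.ndarray           # normalised, max = 1
    counts: np.ndarray            # mean raw counts per frame per bin
    frames: int

    def peak_z(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"selection": self.label,
                             "z": self.bin_centers,
                             "density_norm": self.density,
                             "counts": self.counts})


def z_density_profile(traj: Trajectory, cfg: AnalysisConfig,
                      selections: Dict[str, np.ndarray],
                      register_to: str = "pl-tips") -> List[DensityProfile]:
    """Frame-averaged z histograms of bead selections, bilayer-registered.

    Per frame, z is taken relative to the bilayer midplane (PBC-aware mean z
    of all phospholipid beads), histogrammed at the configured bin width and
    averaged over the analysis window.  The origin is then shifted so the
    registration selection's peak (by default the PL acyl-chain tips) sits
    at z = 0, and each profile is scaled to unit maximum.
    """
    from .system import select
    if not selections:
        raise ValueError("no selections given")
    for label, sel in selections.items():
        if np.asarray(sel).size == 0:
            raise ValueError(f"selection {label!r} is empty")
    sels = dict(selections)
    if register_to not in sels:
        sels[register_to] = select(traj.system, category="phospholipid",
                                   chemical_group="acyl-tip")
        if sels[register_to].size == 0:
            raise RegistrationError(
                "no PL acyl-chain-tip beads available for registration")
    pl_beads = select(traj.system, category="phospholipid")
    if pl_beads.size == 0:
        raise RegistrationError("no phospholipid beads to define the midplane")

    sub = traj.window(cfg.analysis_window)
    half_span = sub.boxes[:, 2].max() / 2.0 + cfg.z_bin
    edges = np.arange(-half_span, half_span + cfg.z_bin, cfg.z_bin)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sums = {label: np.zeros(len(centers)) for label in sels}
    for f, frame in enumerate(sub):
        lz = frame.box[2]
        mid = circular_mean_axis(frame.coordinates[pl_beads, 2], lz)
        for label, sel in sels.items():
            z = frame.coordinates[np.asarray(sel, dtype=int), 2]
            # minimum-image displacement from the midplane
            rel = (z - mid + lz / 2.0) % lz - lz / 2.0
            hist, _ = np.histogram(rel, bins=edges)
            sums[label] += hist

    counts = {label: s / len(sub) for label, s in sums.items()}
    ref = counts[register_to]
    peak = ref.max()
    if peak <= 0:
        raise RegistrationError("registration profile is empty")
    maxima = np.flatnonzero(ref == peak)
    if len(maxima) > 1 and np.ptp(centers[maxima]) > cfg.z_bin * 1.5:
        raise RegistrationError(
            f"registration peak is not unique; tie positions at "
            f"{centers[maxima].tolist()} nm")
    origin = centers[maxima[0]]

    out = []
    for label in selections:
        c = counts[label]
        m = c.max()
        if m <= 0:
            raise ValueError(f"selection {label!r} produced no counts")
        out.append(DensityProfile(label, centers - origin, c / m, c,
                                  len(sub)))
    return out
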