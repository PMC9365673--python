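"""Periodic-boundary geometry for orthorhombic boxes.

All cutoff-based analyses reduce to minimum-image distances; centres of
geometry are computed either naively or PBC-aware via per-axis circular
means, so a bead cluster straddling the boundary yields its physical centre.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .trajectory import Frame


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum image convention."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(frame: Frame, i: int, j: int) -> float:
    """Minimum distance between beads i and j over all periodic images."""
    d = minimum_image_displacement(
        frame.coordinates[j] - frame.coordinates[i], frame.box)
    return float(np.linalg.norm(d))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray,
                                 box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances between point sets."""
    delta = a[:, None, :] - b[None, :, :]
    delta = minimum_image_displacement(delta, box)
    return np.sqrt((delta ** 2).sum(axis=-1))


def min_set_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum over all pairs of minimum-image distances (set-to-set)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("bead sets must be nonempty")
    return float(pairwise_min_image_distances(a, b, box).min())


def circular_mean_axis(x: np.ndarray, length: float) -> float:
    """PBC-aware mean of positions on one periodic axis of given length.

    Maps positions to angles on a circle, averages the unit vectors and maps
    the mean angle back; result lies in [0, length).
    """
    theta = 2.0 * np.pi * np.asarray(x, dtype=float) / length
    s, c = np.sin(theta).mean(), np.cos(theta).mean()
    if s == 0.0 and c == 0.0:
        # perfectly balanced ring: fall back to the naive mean
        return float(np.mean(x) % length)
    ang = np.arctan2(s, c)
    return float((ang / (2.0 * np.pi) * length) % length)


def center_of_geometry(frame: Frame, indices: Iterable[int],
                       pbc_aware: bool = True) -> np.ndarray:
    """Unweighted mean position of a bead set (nm).

    With ``pbc_aware`` the mean is taken per axis on the periodic circle, so
    a compact cluster wrapped across the boundary is centred correctly.
    """
    idx = np.asarray(list(indices) if not isinstance(indices, np.ndarray)
                     else indices, dtype=int)
    if idx.size == 0:
        raise ValueError("center_of_geometry of an empty bead set")
    pts = frame.coordinates[idx]
    if not pbc_aware:
        return pts.mean(axis=0)
    return np.array([circular_mean_axis(pts[:, ax], frame.box[ax])
                     for ax in range(3)])


def lateral_distance_to_point(points: np.ndarray, center: np.ndarray,
                              box: np.ndarray) -> np.ndarray:
    """xy minimum-image distances of points (N, 3) to one centre."""
    delta = points[:, :2] - np.asarray(center)[:2]
    delta = minimum_image_displacement(delta, np.asarray(box)[:2])
    return np.sqrt((delta ** 2).sum(axis=-1))


def unwrap_molecule(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make one molecule's beads minimum-image consistent with its first bead."""
    ref = coords[0]
    return ref + minimum_image_displacement(coords - ref, box)
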