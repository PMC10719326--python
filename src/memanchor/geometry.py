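"""Periodic-boundary geometry for orthorhombic cells.

All functions take box edge lengths as a length-3 array (nm) and apply
the minimum-image convention independently per axis, which is exact for
rectangular cells.
"""

from __future__ import annotations

import numpy as np

from .core import Frame, Topology


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape[-1] != 3:
        raise ValueError("box must have three edge lengths")
    if not np.all(box > 0):
        raise ValueError(f"box lengths must be positive, got {box}")
    return box


def min_image_displacement(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) q - p.

    Broadcasts over leading dimensions of ``p`` and ``q``.
    """
    box = _check_box(box)
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points under PBC."""
    d = min_image_displacement(p, q, box)
    return np.linalg.norm(d, axis=-1)


def pairwise_min_image_distances(
    pa: np.ndarray, pb: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """All cross distances between two point sets; shape (len(pa), len(pb))."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    d = min_image_displacement(pa[:, None, :], pb[None, :, :], box)
    return np.linalg.norm(d, axis=-1)


def min_distance_to_selection(
    frame: Frame, group_a: np.ndarray, group_b: np.ndarray
) -> float:
    """Shortest atom-pair distance between two atom index groups.

    This is the molecule-to-surface distance used by the residence-time
    metric: the minimum over every (a, b) cross pair of the
    minimum-image distance.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0:
        raise ValueError("group_a is empty")
    if group_b.size == 0:
        raise ValueError("group_b is empty")
    d = pairwise_min_image_distances(
        frame.positions[group_a], frame.positions[group_b], frame.box
    )
    return float(d.min())


def assign_midplane(
    frame: Frame, topology: Topology, lipid_indices: np.ndarray | None = None
) -> float:
    """Mass-weighted mean z of the lipid atoms: the bilayer mid-plane.

    All reported z locations are measured relative to this plane.  The
    upper leaflet lies at z greater than the returned value by
    convention.
    """
    if lipid_indices is None:
        lipid_indices = topology.lipid_indices()
    lipid_indices = np.asarray(lipid_indices, dtype=int)
    if lipid_indices.size == 0:
        raise ValueError("lipid selection is empty; cannot locate the mid-plane")
    m = topology.masses[lipid_indices]
    z = frame.positions[lipid_indices, 2]
    return float(np.average(z, weights=m))
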