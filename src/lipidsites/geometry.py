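"""Periodic distance primitives (orthorhombic minimum image) and
KD-tree contact queries.

Coordinates may use any origin convention: wrapping with ``np.mod`` before
building a periodic tree leaves minimum-image distances unchanged.
Triclinic boxes are rejected at the I/O layer; everything here assumes
box = (lx, ly, lz).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "min_image_vec",
    "pairwise_distances",
    "min_pair_distance",
    "contact_pairs",
    "beads_within_cutoff",
    "group_min_distances",
]


def min_image_vec(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box (broadcasts)."""
    vec = np.asarray(vec, dtype=float)
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def pairwise_distances(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(xa), len(xb))."""
    diff = np.asarray(xa, float)[:, None, :] - np.asarray(xb, float)[None, :, :]
    diff = min_image_vec(diff, box)
    return np.sqrt((diff * diff).sum(axis=-1))


def min_pair_distance(xa: np.ndarray, xb: np.ndarray, box: np.ndarray) -> float:
    """Minimum over all bead pairs of the periodic distance."""
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty bead selection")
    return float(pairwise_distances(xa, xb, box).min())


def _wrapped_tree(coords: np.ndarray, box: np.ndarray) -> cKDTree:
    return cKDTree(np.mod(coords, box), boxsize=box)


def contact_pairs(
    coords: np.ndarray,
    box: np.ndarray,
    ids_a: np.ndarray,
    ids_b: np.ndarray,
    cutoff: float,
) -> set[tuple[int, int]]:
    """Bead-index pairs (a, b) with periodic distance < cutoff.

    Uses a periodic KD tree on each side; the brute-force equivalent is the
    all-pairs scan over :func:`pairwise_distances` (used as the oracle in
    the test suite).
    """
    ids_a = np.asarray(ids_a, dtype=np.intp)
    ids_b = np.asarray(ids_b, dtype=np.intp)
    box = np.asarray(box, dtype=float)
    ta = _wrapped_tree(coords[ids_a], box)
    tb = _wrapped_tree(coords[ids_b], box)
    out: set[tuple[int, int]] = set()
    for ia, nbrs in enumerate(ta.query_ball_tree(tb, cutoff)):
        for ib in nbrs:
            # KD tree includes the boundary; the contact rule is strict "<"
            d = np.sqrt(
                (min_image_vec(coords[ids_a[ia]] - coords[ids_b[ib]], box) ** 2).sum()
            )
            if d < cutoff:
                out.add((int(ids_a[ia]), int(ids_b[ib])))
    return out


def beads_within_cutoff(
    coords: np.ndarray,
    box: np.ndarray,
    query_ids: np.ndarray,
    target_ids: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """Indices into ``target_ids`` whose bead lies strictly within ``cutoff``
    of any bead in ``query_ids`` (single frame, periodic)."""
    query_ids = np.asarray(query_ids, dtype=np.intp)
    target_ids = np.asarray(target_ids, dtype=np.intp)
    box = np.asarray(box, dtype=float)
    tree = _wrapped_tree(coords[target_ids], box)
    hits: set[int] = set()
    wrapped_q = np.mod(coords[query_ids], box)
    for nbrs in tree.query_ball_point(wrapped_q, cutoff):
        hits.update(nbrs)
    if not hits:
        return np.empty(0, dtype=np.intp)
    idx = np.fromiter(hits, dtype=np.intp)
    d = np.sqrt(
        (
            min_image_vec(
                coords[target_ids[idx]][:, None, :] - coords[query_ids][None, :, :],
                box,
            )
            ** 2
        ).sum(-1)
    ).min(axis=1)
    return np.sort(idx[d < cutoff])


def group_min_distances(
    coords: np.ndarray,
    box: np.ndarray,
    groups_a: Sequence[np.ndarray],
    groups_b: Sequence[np.ndarray],
) -> np.ndarray:
    """Minimum periodic distance between bead groups, over many frames.

    ``coords`` is (F, B, 3); each group is an array of bead indices (a
    residue's beads, a lipid's headgroup beads, ...). Returns (F, nA, nB).
    Frames are processed in chunks so the bead-pair tensor stays small.
    """
    coords = np.asarray(coords, float)
    F = coords.shape[0]
    flat_a = np.concatenate([np.asarray(g, dtype=np.intp) for g in groups_a])
    flat_b = np.concatenate([np.asarray(g, dtype=np.intp) for g in groups_b])
    bounds_a = np.cumsum([0] + [len(g) for g in groups_a])[:-1]
    bounds_b = np.cumsum([0] + [len(g) for g in groups_b])[:-1]
    box = np.asarray(box, float)
    if box.ndim == 1:
        box = np.broadcast_to(box, (F, 3))

    out = np.empty((F, len(groups_a), len(groups_b)), dtype=float)
    # keep the per-chunk pair tensor around ~40 MB
    pair_floats = max(1, len(flat_a) * len(flat_b) * 3)
    chunk = max(1, min(F, int(5e6 / pair_floats)))
    for lo in range(0, F, chunk):
        hi = min(F, lo + chunk)
        diff = (
            coords[lo:hi][:, flat_a, None, :] - coords[lo:hi][:, None, flat_b, :]
        )
        diff -= box[lo:hi, None, None, :] * np.round(diff / box[lo:hi, None, None, :])
        d = np.sqrt((diff * diff).sum(-1))
        d = np.minimum.reduceat(d, bounds_a, axis=1)
        d = np.minimum.reduceat(d, bounds_b, axis=2)
        out[lo:hi] = d
    return out
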