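"""Minimum-image arithmetic for orthorhombic periodic boxes."""
from __future__ import annotations

import numpy as np


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` is (..., 3); ``box`` is (3,) orthorhombic lengths or None, in
    which case displacements are returned unchanged.
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Pairwise minimum-image distance matrix between point sets a (n,3) and b (m,3)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    delta = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(minimum_image(delta, box), axis=-1)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) along each axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)


def make_whole(coords: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Unwrap a molecule split across the boundary.

    Every atom is shifted by the lattice vector that brings it closest to the
    first atom. Valid for compact molecules (extent < half the box), which is
    the regime the contact analyses require.
    """
    coords = np.asarray(coords, dtype=float)
    if box is None or len(coords) == 0:
        return coords
    anchor = coords[0]
    return anchor + minimum_image(coords - anchor, np.asarray(box, dtype=float))
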