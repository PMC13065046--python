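"""Structural observables: Kabsch superposition, RMSD series, radius of
gyration, Shrake-Rupley SASA, and RMSD-matrix frame clustering with medoid
extraction.

All distances in Angstrom. The SASA quadrature uses a deterministic
golden-spiral sphere point set so results are exactly reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .core import DEFAULT_VDW_RADII, ResultTable, Trajectory
from .errors import MemfluxError

_DEGENERACY_TOL = 1e-9


@dataclass
class Superposition:
    """Optimal rigid-body fit of a mobile point set onto a reference.

    The transform maps mobile coordinates as ``x @ rotation.T + translation``.
    ``unique`` is False for degenerate (e.g. collinear) inputs where the
    rotation is not uniquely determined.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_before: float
    rmsd_after: float
    unique: bool = True

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> Superposition:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Reflections are excluded by the usual determinant sign correction, so the
    returned rotation is always proper (det = +1). With fewer than 3
    non-collinear points the optimum is not unique and the result is flagged.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape != reference.shape:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 1:
        raise ValueError("superposition needs at least one atom")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per atom")

    wsum = w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(0) / wsum
    ref_mean = (w[:, None] * reference).sum(0) / wsum
    ref_c = reference - ref_mean

    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T

    # Degenerate when the two smallest singular values vanish (collinear) or
    # fewer than 3 points are given.
    unique = n >= 3 and s[1] > _DEGENERACY_TOL * max(s[0], 1.0)

    mob_mean = (w[:, None] * mobile).sum(0) / wsum
    translation = ref_mean - rotation @ mob_mean
    aligned = mobile @ rotation.T + translation
    return Superposition(
        rotation=rotation,
        translation=translation,
        rmsd_before=_weighted_rmsd(mobile, reference, w),
        rmsd_after=_weighted_rmsd(aligned, reference, w),
        unique=unique,
    )


def pair_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """RMSD between two conformations after optimal superposition."""
    return kabsch_superpose(a, b, weights).rmsd_after


def rmsd_series(traj: Trajectory, selection: np.ndarray, reference_frame: int = 0,
                align_selection: np.ndarray | None = None) -> ResultTable:
    """Per-frame RMSD of ``selection`` after aligning each frame on
    ``align_selection`` (defaults to ``selection``) to the reference frame.

    Aligning on one selection while measuring on another reproduces the usual
    domain-motion readout (e.g. cytoplasmic-domain RMSD after superposing the
    transmembrane helices).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise MemfluxError("empty measurement selection")
    align = selection if align_selection is None else np.asarray(align_selection, dtype=int)
    if align.size == 0:
        raise MemfluxError("empty alignment selection")
    if not (0 <= reference_frame < traj.n_frames):
        raise MemfluxError(f"reference frame {reference_frame} out of range")

    ref_align = traj.coords[reference_frame, align]
    ref_meas = traj.coords[reference_frame, selection]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[f, align], ref_align)
        moved = sup.transform(traj.coords[f, selection])
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))

    df = pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd": values})
    if traj.frame_times is not None:
        df.insert(1, "time_ns", traj.frame_times)
    return ResultTable(df, provenance={"reference_frame": reference_frame,
                                       "n_selected": int(selection.size)})


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, sqrt(sum m |r - rbar|^2 / sum m)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 1:
        raise ValueError("radius of gyration needs at least one atom")
    m = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    if m.shape != (n,) or np.any(m <= 0):
        raise ValueError("masses must be positive, one per atom")
    com = (m[:, None] * coords).sum(0) / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((coords - com) ** 2, axis=1)) / m.sum()))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                       n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's extended sphere (radius + probe) is sampled with a fixed
    golden-spiral point set; a point is accessible if it lies outside every
    other atom's extended sphere. Returns (per-atom areas, total) in A^2.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    n = coords.shape[0]
    if radii.shape != (n,) or np.any(radii <= 0):
        raise ValueError("radii must be positive, one per atom")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")

    sphere = golden_spiral_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                      if j != i]
        if neighbours:
            nb = np.array(neighbours, dtype=int)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (ext[nb] ** 2)[None, :] - 1e-12, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas, float(areas.sum())


def sasa_series(traj: Trajectory, selection: np.ndarray, probe: float = 1.4,
                n_points: int = 960,
                radii_table: dict[str, float] | None = None) -> ResultTable:
    """Total SASA of a selection for every frame."""
    table = dict(DEFAULT_VDW_RADII if radii_table is None else radii_table)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise MemfluxError("empty selection")
    radii = np.array([table.get(traj.atoms[i].element, 1.7) for i in selection])
    totals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, totals[f] = sasa_shrake_rupley(traj.coords[f, selection], radii,
                                          probe=probe, n_points=n_points)
    df = pd.DataFrame({"frame": np.arange(traj.n_frames), "sasa_A2": totals})
    return ResultTable(df, provenance={"probe": probe, "n_points": n_points})


# ---------------------------------------------------------------------------
# RMSD-matrix clustering


@dataclass
class ClusterResult:
    """Frame clustering with the representative medoid of the largest cluster.

    ``labels`` are 0-based cluster ids per frame; ``medoid_frame`` is the frame
    of the most populated cluster minimizing summed RMSD to its co-members
    (ties broken by lowest frame index everywhere).
    """

    labels: np.ndarray
    medoid_frame: int
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    rmsd_matrix: np.ndarray | None = None


def pairwise_rmsd_matrix(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch-aligned RMSDs over frames."""
    selection = np.asarray(selection, dtype=int)
    n = traj.n_frames
    mat = np.zeros((n, n))
    confs = traj.coords[:, selection]
    for i in range(n):
        for j in range(i + 1, n):
            r = pair_rmsd(confs[i], confs[j])
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_frames(traj: Trajectory, selection: np.ndarray, k: int | None = None,
                   cutoff: float | None = None) -> ClusterResult:
    """Average-linkage hierarchical clustering on the pairwise-aligned RMSD
    matrix, cut to ``k`` clusters or at RMSD threshold ``cutoff``.

    Deterministic: cluster ids are renumbered by first-occurring frame, and the
    medoid tie-break is the lowest frame index.
    """
    if traj.n_frames < 2:
        raise MemfluxError("clustering needs at least 2 frames")
    if (k is None) == (cutoff is None):
        raise MemfluxError("specify exactly one of k or cutoff")
    if k is not None and not (1 <= k <= traj.n_frames):
        raise MemfluxError(f"k={k} outside [1, n_frames={traj.n_frames}]")

    mat = pairwise_rmsd_matrix(traj, selection)
    z = linkage(squareform(mat, checks=False), method="average")
    if k is not None:
        raw = fcluster(z, t=k, criterion="maxclust")
    else:
        raw = fcluster(z, t=cutoff, criterion="distance")

    # Renumber by first occurrence for determinism.
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for f, lab in enumerate(raw):
        labels[f] = remap.setdefault(int(lab), len(remap))

    sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    best_size = max(sizes.values())
    # Most populated cluster; ties -> the one containing the lowest frame.
    top = min(c for c, s in sizes.items() if s == best_size)
    members = np.nonzero(labels == top)[0]
    sums = mat[np.ix_(members, members)].sum(axis=1)
    medoid = int(members[int(np.argmin(sums))])  # argmin keeps lowest index on ties
    return ClusterResult(labels=labels, medoid_frame=medoid,
                         cluster_sizes=sizes, rmsd_matrix=mat)
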