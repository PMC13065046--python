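"""Water permeation through a membrane-embedded protein volume.

A water oxygen is "inside" the protein volume at a frame iff its z lies in the
closed slab interval [z_lower, z_upper] AND its minimum distance to any protein
heavy atom is <= the proximity cutoff (minimum-image when a box is present).
Entry/exit sides are read off the z coordinate at the last/first outside frame;
waters that leave laterally within the slab are attributed to the nearest slab
boundary and flagged. The translocation success rate is the fraction of
resolved events that exit on the side opposite their entry:

    rate = n_crossed / (n_crossed + n_returned)

Waters still inside at the last frame are "unresolved" and excluded from the
denominator, but reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import trim_mean

from .core import ResultTable, Trajectory
from .errors import MemfluxError
from .pbc import wrap

LOWER = "lower"
UPPER = "upper"


@dataclass(frozen=True)
class MembraneSlab:
    """z-interval of the hydrophobic bilayer core; separates the two sides."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise MemfluxError("slab needs z_lower < z_upper")

    def side_of(self, z: float) -> str | None:
        """'lower'/'upper' outside the slab, None inside it (closed interval)."""
        if z < self.z_lower:
            return LOWER
        if z > self.z_upper:
            return UPPER
        return None

    def nearest_side(self, z: float) -> str:
        return LOWER if (z - self.z_lower) <= (self.z_upper - z) else UPPER


@dataclass(frozen=True)
class ProteinVolume:
    """Slab-bounded proximity shell around the protein heavy atoms."""

    protein_selection: np.ndarray
    slab: MembraneSlab
    proximity_cutoff: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_selection",
                           np.asarray(self.protein_selection, dtype=int))
        if self.proximity_cutoff <= 0:
            raise MemfluxError("proximity cutoff must be positive")
        if self.protein_selection.size == 0:
            raise MemfluxError("protein selection is empty")


@dataclass
class PermeationEvent:
    """One continuous stay of a water inside the protein volume."""

    water_index: int
    entry_frame: int
    entry_side: str
    exit_frame: int | None
    exit_side: str | None
    outcome: str  # crossed | returned | unresolved
    entry_lateral: bool = False
    exit_lateral: bool = False
    replica: str | None = None


@dataclass
class RateSummary:
    n_crossed: int
    n_returned: int
    n_unresolved: int
    rate: float | None
    per_replica: dict[str, float] | None = None
    per_replica_mean: float | None = None

    @property
    def n_entries(self) -> int:
        return self.n_crossed + self.n_returned + self.n_unresolved

    @property
    def rate_percent(self) -> float | None:
        return None if self.rate is None else 100.0 * self.rate


def estimate_slab(traj: Trajectory, marker_selection: np.ndarray,
                  quantile_trim: float = 0.0) -> MembraneSlab:
    """Estimate slab bounds from leaflet marker atoms (e.g. lipid phosphorus).

    Markers are split by their joint mean z in each frame; each leaflet bound is
    the (optionally trimmed) mean z of its group, averaged over frames.
    """
    marker_selection = np.asarray(marker_selection, dtype=int)
    if marker_selection.size == 0:
        raise MemfluxError("marker selection is empty")
    lowers, uppers = [], []
    for f in range(traj.n_frames):
        z = traj.coords[f, marker_selection, 2]
        mid = z.mean()
        lower, upper = z[z < mid], z[z >= mid]
        if lower.size == 0 or upper.size == 0 or np.ptp(z) == 0:
            raise MemfluxError(
                "slab markers all fall on one side; cannot define two leaflets"
            )
        lowers.append(trim_mean(lower, quantile_trim) if quantile_trim > 0 else lower.mean())
        uppers.append(trim_mean(upper, quantile_trim) if quantile_trim > 0 else upper.mean())
    return MembraneSlab(float(np.mean(lowers)), float(np.mean(uppers)))


def occupancy_series(traj: Trajectory, volume: ProteinVolume,
                     water_indices: np.ndarray | None = None) -> list[frozenset[int]]:
    """Per-frame sets of water-oxygen atom indices inside the protein volume."""
    waters = traj.water_oxygen_indices() if water_indices is None else np.asarray(
        water_indices, dtype=int)
    if waters.size == 0:
        warnings.warn("no water oxygens found; occupancy is empty", stacklevel=2)
        return [frozenset() for _ in range(traj.n_frames)]

    slab = volume.slab
    out: list[frozenset[int]] = []
    for f in range(traj.n_frames):
        wat = traj.coords[f, waters]
        prot = traj.coords[f, volume.protein_selection]
        box = None if traj.box is None else traj.box[f]
        in_slab = (wat[:, 2] >= slab.z_lower) & (wat[:, 2] <= slab.z_upper)
        near = np.zeros(len(waters), dtype=bool)
        if in_slab.any():
            if box is not None:
                tree = cKDTree(wrap(prot, box), boxsize=box)
                d, _ = tree.query(wrap(wat[in_slab], box))
            else:
                tree = cKDTree(prot)
                d, _ = tree.query(wat[in_slab])
            near[np.nonzero(in_slab)[0]] = d <= volume.proximity_cutoff
        out.append(frozenset(waters[in_slab & near].tolist()))
    return out


def _debounce(inside: np.ndarray, min_dwell: int) -> np.ndarray:
    """Suppress inside-runs shorter than min_dwell frames."""
    out = inside.copy()
    n = len(inside)
    f = 0
    while f < n:
        if inside[f]:
            start = f
            while f < n and inside[f]:
                f += 1
            if f - start < min_dwell:
                out[start:f] = False
        else:
            f += 1
    return out


def extract_events(occupancy: list[frozenset[int]], traj: Trajectory,
                   slab: MembraneSlab, replica: str | None = None,
                   min_dwell: int = 1) -> list[PermeationEvent]:
    """Turn per-frame occupancy sets into entry/exit permeation events.

    An event opens at the first inside frame after an outside frame (or at
    frame 0 if the water starts inside) and closes at the first subsequent
    outside frame. One water can generate several events. ``min_dwell`` > 1
    smooths away inside-stays shorter than that many frames before events are
    extracted (single-frame excursions count by default).
    """
    n_frames = len(occupancy)
    if n_frames != traj.n_frames:
        raise MemfluxError("occupancy length does not match trajectory")
    if min_dwell < 1:
        raise MemfluxError("min_dwell must be >= 1")
    all_waters = sorted(set().union(*occupancy)) if occupancy else []
    if min_dwell > 1:
        smoothed = {
            w: _debounce(np.array([w in occupancy[f] for f in range(n_frames)]),
                         min_dwell)
            for w in all_waters
        }
        occupancy = [
            frozenset(w for w in all_waters if smoothed[w][f])
            for f in range(n_frames)
        ]
        all_waters = sorted(set().union(*occupancy)) if occupancy else []
    events: list[PermeationEvent] = []

    def side_at(widx: int, frame: int) -> tuple[str, bool]:
        z = traj.coords[frame, widx, 2]
        side = slab.side_of(z)
        if side is None:  # laterally outside while within the slab interval
            return slab.nearest_side(z), True
        return side, False

    for w in all_waters:
        open_event: PermeationEvent | None = None
        for f in range(n_frames):
            inside = w in occupancy[f]
            if inside and open_event is None:
                if f == 0:
                    side, lateral = slab.nearest_side(traj.coords[0, w, 2]), True
                else:
                    side, lateral = side_at(w, f - 1)
                open_event = PermeationEvent(
                    water_index=int(w), entry_frame=f, entry_side=side,
                    exit_frame=None, exit_side=None, outcome="unresolved",
                    entry_lateral=lateral, replica=replica,
                )
            elif not inside and open_event is not None:
                side, lateral = side_at(w, f)
                open_event.exit_frame = f
                open_event.exit_side = side
                open_event.exit_lateral = lateral
                open_event.outcome = (
                    "crossed" if side != open_event.entry_side else "returned"
                )
                events.append(open_event)
                open_event = None
        if open_event is not None:  # still inside at the final frame
            events.append(open_event)

    events.sort(key=lambda e: (e.entry_frame, e.water_index))
    return events


def translocation_rate(events: list[PermeationEvent]) -> RateSummary:
    """Crossing fraction over resolved events, with per-replica breakdown."""
    n_crossed = sum(e.outcome == "crossed" for e in events)
    n_returned = sum(e.outcome == "returned" for e in events)
    n_unresolved = sum(e.outcome == "unresolved" for e in events)
    resolved = n_crossed + n_returned
    rate = n_crossed / resolved if resolved else None

    per_replica = None
    per_replica_mean = None
    tags = sorted({e.replica for e in events if e.replica is not None})
    if tags:
        per_replica = {}
        for tag in tags:
            sub = [e for e in events if e.replica == tag]
            c = sum(e.outcome == "crossed" for e in sub)
            r = sum(e.outcome == "returned" for e in sub)
            per_replica[tag] = c / (c + r) if (c + r) else float("nan")
        vals = [v for v in per_replica.values() if not np.isnan(v)]
        per_replica_mean = float(np.mean(vals)) if vals else None

    return RateSummary(n_crossed=n_crossed, n_returned=n_returned,
                       n_unresolved=n_unresolved, rate=rate,
                       per_replica=per_replica, per_replica_mean=per_replica_mean)


def events_table(events: list[PermeationEvent]) -> ResultTable:
    rows = [
        {
            "water_index": e.water_index,
            "entry_frame": e.entry_frame,
            "entry_side": e.entry_side,
            "exit_frame": -1 if e.exit_frame is None else e.exit_frame,
            "exit_side": e.exit_side or "none",
            "outcome": e.outcome,
            "entry_lateral": e.entry_lateral,
            "exit_lateral": e.exit_lateral,
            "replica": e.replica or "",
        }
        for e in events
    ]
    return ResultTable(pd.DataFrame(
        rows,
        columns=["water_index", "entry_frame", "entry_side", "exit_frame",
                 "exit_side", "outcome", "entry_lateral", "exit_lateral", "replica"],
    ))
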