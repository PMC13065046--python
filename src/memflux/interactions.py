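"""Inter-chain salt-bridge and hydrogen-bond occupancy.

A contact is present at a frame when the minimum inter-group heavy-atom
distance is within the cutoff (4.0 A between charged-group atoms for salt
bridges, Barlow-Thornton style; hydrogen bonds reuse the water-wire geometric
criteria). Occupancy is the fraction of analyzed frames in which the contact
is present — the statistic behind statements like "present for 74% of the
simulation time". Phosphoserine (SEP/PSER/S1P) is a first-class anionic group
so phosphorylated systems are expressible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ResultTable, Trajectory
from .errors import SelectionError
from .pbc import min_image_distance

#: Side-chain atoms carrying formal charge, per residue type.
ANIONIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SEP": ("O1P", "O2P", "O3P", "OG"),
    "PSER": ("O1P", "O2P", "O3P", "OG"),
    "S1P": ("O1P", "O2P", "O3P", "OG"),
}
CATIONIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "HSP": ("ND1", "NE2"),
}

SALT_BRIDGE_CUTOFF = 4.0
HBOND_HEAVY_CUTOFF = 3.5


@dataclass(frozen=True)
class ContactSpec:
    """A named pairwise contact between two disjoint atom groups."""

    kind: str  # salt_bridge | hbond
    group_a: np.ndarray
    group_b: np.ndarray
    distance_cutoff: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", np.asarray(self.group_a, dtype=int))
        object.__setattr__(self, "group_b", np.asarray(self.group_b, dtype=int))
        if self.kind not in ("salt_bridge", "hbond"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.group_a.size == 0 or self.group_b.size == 0:
            raise SelectionError("contact groups must be non-empty")
        if set(self.group_a.tolist()) & set(self.group_b.tolist()):
            raise SelectionError("contact groups must be disjoint")

    @property
    def cutoff(self) -> float:
        if self.distance_cutoff is not None:
            return self.distance_cutoff
        return SALT_BRIDGE_CUTOFF if self.kind == "salt_bridge" else HBOND_HEAVY_CUTOFF


@dataclass
class OccupancyResult:
    present: np.ndarray  # per-frame booleans
    occupancy: float
    per_replica: dict[str, float] | None = None

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.occupancy


def contact_series(traj: Trajectory, spec: ContactSpec,
                   replica_of_frame: np.ndarray | None = None) -> OccupancyResult:
    """Per-frame presence and occupancy of one contact."""
    present = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        box = None if traj.box is None else traj.box[f]
        d = min_image_distance(traj.coords[f, spec.group_a],
                               traj.coords[f, spec.group_b], box)
        present[f] = d.min() <= spec.cutoff
    occ = float(present.mean())

    per_replica = None
    if replica_of_frame is not None:
        tags = sorted(set(replica_of_frame))
        per_replica = {
            str(t): float(present[np.asarray(replica_of_frame) == t].mean())
            for t in tags
        }
    return OccupancyResult(present=present, occupancy=occ, per_replica=per_replica)


def resolve_residue_group(traj: Trajectory, chain_id: str, residue_id: int,
                          atom_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Atom indices of one residue, optionally restricted to named atoms."""
    idx = [a.atom_index for a in traj.atoms
           if a.chain_id == chain_id and a.residue_id == residue_id
           and (atom_names is None or a.atom_name in atom_names)]
    if not idx:
        raise SelectionError(
            f"residue {chain_id}:{residue_id} "
            f"({'any' if atom_names is None else ','.join(atom_names)}) not found"
        )
    return np.array(idx, dtype=int)


def _charged_groups(traj: Trajectory, indices: np.ndarray,
                    table: dict[str, tuple[str, ...]]) -> dict[tuple[str, int, str], np.ndarray]:
    """Per-residue charged-group atom indices within a chain selection."""
    sel = set(np.asarray(indices, dtype=int).tolist())
    groups: dict[tuple[str, int, str], list[int]] = {}
    for a in traj.atoms:
        if a.atom_index not in sel:
            continue
        names = table.get(a.residue_name)
        if names and a.atom_name in names:
            key = (a.chain_id, a.residue_id, a.residue_name)
            groups.setdefault(key, []).append(a.atom_index)
    return {k: np.array(v, dtype=int) for k, v in groups.items()}


def _polar_heavy(traj: Trajectory, indices: np.ndarray) -> dict[tuple[str, int, str], np.ndarray]:
    sel = set(np.asarray(indices, dtype=int).tolist())
    groups: dict[tuple[str, int, str], list[int]] = {}
    for a in traj.atoms:
        if a.atom_index in sel and a.element in ("N", "O"):
            groups.setdefault((a.chain_id, a.residue_id, a.residue_name), []).append(a.atom_index)
    return {k: np.array(v, dtype=int) for k, v in groups.items()}


def _pair_occupancy(traj: Trajectory, ga: np.ndarray, gb: np.ndarray, cutoff: float) -> float:
    hits = 0
    for f in range(traj.n_frames):
        box = None if traj.box is None else traj.box[f]
        d = min_image_distance(traj.coords[f, ga], traj.coords[f, gb], box)
        if d.min() <= cutoff:
            hits += 1
    return hits / traj.n_frames


def interaction_inventory(traj: Trajectory, chain_a: np.ndarray, chain_b: np.ndarray,
                          min_occupancy: float = 0.2,
                          saltbridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                          hbond_cutoff: float = HBOND_HEAVY_CUTOFF) -> ResultTable:
    """Scan cross-chain salt-bridge and hydrogen-bond candidates and report
    residue pairs at or above the occupancy threshold, sorted descending."""
    chain_a = np.asarray(chain_a, dtype=int)
    chain_b = np.asarray(chain_b, dtype=int)
    if set(chain_a.tolist()) & set(chain_b.tolist()):
        raise SelectionError("chain selections must be disjoint")

    rows = []
    seen_sb: set[tuple] = set()

    an_a, cat_a = _charged_groups(traj, chain_a, ANIONIC_ATOMS), _charged_groups(traj, chain_a, CATIONIC_ATOMS)
    an_b, cat_b = _charged_groups(traj, chain_b, ANIONIC_ATOMS), _charged_groups(traj, chain_b, CATIONIC_ATOMS)
    for neg, pos in ((an_a, cat_b), (an_b, cat_a)):
        for (ca, ra, na), ga in neg.items():
            for (cb, rb, nb), gb in pos.items():
                occ = _pair_occupancy(traj, ga, gb, saltbridge_cutoff)
                if occ >= min_occupancy:
                    key = tuple(sorted(((ca, ra), (cb, rb))))
                    if key not in seen_sb:
                        seen_sb.add(key)
                        rows.append(("salt_bridge", f"{ca}:{na}{ra}", f"{cb}:{nb}{rb}", occ))

    pol_a, pol_b = _polar_heavy(traj, chain_a), _polar_heavy(traj, chain_b)
    for (ca, ra, na), ga in pol_a.items():
        for (cb, rb, nb), gb in pol_b.items():
            if tuple(sorted(((ca, ra), (cb, rb)))) in seen_sb:
                continue
            occ = _pair_occupancy(traj, ga, gb, hbond_cutoff)
            if occ >= min_occupancy:
                rows.append(("hbond", f"{ca}:{na}{ra}", f"{cb}:{nb}{rb}", occ))

    rows.sort(key=lambda r: (-r[3], r[0], r[1], r[2]))
    df = pd.DataFrame(rows, columns=["kind", "residue_a", "residue_b", "occupancy"])
    return ResultTable(df, provenance={
        "min_occupancy": min_occupancy,
        "saltbridge_cutoff": saltbridge_cutoff,
        "hbond_cutoff": hbond_cutoff,
    })
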