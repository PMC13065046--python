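"""Synthetic trajectories with planted, machine-readable ground truth.

Each generator emulates the geometry one analysis assumes — a membrane slab
with a protein "channel" and scripted water passages, per-frame hydrogen-bond
water chains, multiple protein copies with a scripted merge schedule, or frame
ensembles drawn from planted conformations — and returns the trajectory
together with a GroundTruth record sufficient to score the analysis exactly.
Everything is deterministic given the seed; systems can be written as
multi-MODEL PDB so the full I/O path is exercised. No physical realism is
attempted: these are geometric test benches, not force-field simulations.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AtomRecord, Trajectory
from .errors import MemfluxError

# Rigid water geometry used for all planted molecules (Angstrom).
_WATER_H1 = np.array([0.7572, 0.5861, 0.0])
_WATER_H2 = np.array([-0.7572, 0.5861, 0.0])
_OH = 0.9572  # O-H bond length for donor hydrogens pointed along a wire


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic system; unused fields are ignored by
    generators that do not need them."""

    seed: int = 0
    n_frames: int | None = None
    box: tuple[float, float, float] = (60.0, 60.0, 90.0)
    slab: tuple[float, float] = (-15.0, 15.0)
    n_waters: int = 50  # background (never-entering) waters
    #: (entry_side, outcome) per scripted passage; outcome in
    #: {crossed, returned, unresolved}
    planted_events: list[tuple[str, str]] | None = None
    #: per-frame list of planted chain lengths (molecules)
    planted_wires: list[list[int]] | None = None
    n_copies: int = 7
    #: (frame, partition-from-that-frame-on) entries, partitions as tuples of
    #: copy-id tuples
    merge_schedule: list[tuple[int, tuple[tuple[int, ...], ...]]] | None = None
    #: frames from which the entity containing copy 0 straddles the periodic
    #: boundary (its contacts are then only visible with minimum-image); the
    #: default matches the final merge of the default schedule
    pbc_merge_frames: tuple[int, ...] = (15,)
    #: (n_frames, noise sigma) per planted conformation
    planted_clusters: list[tuple[int, float]] | None = None
    cluster_separation_rmsd: float = 8.0
    cluster_n_atoms: int = 20
    #: per-frame contact presence for the planted residue pair
    contact_schedule: np.ndarray | None = None
    max_speed: float | None = None  # optional cap on per-frame water displacement


@dataclass
class GroundTruth:
    """Machine-readable record of every planted quantity."""

    seed: int
    kind: str
    crossing_rate: float | None = None
    n_crossed: int | None = None
    n_returned: int | None = None
    n_unresolved: int | None = None
    event_records: list[dict] | None = None
    wire_lengths_per_frame: list[list[int]] | None = None
    entity_counts: list[int] | None = None
    partitions: list[list[list[int]]] | None = None
    frame_of_single_entity: int | None = None
    time_of_single_entity_ns: float | None = None
    cluster_labels: list[int] | None = None
    most_populated_cluster: int | None = None
    contact_occupancy: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items() if v is not None}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# atom-list builders


def _protein_rod_atoms(slab: tuple[float, float], spacing: float = 1.5
                       ) -> tuple[list[AtomRecord], np.ndarray]:
    """A static rod of dummy heavy atoms spanning the slab along z: the
    'channel' whose 6 A proximity shell defines the protein volume."""
    z = np.arange(slab[0], slab[1] + 1e-9, spacing)
    coords = np.column_stack((np.zeros_like(z), np.zeros_like(z), z))
    atoms = [
        AtomRecord(atom_index=i, atom_name="C", element="C", residue_name="DUM",
                   residue_id=i + 1, chain_id="P", copy_id=0,
                   is_water_oxygen=False, is_heavy=True)
        for i in range(len(z))
    ]
    return atoms, coords


def _append_waters(atoms: list[AtomRecord], n_waters: int, chain: str = "W",
                   copy_id: int = 1) -> list[int]:
    """Append n_waters TIP3-like waters (O,H1,H2); return their O atom indices."""
    oxygens = []
    start = len(atoms)
    resid0 = 1 + max((a.residue_id for a in atoms if a.chain_id == chain), default=0)
    for w in range(n_waters):
        base = start + 3 * w
        rid = resid0 + w
        atoms.append(AtomRecord(base, "OH2", "O", "HOH", rid, chain, copy_id, True, True))
        atoms.append(AtomRecord(base + 1, "H1", "H", "HOH", rid, chain, copy_id, False, False))
        atoms.append(AtomRecord(base + 2, "H2", "H", "HOH", rid, chain, copy_id, False, False))
        oxygens.append(base)
    return oxygens


def _place_water(coords: np.ndarray, frame: int, o_index: int, o_pos: np.ndarray,
                 h1_offset: np.ndarray | None = None,
                 h2_offset: np.ndarray | None = None) -> None:
    coords[frame, o_index] = o_pos
    coords[frame, o_index + 1] = o_pos + (_WATER_H1 if h1_offset is None else h1_offset)
    coords[frame, o_index + 2] = o_pos + (_WATER_H2 if h2_offset is None else h2_offset)


# ---------------------------------------------------------------------------
# permeation


def default_permeation_events() -> list[tuple[str, str]]:
    """The default scripted passages: 200 resolved events at a 25% crossing
    fraction (50 crossed, 150 returned) plus 10 unresolved, entry sides
    alternating between the two leaflets."""
    events: list[tuple[str, str]] = []
    for i in range(50):
        events.append(("lower" if i % 2 == 0 else "upper", "crossed"))
    for i in range(150):
        events.append(("lower" if i % 2 == 0 else "upper", "returned"))
    for i in range(10):
        events.append(("lower" if i % 2 == 0 else "upper", "unresolved"))
    return events


def generate_permeation_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Membrane-slab system with scripted water passages through the channel.

    Each scripted event gets its own water following a piecewise-linear path:
    parked outside on its entry side, a few frames inside the protein volume,
    then parked on its scripted exit side (or inside until the end for
    unresolved events). Background waters drift far from the channel axis and
    never enter.
    """
    rng = np.random.default_rng(spec.seed)
    events = spec.planted_events if spec.planted_events is not None else default_permeation_events()
    for side, outcome in events:
        if side not in ("lower", "upper") or outcome not in ("crossed", "returned", "unresolved"):
            raise MemfluxError(f"bad scripted event ({side}, {outcome})")
    n_frames = spec.n_frames or 60
    z_lo, z_hi = spec.slab
    if not (-spec.box[2] / 2 < z_lo < z_hi < spec.box[2] / 2):
        raise MemfluxError("slab must lie inside the box")
    dwell = 4
    if n_frames < dwell + 4:
        raise MemfluxError("too few frames for the scripted passages")

    atoms, rod = _protein_rod_atoms(spec.slab)
    n_rod = len(atoms)
    event_oxy = _append_waters(atoms, len(events))
    bg_oxy = _append_waters(atoms, spec.n_waters)
    n_atoms = len(atoms)
    coords = np.zeros((n_frames, n_atoms, 3))
    coords[:, :n_rod] = rod[None, :, :]

    park = 6.0  # how far beyond the slab a parked water sits
    records = []
    start_lo, start_hi = 1, n_frames - dwell - 2
    for i, (side, outcome) in enumerate(events):
        o = event_oxy[i]
        ang = 2 * np.pi * rng.random()
        lat = np.array([1.5 * np.cos(ang), 1.5 * np.sin(ang), 0.0])
        if outcome == "unresolved":
            f0 = n_frames - 1 - int(rng.integers(1, dwell))
        else:
            f0 = int(start_lo + i % max(1, start_hi - start_lo))
        z_entry_park = (z_lo - park) if side == "lower" else (z_hi + park)
        if outcome == "crossed":
            exit_side = "upper" if side == "lower" else "lower"
        else:
            exit_side = side
        z_exit_park = (z_lo - park) if exit_side == "lower" else (z_hi + park)

        inner_in = (z_lo + 2.0) if side == "lower" else (z_hi - 2.0)
        inner_out = (z_hi - 2.0) if exit_side == "upper" else (z_lo + 2.0)
        inside_z = np.linspace(inner_in, inner_out, dwell)

        for f in range(n_frames):
            if f < f0:
                z = z_entry_park
            elif outcome == "unresolved" or f < f0 + dwell:
                k = min(f - f0, dwell - 1)
                z = inside_z[k] if outcome != "unresolved" else inner_in
            else:
                z = z_exit_park
            _place_water(coords, f, o, lat + np.array([0.0, 0.0, z]))
        records.append({
            "water_oxygen": o, "entry_side": side, "outcome": outcome,
            "entry_frame": f0,
            "exit_frame": None if outcome == "unresolved" else f0 + dwell,
        })

    # Background waters: fixed lateral radius >= 12 from the axis, so they can
    # never satisfy the proximity criterion; small z drift.
    for o in bg_oxy:
        r = 14.0 + 10.0 * rng.random()
        ang = 2 * np.pi * rng.random()
        z0 = rng.uniform(-spec.box[2] / 2 + 5, spec.box[2] / 2 - 5)
        drift = np.cumsum(rng.normal(0.0, 0.3, size=n_frames))
        for f in range(n_frames):
            pos = np.array([r * np.cos(ang), r * np.sin(ang), z0 + drift[f]])
            _place_water(coords, f, o, pos)

    if spec.max_speed is not None:
        planted = np.array(event_oxy, dtype=int)
        steps = np.linalg.norm(np.diff(coords[:, planted], axis=0), axis=-1)
        if steps.size and steps.max() > spec.max_speed:
            raise MemfluxError(
                f"scripted passage needs a {steps.max():.1f} A step per frame, "
                f"over the {spec.max_speed} A speed cap"
            )

    n_crossed = sum(1 for _, o in events if o == "crossed")
    n_returned = sum(1 for _, o in events if o == "returned")
    n_unresolved = sum(1 for _, o in events if o == "unresolved")
    rate = n_crossed / (n_crossed + n_returned) if (n_crossed + n_returned) else None
    truth = GroundTruth(
        seed=spec.seed, kind="permeation",
        crossing_rate=rate, n_crossed=n_crossed, n_returned=n_returned,
        n_unresolved=n_unresolved, event_records=records,
        extras={"slab": list(spec.slab), "proximity_cutoff": 6.0},
    )
    traj = Trajectory(atoms=atoms, coords=coords,
                      box=np.tile(np.asarray(spec.box), (n_frames, 1)))
    return traj, truth


# ---------------------------------------------------------------------------
# water wires


def default_wire_schedule() -> list[list[int]]:
    """Planted chain lengths per frame, spanning every length 2..9 (one frame
    carries the 9-molecule extreme, one frame only isolated decoys)."""
    return [[3, 5], [9], [2], [4], [6], [7], [8], [], [2, 3], [5, 2], [3, 3], [4, 6]]


_CHAIN_OFFSETS = [(3.0, 0.0), (-3.0, 0.0), (0.0, 3.0)]
_DECOY_OFFSET = (0.0, -3.0)


def generate_wire_frames(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Frames with hydrogen-bonded water chains planted inside the channel
    volume, isolated in-volume decoys, and an out-of-volume decoy chain that a
    correct analysis must ignore.

    Chains run along z at 2.8 A O-O spacing with the donor hydrogen of each
    water pointing at the next oxygen (D-H...A of 180 degrees), so both the
    distance and the angle criterion hold by construction.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = spec.planted_wires if spec.planted_wires is not None else default_wire_schedule()
    n_frames = spec.n_frames or len(schedule)
    if len(schedule) != n_frames:
        raise MemfluxError("planted_wires length must equal n_frames")
    z_lo, z_hi = spec.slab
    spacing = 2.8
    for lengths in schedule:
        if len(lengths) > len(_CHAIN_OFFSETS):
            raise MemfluxError(f"at most {len(_CHAIN_OFFSETS)} chains per frame")
        for L in lengths:
            if L < 2 or z_lo + 3 + (L - 1) * spacing > z_hi - 1:
                raise MemfluxError(f"chain of {L} waters does not fit in the slab")

    max_chain_waters = max((sum(ls) for ls in schedule), default=0)
    n_decoys = 4
    n_far = 4  # out-of-volume chain

    atoms, rod = _protein_rod_atoms(spec.slab)
    n_rod = len(atoms)
    chain_oxy = _append_waters(atoms, max_chain_waters)
    decoy_oxy = _append_waters(atoms, n_decoys)
    far_oxy = _append_waters(atoms, n_far)
    coords = np.zeros((n_frames, len(atoms), 3))
    coords[:, :n_rod] = rod[None, :, :]

    parked = np.array([25.0, 25.0, 0.0])  # outside the volume, inside the box
    truth_lengths: list[list[int]] = []
    for f, lengths in enumerate(schedule):
        used = 0
        for o in chain_oxy:
            _place_water(coords, f, o, parked + np.array([0, 0, -30.0]))
        for ci, L in enumerate(lengths):
            ox, oy = _CHAIN_OFFSETS[ci]
            z0 = z_lo + 3.0
            for k in range(L):
                o = chain_oxy[used]
                used += 1
                pos = np.array([ox, oy, z0 + k * spacing])
                if k < L - 1:  # donor hydrogen aimed at the next oxygen
                    h1 = np.array([0.0, 0.0, _OH])
                else:
                    h1 = np.array([_OH, 0.0, 0.0])
                h2 = np.array([-0.68, 0.68, 0.0])
                _place_water(coords, f, o, pos, h1, h2)
        # isolated in-volume decoys, >= 4 A from every chain and one another
        dx, dy = _DECOY_OFFSET
        for j, o in enumerate(decoy_oxy):
            z = z_lo + 3.0 + 5.0 * j + rng.uniform(-0.3, 0.3)
            _place_water(coords, f, o, np.array([dx, dy, z]))
        # a hydrogen-bonded chain far from the protein: outside the volume
        for j, o in enumerate(far_oxy):
            pos = np.array([22.0, 0.0, z_lo + 3.0 + j * spacing])
            h1 = np.array([0.0, 0.0, _OH]) if j < n_far - 1 else np.array([_OH, 0.0, 0.0])
            _place_water(coords, f, o, pos, h1, np.array([-0.68, 0.68, 0.0]))
        truth_lengths.append(sorted(lengths))

    truth = GroundTruth(seed=spec.seed, kind="wires",
                        wire_lengths_per_frame=truth_lengths,
                        extras={"slab": list(spec.slab), "oo_spacing": spacing})
    traj = Trajectory(atoms=atoms, coords=coords,
                      box=np.tile(np.asarray(spec.box), (n_frames, 1)))
    return traj, truth


# ---------------------------------------------------------------------------
# aggregation


def default_merge_schedule() -> list[tuple[int, tuple[tuple[int, ...], ...]]]:
    """Entity partitions over time for 7 copies: 7 -> 4 -> 2 -> 1."""
    return [
        (5, ((0, 1), (2, 3), (4, 5), (6,))),
        (10, ((0, 1, 2, 3), (4, 5, 6))),
        (15, ((0, 1, 2, 3, 4, 5, 6),)),
    ]


_LATTICE = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
                     (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)], dtype=float)
_TETRA = 1.2 * np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / np.sqrt(3)


def generate_aggregation_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Multi-copy box with a scripted merge schedule.

    Copies are rigid 4-atom dummies; entities sit at well-separated sites and
    the copies inside an entity occupy adjacent cells of a 5 A cubic lattice,
    which keeps every entity contact-connected at the 4.5 A cutoff while
    entities stay far apart. From ``pbc_merge_frames`` on, the entity holding
    copy 0 is centred on the box face so its contacts are only visible through
    minimum-image distances. Coordinates are stored wrapped into [0, L).
    """
    rng = np.random.default_rng(spec.seed)
    n_copies = spec.n_copies
    if n_copies < 2:
        raise MemfluxError("need at least 2 copies")
    schedule = (spec.merge_schedule if spec.merge_schedule is not None
                else (default_merge_schedule() if n_copies == 7 else []))
    n_frames = spec.n_frames or 20
    box = np.asarray(spec.box, dtype=float)
    if spec.box == (60.0, 60.0, 90.0):  # permeation default; aggregation wants a cube
        box = np.array([90.0, 90.0, 90.0])

    # partition per frame
    partitions: list[list[tuple[int, ...]]] = []
    current: list[tuple[int, ...]] = [(i,) for i in range(n_copies)]
    sched = sorted(schedule)
    si = 0
    for f in range(n_frames):
        while si < len(sched) and sched[si][0] == f:
            current = [tuple(sorted(g)) for g in sched[si][1]]
            flat = sorted(c for g in current for c in g)
            if flat != list(range(n_copies)):
                raise MemfluxError(f"schedule at frame {f} is not a partition of the copies")
            si += 1
        partitions.append(sorted(current, key=lambda g: g[0]))

    sites = np.array([
        (0.2, 0.2, 0.2), (0.7, 0.2, 0.2), (0.2, 0.7, 0.2), (0.7, 0.7, 0.2),
        (0.2, 0.2, 0.7), (0.7, 0.2, 0.7), (0.2, 0.7, 0.7), (0.7, 0.7, 0.7),
    ]) * box
    if n_copies > len(sites):
        raise MemfluxError("too many copies for the fixed site layout")

    atoms: list[AtomRecord] = []
    for c in range(n_copies):
        chain = chr(ord("A") + c)
        for k in range(4):
            atoms.append(AtomRecord(len(atoms), f"C{k + 1}", "C", "DUM", 1, chain,
                                    c, False, True))
    coords = np.zeros((n_frames, len(atoms), 3))

    jitter = rng.normal(0.0, 0.4, size=(n_frames, len(sites), 3))
    for f in range(n_frames):
        for ent_idx, group in enumerate(partitions[f]):
            centre = sites[ent_idx] + jitter[f, ent_idx]
            if 0 in group and spec.pbc_merge_frames and f >= min(spec.pbc_merge_frames):
                centre = np.array([0.0, 0.5 * box[1], 0.5 * box[2]])  # straddles x boundary
            offsets = _LATTICE[: len(group)] * 5.0
            offsets = offsets - offsets.mean(axis=0)
            for copy, off in zip(group, offsets):
                base = 4 * copy
                coords[f, base:base + 4] = centre + off + _TETRA
    coords = np.mod(coords, box)

    counts = [len(p) for p in partitions]
    frame_times = 20.0 * np.arange(n_frames)  # ns
    ones = [f for f, c in enumerate(counts) if c == 1]
    truth = GroundTruth(
        seed=spec.seed, kind="aggregation",
        entity_counts=counts,
        partitions=[[sorted(g) for g in p] for p in partitions],
        frame_of_single_entity=ones[0] if ones else None,
        time_of_single_entity_ns=float(frame_times[ones[0]]) if ones else None,
        extras={"n_copies": n_copies, "contact_cutoff": 4.5,
                "pbc_merge_frames": list(spec.pbc_merge_frames)},
    )
    traj = Trajectory(atoms=atoms, coords=coords,
                      box=np.tile(box, (n_frames, 1)), frame_times=frame_times)
    return traj, truth


# ---------------------------------------------------------------------------
# conformational clusters


def generate_cluster_frames(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Frames drawn from planted conformations plus isotropic Gaussian noise,
    each frame additionally rotated and translated at random so clustering has
    to superpose before measuring."""
    from scipy.spatial.transform import Rotation

    from .geometry import pair_rmsd

    rng = np.random.default_rng(spec.seed)
    clusters = spec.planted_clusters if spec.planted_clusters is not None else [(40, 0.2), (20, 0.2)]
    n_atoms = spec.cluster_n_atoms
    target = spec.cluster_separation_rmsd

    base = 3.0 * rng.normal(size=(n_atoms, 3))
    confs = [base]
    for _ in range(len(clusters) - 1):
        direction = rng.normal(size=(n_atoms, 3))
        direction -= direction.mean(axis=0)
        # Scale the displacement so the superposed RMSD to the base hits the
        # requested separation (bisection; superposition absorbs part of it).
        lo, hi = 0.0, 10.0 * target
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if pair_rmsd(base, base + mid * direction / np.sqrt((direction ** 2).sum(1).mean())) < target:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi) / np.sqrt((direction ** 2).sum(1).mean())
        confs.append(base + scale * direction)

    labels: list[int] = []
    for ci, (nf, _sigma) in enumerate(clusters):
        labels.extend([ci] * nf)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    frames = []
    per_label_sigma = {ci: s for ci, (_n, s) in enumerate(clusters)}
    for lab in labels:
        conf = confs[lab] + rng.normal(0.0, per_label_sigma[lab], size=(n_atoms, 3))
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        shift = rng.uniform(-10, 10, size=3)
        frames.append(conf @ rot.T + shift)

    sizes = [n for n, _ in clusters]
    most = int(np.argmax(sizes))  # argmax keeps the lowest index on ties
    atoms = [
        AtomRecord(i, "CA", "C", "GLY", i + 1, "A", 0, False, True)
        for i in range(n_atoms)
    ]
    truth = GroundTruth(seed=spec.seed, kind="clusters",
                        cluster_labels=labels, most_populated_cluster=most,
                        extras={"separation_rmsd": target,
                                "sizes": sizes})
    return Trajectory(atoms=atoms, coords=np.array(frames)), truth


# ---------------------------------------------------------------------------
# planted contact series


def generate_contact_trajectory(spec: SyntheticSpec, n_present: int = 74,
                                n_frames: int = 100, phospho: bool = False
                                ) -> tuple[Trajectory, GroundTruth]:
    """Two-chain system with a salt bridge present in exactly ``n_present`` of
    ``n_frames`` frames.

    Chain A carries a glutamate-like carboxylate (or a phosphoserine when
    ``phospho``); chain B an arginine-like guanidinium. In "present" frames the
    groups sit 3.5 A apart; otherwise 12 A. The schedule (which frames are
    present) is a seeded permutation, or ``spec.contact_schedule`` verbatim.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.contact_schedule is not None:
        present = np.asarray(spec.contact_schedule, dtype=bool)
        n_frames = len(present)
    else:
        present = np.zeros(n_frames, dtype=bool)
        present[rng.permutation(n_frames)[:n_present]] = True

    atoms: list[AtomRecord] = []
    if phospho:
        resname, names = "SEP", ("O1P", "O2P", "O3P")
    else:
        resname, names = "GLU", ("OE1", "OE2")
    for k, nm in enumerate(names):
        atoms.append(AtomRecord(len(atoms), nm, "O", resname, 28, "A", 0, False, True))
    for nm in ("NH1", "NH2", "NE"):
        atoms.append(AtomRecord(len(atoms), nm, "N", "ARG", 324, "B", 1, False, True))
    n_a = len(names)

    coords = np.zeros((n_frames, len(atoms), 3))
    for f in range(n_frames):
        gap = 3.5 if present[f] else 12.0
        for k in range(n_a):
            coords[f, k] = np.array([0.0, 1.2 * k, 0.0])
        for k in range(3):
            coords[f, n_a + k] = np.array([gap, 1.2 * k, 0.0])

    truth = GroundTruth(seed=spec.seed, kind="contact",
                        contact_occupancy=float(present.mean()),
                        extras={"present_frames": [int(i) for i in np.nonzero(present)[0]],
                                "phospho": phospho})
    return Trajectory(atoms=atoms, coords=coords), truth
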