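"""Core data model and I/O: atoms, trajectories, result tables, PDB reading/writing.

Internal conventions: lengths in Angstrom, times in ns, 0-based atom and frame
indices. Only orthorhombic periodic boxes are supported; triclinic input is
refused explicitly.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    MemfluxError,
    PDBParseError,
    StructureError,
    UnsupportedFeatureError,
)

#: Residue names recognised as water (configurable per call).
DEFAULT_WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: Bondi-style van der Waals radii (Angstrom) used for SASA and heavy-atom work.
DEFAULT_VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

_STANDARD_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                    "S": 32.06, "P": 30.974}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``copy_id`` identifies which protein copy the atom belongs to (used by the
    aggregation analysis); by default copies are assigned per chain, in order
    of first appearance.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    copy_id: int
    is_water_oxygen: bool
    is_heavy: bool


def _infer_element(atom_name: str, element_field: str = "") -> str:
    el = element_field.strip()
    if el:
        return el.capitalize()
    # Fall back to the first alphabetic character of the atom name,
    # skipping leading digits (e.g. "1HB" -> H).
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass
class Trajectory:
    """In-memory trajectory: atom metadata plus per-frame coordinates.

    coords has shape (n_frames, n_atoms, 3) in Angstrom. ``box`` holds the
    per-frame orthorhombic box lengths (Lx, Ly, Lz), or None when the input
    carried no box. ``frame_times``, if present, is in ns and strictly
    increasing.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    box: np.ndarray | None = None
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coords carry {self.coords.shape[1]} atoms but topology has {len(self.atoms)}"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise StructureError("box must have shape (n_frames, 3)")
            if not np.all(self.box > 0):
                raise StructureError("box lengths must be positive")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise StructureError("frame_times must have one entry per frame")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise StructureError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    # -- common selections -------------------------------------------------

    def water_oxygen_indices(self) -> np.ndarray:
        return np.array([a.atom_index for a in self.atoms if a.is_water_oxygen], dtype=int)

    def protein_heavy_indices(self) -> np.ndarray:
        """Heavy atoms of everything that is not water."""
        water_res = {(a.chain_id, a.residue_id) for a in self.atoms if a.is_water_oxygen}
        return np.array(
            [a.atom_index for a in self.atoms
             if a.is_heavy and (a.chain_id, a.residue_id) not in water_res],
            dtype=int,
        )

    def water_hydrogens(self) -> dict[int, list[int]]:
        """Map each water oxygen index to the hydrogen indices of its molecule."""
        by_residue: dict[tuple[str, int], list[AtomRecord]] = {}
        for a in self.atoms:
            by_residue.setdefault((a.chain_id, a.residue_id), []).append(a)
        mapping: dict[int, list[int]] = {}
        for a in self.atoms:
            if a.is_water_oxygen:
                mates = by_residue[(a.chain_id, a.residue_id)]
                mapping[a.atom_index] = [m.atom_index for m in mates if m.element == "H"]
        return mapping

    def copy_ids(self) -> np.ndarray:
        return np.array([a.copy_id for a in self.atoms], dtype=int)

    def masses(self) -> np.ndarray:
        return np.array([_STANDARD_MASSES.get(a.element, 12.0) for a in self.atoms])

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            atoms=self.atoms,
            coords=self.coords[::stride],
            box=None if self.box is None else self.box[::stride],
            frame_times=None if self.frame_times is None else self.frame_times[::stride],
        )


# ---------------------------------------------------------------------------
# ResultTable


@dataclass
class ResultTable:
    """A typed tabular result with a provenance block.

    The TSV writer emits a single header row plus data rows; the JSON writer
    additionally embeds provenance (inputs, parameters, seed, tool version).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prov = dict(self.provenance)
        prov.setdefault("tool", "memflux")
        from . import __version__

        prov.setdefault("version", __version__)
        self.provenance = prov

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        return self.data.equals(other.data)

    def write(self, path: str | Path, fmt: str | None = None, empty_ok: bool = False) -> None:
        write_result(self, path, fmt=fmt, empty_ok=empty_ok)


def write_result(table: ResultTable, path: str | Path, fmt: str | None = None,
                 empty_ok: bool = False) -> None:
    """Serialize a ResultTable as TSV or JSON.

    Empty tables are refused unless ``empty_ok`` is set, so silently vacuous
    analyses cannot masquerade as results.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown result format {fmt!r}")
    if len(table.data) == 0 and not empty_ok:
        raise MemfluxError(f"refusing to write empty table to {path} (pass empty_ok=True)")
    if fmt == "tsv":
        table.data.to_csv(path, sep="\t", index=False)
    else:
        payload = {
            "provenance": table.provenance,
            "columns": list(table.data.columns),
            "rows": json.loads(table.data.to_json(orient="values")),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path, fmt: str | None = None) -> ResultTable:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "tsv":
        return ResultTable(pd.read_csv(path, sep="\t"))
    payload = json.loads(path.read_text())
    df = pd.DataFrame(payload["rows"], columns=payload["columns"])
    return ResultTable(df, provenance=payload.get("provenance", {}))


# ---------------------------------------------------------------------------
# PDB reading / writing

_ORTHO_TOL = 1e-3


def _parse_cryst1(line: str, line_no: int) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed CRYST1 record: {exc}", line_no) from exc
    if any(abs(angle - 90.0) > _ORTHO_TOL for angle in (alpha, beta, gamma)):
        raise UnsupportedFeatureError(
            f"triclinic box (angles {alpha}, {beta}, {gamma}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return np.array([a, b, c])


def load_structure(path: str | Path, fmt: str = "pdb",
                   water_residues: frozenset[str] = DEFAULT_WATER_RESIDUES) -> Trajectory:
    """Parse a (possibly multi-MODEL) PDB file into a Trajectory.

    Each MODEL becomes one frame; a file without MODEL records yields a single
    frame. CRYST1, when present, sets the orthorhombic box on every frame.
    Waters are detected by residue name against ``water_residues``.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported structure format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    box_lengths: np.ndarray | None = None
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    atoms_meta: list[dict] | None = None
    current_meta: list[dict] = []
    in_model = False

    def close_frame(meta: list[dict], coords: list, line_no: int) -> None:
        nonlocal atoms_meta
        if atoms_meta is None:
            atoms_meta = meta
        elif len(meta) != len(atoms_meta):
            raise StructureError(
                f"model ending at line {line_no} has {len(meta)} atoms; "
                f"expected {len(atoms_meta)} as in the first model"
            )
        frames.append(coords)

    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            box_lengths = _parse_cryst1(line, line_no)
        elif record == "MODEL":
            in_model = True
            current = []
            current_meta = []
        elif record == "ENDMDL":
            if current is None:
                raise PDBParseError("ENDMDL without matching MODEL", line_no)
            close_frame(current_meta, current, line_no)
            current = None
            current_meta = []
        elif record in ("ATOM", "HETATM"):
            if current is None:
                current = []
                current_meta = []
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                residue_id = int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"malformed {record} record: {exc}", line_no) from exc
            name = line[12:16].strip()
            if not name:
                raise PDBParseError(f"{record} record has empty atom name", line_no)
            current.append((x, y, z))
            current_meta.append(
                {
                    "atom_name": name,
                    "residue_name": line[17:21].strip(),
                    "chain_id": line[21:22].strip() or "A",
                    "residue_id": residue_id,
                    "element": _infer_element(name, line[76:78] if len(line) >= 78 else ""),
                }
            )

    if current is not None and current:
        if in_model:
            raise PDBParseError("file ends inside an unterminated MODEL block", line_no)
        close_frame(current_meta, current, line_no)

    if not frames:
        raise StructureError(f"{path} contains no atoms")

    assert atoms_meta is not None
    chain_order: dict[str, int] = {}
    atoms: list[AtomRecord] = []
    for idx, meta in enumerate(atoms_meta):
        chain = meta["chain_id"]
        copy_id = chain_order.setdefault(chain, len(chain_order))
        element = meta["element"]
        is_wox = element == "O" and meta["residue_name"] in water_residues
        atoms.append(
            AtomRecord(
                atom_index=idx,
                atom_name=meta["atom_name"],
                element=element,
                residue_name=meta["residue_name"],
                residue_id=meta["residue_id"],
                chain_id=chain,
                copy_id=copy_id,
                is_water_oxygen=is_wox,
                is_heavy=element != "H",
            )
        )

    coords = np.array(frames, dtype=float)
    box = None if box_lengths is None else np.tile(box_lengths, (len(frames), 1))
    return Trajectory(atoms=atoms, coords=coords, box=box)


def write_structure(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-MODEL PDB (coordinates at %8.3f)."""
    path = Path(path)
    buf = io.StringIO()
    if traj.box is not None:
        a, b, c = traj.box[0]
        buf.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
    for f in range(traj.n_frames):
        buf.write(f"MODEL {f + 1:>8d}\n")
        for a in traj.atoms:
            x, y, z = traj.coords[f, a.atom_index]
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            buf.write(
                f"ATOM  {a.atom_index % 99999 + 1:>5d} {name:<4.4s} "
                f"{a.residue_name:<4.4s}{a.chain_id[:1]}{a.residue_id % 10000:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element:>2.2s}\n"
            )
        buf.write("ENDMDL\n")
    buf.write("END\n")
    path.write_text(buf.getvalue())


def load_trajectory(topology: str | Path, traj: str | Path,
                    water_residues: frozenset[str] = DEFAULT_WATER_RESIDUES) -> Trajectory:
    """Load a binary trajectory (DCD, XTC, ...) against a topology via MDAnalysis.

    The Trajectory contract is identical to :func:`load_structure`. Frames
    without box information yield ``box=None`` and PBC-dependent analyses will
    refuse to run.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        try:
            u = mda.Universe(str(topology), str(traj))
        except (ValueError, IOError, EOFError) as exc:
            raise StructureError(f"could not load trajectory {traj}: {exc}") from exc

        chain_order: dict[str, int] = {}
        atoms: list[AtomRecord] = []
        for idx, at in enumerate(u.atoms):
            try:
                chain = str(at.segid).strip() or "A"
            except Exception:
                chain = "A"
            copy_id = chain_order.setdefault(chain, len(chain_order))
            try:
                element = str(at.element).capitalize()
            except Exception:
                element = _infer_element(at.name)
            resname = str(at.resname).strip()
            is_wox = element == "O" and resname in water_residues
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=str(at.name),
                    element=element,
                    residue_name=resname,
                    residue_id=int(at.resid),
                    chain_id=chain,
                    copy_id=copy_id,
                    is_water_oxygen=is_wox,
                    is_heavy=element != "H",
                )
            )

        coords = []
        boxes = []
        have_box = True
        for ts in u.trajectory:
            coords.append(ts.positions.copy())
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                have_box = False
            else:
                if any(abs(angle - 90.0) > _ORTHO_TOL for angle in dims[3:6]):
                    raise UnsupportedFeatureError(
                        "triclinic trajectory boxes are not supported"
                    )
                boxes.append(np.asarray(dims[:3], dtype=float))

    return Trajectory(
        atoms=atoms,
        coords=np.array(coords, dtype=float),
        box=np.array(boxes) if have_box and boxes else None,
    )
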