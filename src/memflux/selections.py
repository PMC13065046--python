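"""A deliberately small atom-selection mini-language.

Grammar (clauses joined by ``and``):

    chain <id> [<id> ...]
    resid <n> | <a>-<b>
    resname <name> [<name> ...]
    name <atom-name> [<atom-name> ...]
    element <symbol> [<symbol> ...]
    protein | water | heavy | all

Examples: ``"chain A and name CA"``, ``"resid 1-30 and heavy"``.
"""
from __future__ import annotations

import numpy as np

from .core import Trajectory
from .errors import SelectionError


def _clause_mask(traj: Trajectory, tokens: list[str]) -> np.ndarray:
    n = traj.n_atoms
    kw = tokens[0].lower()
    args = tokens[1:]
    atoms = traj.atoms
    if kw == "all":
        return np.ones(n, dtype=bool)
    if kw == "heavy":
        return np.array([a.is_heavy for a in atoms])
    if kw == "water":
        water_res = {(a.chain_id, a.residue_id) for a in atoms if a.is_water_oxygen}
        return np.array([(a.chain_id, a.residue_id) in water_res for a in atoms])
    if kw == "protein":
        water_res = {(a.chain_id, a.residue_id) for a in atoms if a.is_water_oxygen}
        return np.array([(a.chain_id, a.residue_id) not in water_res for a in atoms])
    if not args:
        raise SelectionError(f"selection keyword {kw!r} needs arguments")
    if kw == "chain":
        wanted = set(args)
        return np.array([a.chain_id in wanted for a in atoms])
    if kw == "resname":
        wanted = set(args)
        return np.array([a.residue_name in wanted for a in atoms])
    if kw == "name":
        wanted = set(args)
        return np.array([a.atom_name in wanted for a in atoms])
    if kw == "element":
        wanted = {w.capitalize() for w in args}
        return np.array([a.element in wanted for a in atoms])
    if kw == "resid":
        mask = np.zeros(n, dtype=bool)
        for arg in args:
            if "-" in arg and not arg.startswith("-"):
                lo_s, _, hi_s = arg.partition("-")
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError as exc:
                    raise SelectionError(f"bad resid range {arg!r}") from exc
                mask |= np.array([lo <= a.residue_id <= hi for a in atoms])
            else:
                try:
                    rid = int(arg)
                except ValueError as exc:
                    raise SelectionError(f"bad resid {arg!r}") from exc
                mask |= np.array([a.residue_id == rid for a in atoms])
        return mask
    raise SelectionError(f"unknown selection keyword {kw!r}")


def select(traj: Trajectory, expression: str) -> np.ndarray:
    """Resolve a selection expression to sorted atom indices."""
    expression = expression.strip()
    if not expression:
        raise SelectionError("empty selection expression")
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        tokens = clause.split()
        if not tokens:
            raise SelectionError(f"empty clause in {expression!r}")
        mask &= _clause_mask(traj, tokens)
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return indices
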