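"""Hydrogen-bonded water wires inside the protein volume.

Per frame, a graph is built over the in-volume water oxygens with an edge
between two waters when their O-O distance is within the cutoff and (when
hydrogens are available) some D-H...A angle passes the linearity threshold in
either donor direction. A "wire" is a connected component with >= 2 molecules;
its length is the number of molecules on the component's longest simple path,
computed exactly for components up to 15 nodes and bounded from below by a
double-sweep BFS (flagged approximate) beyond that.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ResultTable, Trajectory
from .errors import MemfluxError
from .pbc import minimum_image, wrap
from .permeation import ProteinVolume, occupancy_series

EXACT_PATH_LIMIT = 15


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition for water-water contacts.

    When ``require_hydrogens`` is False (e.g. a heavy-atom-only topology) the
    angle test is skipped and only the O-O distance applies; outputs flag this.
    """

    max_oo_distance: float = 3.5
    min_dha_angle: float = 150.0
    require_hydrogens: bool = True


@dataclass
class WireGraph:
    frame: int
    graph: nx.Graph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


@dataclass
class WireMeasure:
    """Length (molecules on the longest simple path) of one wire."""

    length: int
    n_molecules: int
    approx: bool = False


@dataclass
class WireStats:
    frames: np.ndarray
    wire_count: np.ndarray
    max_length: np.ndarray  # NaN where a frame has no wires
    mean_length: np.ndarray
    per_frame_wires: list[list[WireMeasure]] = field(default_factory=list)

    def to_table(self, provenance: dict | None = None) -> ResultTable:
        df = pd.DataFrame({
            "frame": self.frames,
            "wire_count": self.wire_count,
            "max_wire_length": self.max_length,
            "mean_wire_length": self.mean_length,
        })
        return ResultTable(df, provenance=provenance or {})


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray,
               box: np.ndarray | None) -> float:
    """D-H...A angle at the hydrogen, degrees (180 = linear)."""
    v1 = minimum_image(donor - hydrogen, box)
    v2 = minimum_image(acceptor - hydrogen, box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_edges(coords: np.ndarray, water_oxygens: np.ndarray,
                hydrogens: dict[int, list[int]] | None,
                criteria: HBondCriteria,
                box: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Water-water hydrogen-bond edges among the given oxygen atom indices."""
    oxy = np.asarray(water_oxygens, dtype=int)
    if oxy.size == 0:
        raise MemfluxError("oxygen set is empty")
    if criteria.require_hydrogens:
        if not hydrogens or any(not hydrogens.get(int(o)) for o in oxy):
            raise MemfluxError(
                "hydrogen positions unavailable for some waters; rerun with "
                "require_hydrogens=False for distance-only hydrogen bonds"
            )

    pts = coords[oxy]
    if box is not None:
        tree = cKDTree(wrap(pts, box), boxsize=box)
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(criteria.max_oo_distance, output_type="ndarray")

    edges: list[tuple[int, int]] = []
    for ia, ib in pairs:
        a, b = int(oxy[ia]), int(oxy[ib])
        if not criteria.require_hydrogens:
            edges.append((min(a, b), max(a, b)))
            continue
        bonded = False
        for donor, acceptor in ((a, b), (b, a)):
            for h in hydrogens[donor]:
                ang = _dha_angle(coords[donor], coords[h], coords[acceptor], box)
                if ang >= criteria.min_dha_angle:
                    bonded = True
                    break
            if bonded:
                break
        if bonded:
            edges.append((min(a, b), max(a, b)))
    return sorted(edges)


def _longest_simple_path_exact(g: nx.Graph) -> int:
    """Node count of the longest simple path, exhaustive DFS with extension pruning."""
    best = 1
    nodes = sorted(g.nodes)

    def dfs(node, visited: set, length: int) -> None:
        nonlocal best
        if length > best:
            best = length
        for nb in g.neighbors(node):
            if nb not in visited:
                visited.add(nb)
                dfs(nb, visited, length + 1)
                visited.remove(nb)

    for start in nodes:
        dfs(start, {start}, 1)
    return best


def _double_sweep_lower_bound(g: nx.Graph) -> int:
    start = min(g.nodes)
    dist = nx.single_source_shortest_path_length(g, start)
    far = min(n for n, d in dist.items() if d == max(dist.values()))
    dist2 = nx.single_source_shortest_path_length(g, far)
    return max(dist2.values()) + 1


def wire_lengths(graph: nx.Graph) -> list[WireMeasure]:
    """Lengths of all wires (components with >= 2 molecules) in a frame graph.

    Exact longest-simple-path for components up to ``EXACT_PATH_LIMIT`` nodes;
    larger components get a BFS double-sweep lower bound flagged approx.
    """
    out: list[WireMeasure] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        if len(comp) <= EXACT_PATH_LIMIT:
            out.append(WireMeasure(_longest_simple_path_exact(sub), len(comp), False))
        else:
            out.append(WireMeasure(_double_sweep_lower_bound(sub), len(comp), True))
    out.sort(key=lambda w: (-w.length, -w.n_molecules))
    return out


def wire_graph_series(traj: Trajectory, volume: ProteinVolume,
                      criteria: HBondCriteria) -> list[WireGraph]:
    occupancy = occupancy_series(traj, volume)
    hydrogens = traj.water_hydrogens() if criteria.require_hydrogens else None
    graphs: list[WireGraph] = []
    for f, members in enumerate(occupancy):
        g = nx.Graph()
        g.add_nodes_from(sorted(members))
        if members:
            box = None if traj.box is None else traj.box[f]
            edges = hbond_edges(traj.coords[f], np.array(sorted(members)),
                                hydrogens, criteria, box)
            g.add_edges_from(edges)
        graphs.append(WireGraph(frame=f, graph=g))
    return graphs


def wire_stats_series(traj: Trajectory, volume: ProteinVolume,
                      criteria: HBondCriteria | None = None) -> WireStats:
    """Per-frame max/mean wire length; frames without wires carry NaN, not 0."""
    criteria = criteria or HBondCriteria()
    graphs = wire_graph_series(traj, volume, criteria)
    n = len(graphs)
    counts = np.zeros(n, dtype=int)
    max_len = np.full(n, np.nan)
    mean_len = np.full(n, np.nan)
    per_frame: list[list[WireMeasure]] = []
    for i, wg in enumerate(graphs):
        wires = wire_lengths(wg.graph)
        per_frame.append(wires)
        counts[i] = len(wires)
        if wires:
            lengths = [w.length for w in wires]
            max_len[i] = max(lengths)
            mean_len[i] = float(np.mean(lengths))
    return WireStats(frames=np.arange(n), wire_count=counts,
                     max_length=max_len, mean_length=mean_len,
                     per_frame_wires=per_frame)


def length_histograms(stats: WireStats) -> dict[str, dict]:
    """Aggregate distributions of per-frame max and mean wire lengths."""
    max_vals = stats.max_length[~np.isnan(stats.max_length)]
    mean_vals = stats.mean_length[~np.isnan(stats.mean_length)]
    max_hist = {int(v): int(c) for v, c in
                zip(*np.unique(max_vals.astype(int), return_counts=True))} if max_vals.size else {}
    mean_edges = np.arange(2.0, (mean_vals.max() if mean_vals.size else 2.0) + 1.0, 0.5)
    if mean_vals.size:
        counts, edges = np.histogram(mean_vals, bins=mean_edges) if len(mean_edges) > 1 else (
            np.array([mean_vals.size]), np.array([2.0, 2.5]))
        mean_hist = {"bin_edges": edges.tolist(), "counts": counts.tolist()}
    else:
        mean_hist = {"bin_edges": [], "counts": []}
    return {"max_wire_length": max_hist, "mean_wire_length": mean_hist}
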