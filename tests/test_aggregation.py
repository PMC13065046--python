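import itertools

import networkx as nx
import numpy as np
import pytest

import memflux as mf
from conftest import make_toy_trajectory


def brute_force_components(graph: nx.Graph) -> list[frozenset]:
    """Transitive closure by repeated squaring of the adjacency relation."""
    nodes = sorted(graph.nodes)
    reach = {n: {n} | set(graph.neighbors(n)) for n in nodes}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            new = set().union(*(reach[m] for m in reach[n]))
            if new != reach[n]:
                reach[n] = new
                changed = True
    return sorted({frozenset(v) for v in reach.values()}, key=min)


def brute_force_min_image_dist(a, b, box):
    """Minimum distance over all 27 periodic images."""
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * box
        d = np.linalg.norm(a[:, None, :] - (b + shift)[None, :, :], axis=-1)
        best = min(best, d.min())
    return best


def copies_trajectory(centres, box=None):
    """One frame, one atom per copy at the given centres."""
    centres = np.asarray(centres, dtype=float)
    atoms = [mf.AtomRecord(i, "C", "C", "DUM", 1, chr(ord("A") + i), i, False, True)
             for i in range(len(centres))]
    return mf.Trajectory(atoms=atoms, coords=centres[None, :, :],
                         box=None if box is None else np.asarray(box)[None, :])


class TestContactGraph:
    def test_all_far_apart_edgeless(self):
        centres = np.array([[10.0 * i, 11.0 * i % 80, 13.0 * i % 80] for i in range(7)])
        t = copies_trajectory(centres)
        g = mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                  mf.ContactGraphSpec(use_pbc=False))
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 7

    def test_chain_gives_path_graph(self):
        centres = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        t = copies_trajectory(centres)
        g = mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                  mf.ContactGraphSpec(use_pbc=False))
        assert sorted(g.edges) == [(0, 1), (1, 2)]

    def test_edge_across_boundary_only_with_pbc(self):
        box = np.array([50.0, 50.0, 50.0])
        centres = np.array([[1.0, 25.0, 25.0], [48.0, 25.0, 25.0]])  # 3 A via image
        t = copies_trajectory(centres, box=box)
        g_pbc = mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                      mf.ContactGraphSpec(use_pbc=True), box=box)
        assert (0, 1) in g_pbc.edges
        g_direct = mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                         mf.ContactGraphSpec(use_pbc=False))
        assert (0, 1) not in g_direct.edges
        # agreement with the 27-image brute force
        assert brute_force_min_image_dist(centres[:1], centres[1:], box) == pytest.approx(3.0)

    def test_pbc_without_box_refused(self):
        t = copies_trajectory(np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(mf.errors.MemfluxError):
            mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                  mf.ContactGraphSpec(use_pbc=True), box=None)

    def test_random_frames_match_brute_force_closure(self, rng):
        """Entity partitions equal brute-force transitive closure over random
        7-copy contact graphs, with PBC distances checked against 27 images."""
        box = np.array([40.0, 40.0, 40.0])
        spec = mf.ContactGraphSpec(contact_cutoff=4.5, use_pbc=True)
        for _ in range(60):
            centres = rng.uniform(0, 40, size=(7, 3))
            t = copies_trajectory(centres, box=box)
            g = mf.copy_contact_graph(t.coords[0], t.copy_ids(), spec, box=box)
            # edges must match the brute-force distance criterion
            for i, j in itertools.combinations(range(7), 2):
                d = brute_force_min_image_dist(centres[i:i + 1], centres[j:j + 1], box)
                assert ((i, j) in g.edges) == (d <= 4.5)
            got = sorted(nx.connected_components(g), key=min)
            want = brute_force_components(g)
            assert [frozenset(c) for c in got] == want

    def test_lattice_shift_invariance(self, rng):
        box = np.array([30.0, 30.0, 30.0])
        centres = rng.uniform(0, 30, size=(5, 3))
        spec = mf.ContactGraphSpec(use_pbc=True)
        t1 = copies_trajectory(centres, box=box)
        g1 = mf.copy_contact_graph(t1.coords[0], t1.copy_ids(), spec, box=box)
        shifted = centres + np.array([30.0, -60.0, 90.0])
        t2 = copies_trajectory(shifted, box=box)
        g2 = mf.copy_contact_graph(t2.coords[0], t2.copy_ids(), spec, box=box)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_count_monotone_in_cutoff(self, rng):
        box = np.array([30.0, 30.0, 30.0])
        centres = rng.uniform(0, 30, size=(6, 3))
        t = copies_trajectory(centres, box=box)
        counts = []
        for cutoff in (2.0, 4.0, 6.0, 10.0, 20.0):
            g = mf.copy_contact_graph(t.coords[0], t.copy_ids(),
                                      mf.ContactGraphSpec(cutoff, True), box=box)
            counts.append(nx.number_connected_components(g))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestTimeline:
    def test_scripted_merges_recovered(self, agg_system):
        traj, truth = agg_system
        tl = mf.entity_timeline(traj)
        assert tl.entity_count.tolist() == truth.entity_counts
        got = [[sorted(e) for e in p] for p in tl.partitions]
        assert got == truth.partitions
        assert tl.frame_of_single_entity == truth.frame_of_single_entity
        assert tl.time_to_single_entity == truth.time_of_single_entity_ns

    def test_boundary_merge_needs_minimum_image(self, agg_system):
        traj, truth = agg_system
        f = truth.extras["pbc_merge_frames"][0]
        no_pbc = mf.entity_timeline(traj, mf.ContactGraphSpec(use_pbc=False))
        assert no_pbc.entity_count[f] > 1  # split without minimum-image
        assert mf.entity_timeline(traj).entity_count[f] == 1

    def test_never_single_entity_representable(self):
        spec = mf.SyntheticSpec(seed=41, n_copies=4, merge_schedule=[],
                                pbc_merge_frames=(), n_frames=6)
        traj, truth = mf.generate_aggregation_trajectory(spec)
        tl = mf.entity_timeline(traj)
        assert tl.entity_count.tolist() == [4] * 6
        assert tl.time_to_single_entity is None
        assert truth.frame_of_single_entity is None

    def test_counts_within_bounds(self, agg_system):
        traj, _ = agg_system
        tl = mf.entity_timeline(traj)
        assert np.all(tl.entity_count >= 1)
        assert np.all(tl.entity_count <= len(set(traj.copy_ids())))
        for part in tl.partitions:  # true partition: disjoint and covering
            flat = sorted(c for e in part for c in e)
            assert flat == sorted(set(traj.copy_ids()))


class TestEntityLabels:
    def test_constant_without_topology_changes(self):
        spec = mf.SyntheticSpec(seed=42, n_copies=3, merge_schedule=[],
                                pbc_merge_frames=(), n_frames=5)
        traj, _ = mf.generate_aggregation_trajectory(spec)
        labels = mf.entity_track_labels(mf.entity_timeline(traj))
        assert all(lab == labels[0] for lab in labels)

    def test_merge_inherits_larger_predecessor_label(self):
        tl = mf.EntityTimeline(
            frames=np.arange(2),
            partitions=[
                [frozenset({0}), frozenset({1, 2})],
                [frozenset({0, 1, 2})],
            ],
            entity_count=np.array([2, 1]),
        )
        labels = mf.entity_track_labels(tl)
        assert labels[1][0] == labels[0][1]  # {B,C}'s label survives the merge
        assert labels[1][0] != labels[0][0]

    def test_scripted_merge_split_sequence_hand_derived(self):
        tl = mf.EntityTimeline(
            frames=np.arange(4),
            partitions=[
                [frozenset({0}), frozenset({1}), frozenset({2, 3})],
                [frozenset({0, 1}), frozenset({2, 3})],   # 0+1 merge
                [frozenset({0, 1, 2, 3})],                # all merge
                [frozenset({0, 1}), frozenset({2, 3})],   # split again
            ],
            entity_count=np.array([3, 2, 1, 2]),
        )
        labels = mf.entity_track_labels(tl)
        l0 = labels[0]
        assert l0 == {0: 0, 1: 1, 2: 2}
        # merge of {0} and {1}: equal size, tie -> predecessor with lowest copy id
        assert labels[1] == {0: 0, 2: 2}
        # merge of {0,1} and {2,3}: equal size, tie -> lowest copy id ({0,1})
        assert labels[2] == {0: 0}
        # split: the piece keeping most overlap with the old entity keeps label 0,
        # the other gets a fresh label
        assert labels[3][0] == 0
        assert labels[3][2] not in (0,)


def test_agg_system_copies_are_whole_after_unwrapping(agg_system):
    """make_whole reassembles a copy wrapped across the boundary."""
    traj, truth = agg_system
    f = truth.extras["pbc_merge_frames"][0]
    copy_ids = traj.copy_ids()
    sub = traj.coords[f][copy_ids == 0]
    whole = mf.pbc.make_whole(sub, traj.box[f])
    assert np.ptp(whole, axis=0).max() < 10.0  # compact after unwrapping
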