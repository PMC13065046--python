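import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memflux as mf
from conftest import make_toy_trajectory, volume_for

SLAB = mf.MembraneSlab(-17.0, 17.0)


ROD_Z = np.arange(-16.0, 17.0, 2.0)


def path_trajectory(z_path, lateral=(1.0, 0.0)):
    """A rod of protein atoms spanning the slab plus one water following
    z_path; returns (trajectory, water_atom_index)."""
    rod = np.column_stack((np.zeros_like(ROD_Z), np.zeros_like(ROD_Z), ROD_Z))
    frames = []
    for z in z_path:
        frames.append(np.vstack([rod, [lateral[0], lateral[1], z]]))
    widx = len(ROD_Z)
    return make_toy_trajectory(np.array(frames), water={widx}), widx


def events_for(z_path, slab=SLAB, cutoff=6.0):
    t, _ = path_trajectory(z_path)
    vol = mf.ProteinVolume(np.arange(len(ROD_Z)), slab, cutoff)
    occ = mf.occupancy_series(t, vol)
    return mf.extract_events(occ, t, slab), occ


class TestEstimateSlab:
    def test_two_leaflets(self, rng):
        z = np.concatenate([np.full(50, -17.0), np.full(50, 17.0)])
        coords = np.zeros((1, 100, 3))
        coords[0, :, 2] = z
        t = make_toy_trajectory(coords)
        slab = mf.estimate_slab(t, np.arange(100))
        assert slab.z_lower == pytest.approx(-17.0)
        assert slab.z_upper == pytest.approx(17.0)

    def test_trimmed_mean_resists_outlier(self):
        z = np.concatenate([np.full(50, -17.0), np.full(49, 17.0), [30.0]])
        coords = np.zeros((1, 100, 3))
        coords[0, :, 2] = z
        t = make_toy_trajectory(coords)
        slab = mf.estimate_slab(t, np.arange(100), quantile_trim=0.05)
        assert slab.z_upper == pytest.approx(17.0, abs=0.2)

    def test_one_sided_markers_rejected(self):
        coords = np.zeros((1, 10, 3))
        coords[0, :, 2] = 5.0
        t = make_toy_trajectory(coords)
        with pytest.raises(mf.errors.MemfluxError):
            mf.estimate_slab(t, np.arange(10))


class TestOccupancy:
    @pytest.mark.parametrize(
        "water_pos,inside",
        [
            ((3.0, 0.0, 0.0), True),   # in slab, 3 A from protein
            ((8.0, 0.0, 0.0), False),  # in slab but 8 A away
            ((3.0, 0.0, 20.0), False),  # close laterally but above the slab
            ((6.0, 0.0, 17.0), True),  # closed interval boundary, distance == cutoff
        ],
    )
    def test_volume_membership(self, water_pos, inside):
        coords = np.array([[[0.0, 0.0, water_pos[2]], list(water_pos)]])
        t = make_toy_trajectory(coords, water={1})
        vol = mf.ProteinVolume(np.array([0]), SLAB, 6.0)
        occ = mf.occupancy_series(t, vol)
        assert (1 in occ[0]) == inside

    def test_minimum_image_distance_used_when_box_present(self):
        # protein at x=1, water at x=59 in a 60 A box: direct 58, min-image 2
        coords = np.array([[[1.0, 0.0, 0.0], [59.0, 0.0, 0.0]]])
        box = np.array([[60.0, 60.0, 60.0]])
        t_pbc = make_toy_trajectory(coords, box=box, water={1})
        vol = mf.ProteinVolume(np.array([0]), SLAB, 6.0)
        assert 1 in mf.occupancy_series(t_pbc, vol)[0]
        t_nopbc = make_toy_trajectory(coords, water={1})
        assert 1 not in mf.occupancy_series(t_nopbc, vol)[0]

    def test_no_waters_warns(self):
        t = make_toy_trajectory(np.zeros((2, 1, 3)))
        vol = mf.ProteinVolume(np.array([0]), SLAB, 6.0)
        with pytest.warns(UserWarning):
            occ = mf.occupancy_series(t, vol)
        assert occ == [frozenset(), frozenset()]


class TestEvents:
    def test_planted_crossing(self):
        events, _ = events_for([-20, 0, 20])
        assert len(events) == 1
        e = events[0]
        assert (e.entry_side, e.exit_side, e.outcome) == ("lower", "upper", "crossed")

    def test_planted_return(self):
        events, _ = events_for([-20, 0, -20])
        assert [e.outcome for e in events] == ["returned"]

    def test_unresolved_at_final_frame(self):
        events, _ = events_for([-20, 0, 0])
        assert [e.outcome for e in events] == ["unresolved"]
        assert events[0].exit_frame is None

    def test_multiple_events_same_water(self):
        events, _ = events_for([-20, 0, -20, 0, 20])
        assert [e.outcome for e in events] == ["returned", "crossed"]

    def test_min_dwell_smooths_single_frame_excursions(self):
        # single-frame dip inside counts by default, vanishes with min_dwell=2
        t, _ = path_trajectory([-20, 0, -20, 0, 5, -20])
        vol = mf.ProteinVolume(np.arange(len(ROD_Z)), SLAB, 6.0)
        occ = mf.occupancy_series(t, vol)
        default = mf.extract_events(occ, t, SLAB)
        assert len(default) == 2
        smoothed = mf.extract_events(occ, t, SLAB, min_dwell=2)
        assert [e.outcome for e in smoothed] == ["returned"]
        assert smoothed[0].entry_frame == 3

    def test_lateral_exit_attributed_to_nearest_boundary(self):
        # leaves sideways at z = 10: nearer the upper boundary (17) than lower
        t, widx = path_trajectory([-20, 10, 10])
        t.coords[2, widx, 0] = 30.0  # far from the rod, still inside the slab z-range
        vol = mf.ProteinVolume(np.arange(len(ROD_Z)), SLAB, 6.0)
        occ = mf.occupancy_series(t, vol)
        events = mf.extract_events(occ, t, SLAB)
        assert events[0].exit_side == "upper" and events[0].exit_lateral


class TestRate:
    def test_rate_arithmetic(self):
        events = [mf.PermeationEvent(0, 0, "lower", 1, "upper", "crossed")]
        events += [mf.PermeationEvent(i, 0, "lower", 1, "lower", "returned")
                   for i in range(1, 4)]
        s = mf.translocation_rate(events)
        assert s.rate_percent == pytest.approx(25.0)

    def test_all_returned_zero(self):
        events = [mf.PermeationEvent(i, 0, "upper", 1, "upper", "returned")
                  for i in range(5)]
        assert mf.translocation_rate(events).rate == 0.0

    def test_no_resolved_events_sentinel(self):
        events = [mf.PermeationEvent(0, 0, "lower", None, None, "unresolved")]
        s = mf.translocation_rate(events)
        assert s.rate is None and s.n_unresolved == 1

    def test_per_replica_rates(self):
        events = []
        for rep, (c, r) in {"r1": (1, 9), "r2": (9, 21)}.items():
            events += [mf.PermeationEvent(0, 0, "lower", 1, "upper", "crossed", replica=rep)
                       for _ in range(c)]
            events += [mf.PermeationEvent(0, 0, "lower", 1, "lower", "returned", replica=rep)
                       for _ in range(r)]
        s = mf.translocation_rate(events)
        assert s.per_replica == pytest.approx({"r1": 0.1, "r2": 0.3})
        assert s.per_replica_mean == pytest.approx(0.2)
        assert s.rate == pytest.approx(0.25)  # pooled 10/40


class TestInvariants:
    def test_event_conservation_on_synthetic_system(self, perm_system):
        traj, truth = perm_system
        vol = volume_for(traj, truth)
        occ = mf.occupancy_series(traj, vol)
        events = mf.extract_events(occ, traj, vol.slab)
        s = mf.translocation_rate(events)
        assert s.n_entries == s.n_crossed + s.n_returned + s.n_unresolved
        assert s.n_crossed == truth.n_crossed
        assert s.n_returned == truth.n_returned
        assert s.n_unresolved == truth.n_unresolved
        assert s.rate == pytest.approx(truth.crossing_rate)

    def test_time_reversal_preserves_crossed_count(self):
        z_path = [-20, -5, 5, 20, 20, 0, 20, -20, -10, 0, -20]
        events_fwd, _ = events_for(z_path)
        events_rev, _ = events_for(z_path[::-1])
        crossed_fwd = sum(e.outcome == "crossed" for e in events_fwd)
        crossed_rev = sum(e.outcome == "crossed" for e in events_rev)
        assert crossed_fwd == crossed_rev
        for ef, er in zip(events_fwd, reversed(events_rev)):
            if ef.outcome == "crossed":
                assert (ef.entry_side, ef.exit_side) == (er.exit_side, er.entry_side)

    @given(st.lists(st.sampled_from(["crossed", "returned", "unresolved"]),
                    min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rate_bounded_whenever_defined(self, outcomes):
        events = [
            mf.PermeationEvent(i, 0, "lower",
                               None if o == "unresolved" else 1,
                               None if o == "unresolved" else
                               ("upper" if o == "crossed" else "lower"), o)
            for i, o in enumerate(outcomes)
        ]
        s = mf.translocation_rate(events)
        if s.rate is not None:
            assert 0.0 <= s.rate <= 1.0
        assert s.n_entries == len(outcomes)
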