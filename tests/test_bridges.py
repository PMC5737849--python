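import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from hydration import bridges as br
from hydration import hbonds as hb
from hydration import structures as st
from hydration import synth


def series(ids, dt=100.0):
    return br.BridgeStateSeries(occupant=np.array(ids), dt_ps=dt)


W1, W2, W3, NO = 10, 20, 30, br.NO_WATER


class TestBridgeStatistics:
    def test_worked_example(self):
        s = series([W1, W1, W1, NO, W2, W2], dt=100.0)
        stats = br.bridge_statistics(s)
        assert stats.occupancy_percent == pytest.approx(5 / 6 * 100)
        assert stats.n_events == 2
        assert stats.max_binding_ns == pytest.approx(0.3)
        assert stats.mean_binding_ns == pytest.approx(0.25)
        assert stats.exchange_count == 0

    def test_gap_to_different_water_never_bridged(self):
        s = series([W1, W1, W1, NO, W2, W2], dt=100.0)
        stats = br.bridge_statistics(s, gap_tolerance_ps=150.0)
        assert stats.n_events == 2

    def test_same_water_gap_absorbed(self):
        s = series([W1, W1, NO, W1, W1], dt=100.0)
        strict = br.bridge_statistics(s)
        assert strict.n_events == 2 and strict.max_binding_ns == pytest.approx(0.2)
        tol = br.bridge_statistics(s, gap_tolerance_ps=150.0)
        assert tol.n_events == 1
        assert tol.max_binding_ns == pytest.approx(0.5)  # span incl. gap

    def test_interleaved_occupant_counts_as_interruption(self):
        s = series([W1, W2, W1], dt=100.0)
        assert br.bridge_statistics(s).n_events == 3
        merged = br.bridge_statistics(s, gap_tolerance_ps=150.0)
        # W2's one-frame visit is absorbed into W1's event and does not
        # spawn an event of its own (n_events is non-increasing in tolerance)
        assert merged.n_events == 1
        assert merged.max_binding_ns == pytest.approx(0.3)
        assert s.occupant.tolist() == [W1, W2, W1]  # input untouched

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            br.bridge_statistics(series([W1]), gap_tolerance_ps=-1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 10_000))
    def test_max_binding_nondecreasing_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        ids = rng.choice([NO, W1, W2, W3], size=60)
        s = series(ids, dt=10.0)
        maxima = [br.bridge_statistics(s, gap_tolerance_ps=tol).max_binding_ns
                  for tol in (0.0, 15.0, 35.0, 105.0)]
        assert maxima == sorted(maxima)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 10_000))
    def test_occupancy_definitional_consistency(self, seed):
        rng = np.random.default_rng(seed)
        ids = rng.choice([NO, W1, W2], size=50)
        s = series(ids, dt=10.0)
        stats = br.bridge_statistics(s)
        assert stats.occupancy_percent == pytest.approx(
            np.mean(ids != NO) * 100)


class TestBridgeStateSeries:
    def test_planted_bridge_recovered_exactly(self, planted_trajectory):
        traj, truth, site = planted_trajectory
        s = br.bridge_state_series(traj, site)
        np.testing.assert_array_equal(s.occupant, truth.occupant_series[0])

    def test_two_half_bridges_are_not_fully_formed(self):
        # two waters, each H-bonded to only one of the two site atoms
        atoms = [
            st.Atom(1, "O", "O", "GLY", 1, "A", np.array([0.0, 0.0, 0.0])),
            st.Atom(2, "O", "O", "GLY", 2, "A", np.array([8.0, 0.0, 0.0])),
            st.Atom(3, "O", "O", "HOH", 10, "W", np.array([2.8, 0.0, 0.0])),
            st.Atom(4, "H1", "H", "HOH", 10, "W", np.array([1.9, 0.0, 0.0])),
            st.Atom(5, "H2", "H", "HOH", 10, "W", np.array([3.2, 0.9, 0.0])),
            st.Atom(6, "O", "O", "HOH", 11, "W", np.array([5.2, 0.0, 0.0])),
            st.Atom(7, "H1", "H", "HOH", 11, "W", np.array([6.1, 0.0, 0.0])),
            st.Atom(8, "H2", "H", "HOH", 11, "W", np.array([4.8, 0.9, 0.0])),
        ]
        topo = st.StructureModel(atoms=atoms)
        traj = st.Trajectory(topology=topo, coords=topo.coords()[None], dt_ps=10.0)
        s = br.bridge_state_series(traj, br.BridgeDefinition((0, 1)))
        assert s.occupant[0] == br.NO_WATER
        # but each half is individually bonded
        bonds, _ = br.water_solute_bond_matrix(traj, np.array([2, 5]),
                                               np.array([0, 1]))
        assert bonds[0, 0, 0] and bonds[0, 1, 1]

    def test_site_containing_water_rejected(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        w = traj.topology.water_oxygen_indices()[0]
        with pytest.raises(ValueError):
            br.bridge_state_series(traj, br.BridgeDefinition((int(w),)))

    def test_dwell_time_distribution_is_exponential(self, bridge_pair):
        """Empirical dwell distribution vs Exp(τ): one-sided KS at α = 0.01."""
        from scipy import stats as sps
        model, i, j = bridge_pair
        tau_ps = 150.0
        plan = synth.BridgePlan(site_atoms=(i, j), mean_dwell_ps=tau_ps,
                                target_occupancy=0.85)
        traj, _ = synth.simulate_bridge_trajectory(
            model, [plan], n_frames=6000, dt_ps=10.0, n_bulk_waters=0,
            box=45.0, seed=7)
        s = br.bridge_state_series(traj, br.BridgeDefinition((i, j)))
        dwells = br.event_lengths(s) * 1000.0  # ps
        assert len(dwells) >= 200
        res = sps.kstest(dwells, "expon", args=(0, tau_ps))
        assert res.pvalue > 0.01


class TestDiscoverBridges:
    def test_bulk_only_is_empty(self, toy_system):
        traj, _ = synth.simulate_bridge_trajectory(
            toy_system, [], n_frames=60, dt_ps=10.0, n_bulk_waters=15,
            box=45.0, seed=2)
        assert br.discover_bridges(traj, min_occupancy_percent=10.0) == []

    def test_planted_pair_recovered_with_occupancy(self, bridge_pair):
        model, i, j = bridge_pair
        plan = synth.BridgePlan(site_atoms=(i, j), mean_dwell_ps=100.0,
                                target_occupancy=0.6)
        traj, truth = synth.simulate_bridge_trajectory(
            model, [plan], n_frames=2000, dt_ps=10.0, n_bulk_waters=0,
            box=45.0, seed=4)
        found = br.discover_bridges(traj, min_occupancy_percent=30.0)
        assert [bd.site_atoms for bd, _ in found] == [(i, j)]
        truth_occ = np.mean(truth.occupant_series[0] != br.NO_WATER) * 100
        assert found[0][1].occupancy_percent == pytest.approx(truth_occ, abs=2.0)

    def test_matches_brute_force_triple_loop(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        small = st.Trajectory(topology=traj.topology,
                              coords=traj.coords[:50], dt_ps=traj.dt_ps)
        table = hb.classify_polar_atoms(small.topology)
        crit = hb.HBondCriterion()
        waters = small.topology.water_oxygen_indices()
        solute = br._polar_solute_atoms(small.topology, table)

        def bonded(f, w, s):
            ok_wd = ok_sd = False
            if s in set(table.acceptors):
                hyd = [small.coords[f, h] for h in table.donors[int(w)]]
                ok_wd, _, _ = hb.hbond_present(small.coords[f, w], hyd,
                                               small.coords[f, s], crit)
            if int(s) in table.donors and table.donors[int(s)]:
                hyd = [small.coords[f, h] for h in table.donors[int(s)]]
                ok_sd, _, _ = hb.hbond_present(small.coords[f, s], hyd,
                                               small.coords[f, w], crit)
            return ok_wd or ok_sd

        expected = {}
        for ai, aj in itertools.combinations(range(len(solute)), 2):
            hits = 0
            for f in range(small.n_frames):
                if any(bonded(f, w, solute[ai]) and bonded(f, w, solute[aj])
                       for w in waters):
                    hits += 1
            occ = hits / small.n_frames * 100
            if occ >= 10.0:
                expected[(int(solute[ai]), int(solute[aj]))] = occ

        found = br.discover_bridges(small, min_occupancy_percent=10.0)
        got = {bd.site_atoms: s.occupancy_percent for bd, s in found}
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_threshold_subset_property(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        low = {bd.site_atoms for bd, _ in
               br.discover_bridges(traj, min_occupancy_percent=10.0)}
        high = {bd.site_atoms for bd, _ in
                br.discover_bridges(traj, min_occupancy_percent=40.0)}
        assert high <= low


class TestClassifyWaters:
    def test_three_groups(self, planted_trajectory):
        traj, truth, site = planted_trajectory
        labels = br.classify_waters(traj)
        w_idx = {int(w): k for k, w in enumerate(labels.water_oxygens)}
        occ = truth.occupant_series[0]
        truth_occ_frac = np.mean(occ != br.NO_WATER)
        # the planted water column is labelled bridging whenever it occupies
        bridging_frac = 0.0
        for f in range(traj.n_frames):
            if occ[f] != br.NO_WATER:
                bridging_frac += labels.labels[f, w_idx[occ[f]]] == 2
        bridging_frac /= traj.n_frames
        assert bridging_frac >= truth_occ_frac - 1e-9

    def test_far_water_is_bulk_and_single_contact_is_shell(self):
        atoms = [
            st.Atom(1, "O", "O", "GLY", 1, "A", np.zeros(3)),
            st.Atom(2, "O", "O", "HOH", 10, "W", np.array([2.8, 0.0, 0.0])),
            st.Atom(3, "H1", "H", "HOH", 10, "W", np.array([1.9, 0.0, 0.0])),
            st.Atom(4, "H2", "H", "HOH", 10, "W", np.array([3.2, 0.9, 0.0])),
            st.Atom(5, "O", "O", "HOH", 11, "W", np.array([10.0, 0.0, 0.0])),
            st.Atom(6, "H1", "H", "HOH", 11, "W", np.array([10.96, 0.0, 0.0])),
            st.Atom(7, "H2", "H", "HOH", 11, "W", np.array([9.7, 0.9, 0.0])),
        ]
        topo = st.StructureModel(atoms=atoms)
        traj = st.Trajectory(topology=topo, coords=topo.coords()[None], dt_ps=1.0)
        labels = br.classify_waters(traj)
        assert labels.labels[0].tolist() == [1, 0]  # shell, bulk


class TestSaltBridge:
    def _traj_with_schedule(self):
        """Arg NH1 vs Asp OD1: alternating direct / water-mediated frames."""
        base = [
            st.Atom(1, "NH1", "N", "ARG", 1, "A", np.array([0.0, 0.0, 0.0])),
            st.Atom(2, "HH11", "H", "ARG", 1, "A", np.array([0.98, 0.0, 0.0])),
            st.Atom(3, "OD1", "O", "ASP", 2, "A", np.array([2.9, 0.0, 0.0])),
            st.Atom(4, "O", "O", "HOH", 10, "W", np.array([0.0, 30.0, 0.0])),
            st.Atom(5, "H1", "H", "HOH", 10, "W", np.array([0.96, 30.0, 0.0])),
            st.Atom(6, "H2", "H", "HOH", 10, "W", np.array([-0.7, 30.7, 0.0])),
        ]
        topo = st.StructureModel(atoms=base)
        x0 = topo.coords()
        frames = []
        for f in range(8):
            x = x0.copy()
            if f % 2 == 1:  # pull the pair apart, park the water between
                x[2] = [5.6, 0.0, 0.0]
                x[3] = [2.8, 0.0, 0.0]    # water O: 2.8 from both N and OD1
                x[4] = [3.76, 0.0, 0.0]   # H1 toward OD1
                x[5] = [2.1, 0.7, 0.0]
            frames.append(x)
        return st.Trajectory(topology=topo, coords=np.array(frames), dt_ps=10.0)

    def test_direct_and_mediated_schedule_exact(self):
        traj = self._traj_with_schedule()
        states, pops = br.saltbridge_states(traj, cation_atoms=[0],
                                            anion_atoms=[2])
        assert states.tolist() == ["direct", "water_mediated"] * 4
        assert pops["direct"] == pytest.approx(50.0)
        assert pops["water_mediated"] == pytest.approx(50.0)
        assert sum(pops.values()) == pytest.approx(100.0)

    def test_overlapping_sets_rejected(self):
        traj = self._traj_with_schedule()
        with pytest.raises(ValueError):
            br.saltbridge_states(traj, cation_atoms=[0], anion_atoms=[0, 2])


class TestHydrationProfile:
    def test_profile_bounds_and_pinned_water(self, planted_trajectory):
        traj, truth, site = planted_trajectory
        prof = br.per_atom_hydration_profile(traj)
        assert ((prof.pct_frames_hbonded >= 0)
                & (prof.pct_frames_hbonded <= 100)).all()
        # mean count >= pct/100 by construction
        assert (prof.mean_hbond_count >= prof.pct_frames_hbonded / 100 - 1e-12).all()
        # site atoms are hydrated whenever the bridge is formed
        occ_pct = np.mean(truth.occupant_series[0] != br.NO_WATER) * 100
        by_idx = prof.set_index("atom_index")
        for a in site.site_atoms:
            assert by_idx.loc[a, "pct_frames_hbonded"] >= occ_pct - 1e-9
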