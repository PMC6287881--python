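"""Trajectory simulation, kinetic summaries and dose-response behaviour."""

import numpy as np
import pytest

from ifnkin.network import build_network
from ifnkin.simulate import (StimulusCondition, Trajectory,
                             apply_overexpression, kinetic_summary,
                             max_induction_ratio, simulate)

GRID = [3.0, 6.0, 12.0, 24.0]


class TestStimulusCondition:
    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            StimulusCondition("I", -0.1)

    def test_unknown_ifn_rejected(self):
        with pytest.raises(ValueError):
            StimulusCondition("II", 1.0)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            StimulusCondition("I", 1.0, factor_I=0.0)


class TestSimulate:
    def test_zero_dose_keeps_fold_change_at_one(self, network, params):
        traj = simulate(network, params, StimulusCondition("I", 0.0),
                        np.linspace(0, 24, 25))
        assert np.allclose(traj.fold_change, 1.0, atol=1e-7)

    def test_time_grid_must_increase(self, network, params):
        with pytest.raises(ValueError):
            Trajectory([3, 3, 6], np.zeros((3, network.n_species)),
                       network.species, StimulusCondition("I", 1.0))

    def test_peak_monotone_in_dose(self, network, params, dense_times):
        doses = [0.01, 0.033, 0.1, 0.33, 1.0]
        peaks = []
        for ifn in ("I", "III"):
            peaks = [kinetic_summary(simulate(
                network, params, StimulusCondition(ifn, d), dense_times)
            )["peak_fold_change"] for d in doses]
            assert np.all(np.diff(peaks) > 0)

    def test_bitwise_deterministic(self, network, params):
        c = StimulusCondition("III", 13.7)
        a = simulate(network, params, c, GRID).fold_change
        b = simulate(network, params, c, GRID).fold_change
        assert np.array_equal(a, b)

    def test_high_affinity_raises_magnitude_at_subsaturating_dose(
            self, network, params, dense_times):
        lo = kinetic_summary(simulate(network, params,
                                      StimulusCondition("III", 0.05),
                                      dense_times))
        ha = kinetic_summary(simulate(network, params,
                                      StimulusCondition("III-HA", 0.05),
                                      dense_times))
        assert ha["peak_fold_change"] > lo["peak_fold_change"]


class TestKineticSummary:
    def test_peak_is_argmax_on_grid(self, network, params):
        traj = Trajectory([0, 3, 6, 12], np.zeros((4, network.n_species)),
                          network.species, StimulusCondition("I", 1.0))
        traj.states["ISG_FC"] = [1.0, 4.0, 9.0, 5.0]
        s = kinetic_summary(traj)
        assert s["peak_time"] == 6.0
        assert s["peak_fold_change"] == 9.0

    def test_monotone_series_peaks_at_last_point(self, network, params):
        traj = Trajectory(GRID, np.zeros((4, network.n_species)),
                          network.species, StimulusCondition("I", 1.0))
        traj.states["ISG_FC"] = [1.0, 2.0, 3.0, 4.0]
        assert kinetic_summary(traj)["peak_time"] == 24.0

    def test_tied_maxima_break_toward_earliest(self, network, params):
        traj = Trajectory(GRID, np.zeros((4, network.n_species)),
                          network.species, StimulusCondition("I", 1.0))
        traj.states["ISG_FC"] = [9.0, 9.0, 2.0, 1.0]
        assert kinetic_summary(traj)["peak_time"] == 3.0

    def test_flat_series_is_flagged(self, network, params):
        traj = Trajectory(GRID, np.zeros((4, network.n_species)),
                          network.species, StimulusCondition("I", 0.0))
        traj.states["ISG_FC"] = [1.0, 1.0, 1.0, 1.0]
        assert kinetic_summary(traj)["flat"]


class TestOverexpression:
    def test_identity_factors_leave_state_unchanged(self, network, params):
        ss = network.steady_state(params)
        p2, s2 = apply_overexpression(params, ss, 1.0, 1.0)
        assert np.array_equal(ss.array, s2.array)
        assert p2.to_dict() == params.to_dict()

    def test_factors_scale_only_receptor_pools(self, network, params):
        ss = network.steady_state(params)
        p2, s2 = apply_overexpression(params, ss, 2.6, 1.5)
        assert s2["R_I"] == pytest.approx(2.6 * ss["R_I"])
        assert s2["R_III"] == pytest.approx(1.5 * ss["R_III"])
        assert s2["STAT"] == ss["STAT"]
        assert s2["ISG_FC"] == ss["ISG_FC"]
        assert p2.r_tot_I == pytest.approx(2.6 * params.r_tot_I)

    def test_nonpositive_factor_rejected(self, network, params):
        ss = network.steady_state(params)
        with pytest.raises(ValueError):
            apply_overexpression(params, ss, -2.0, 1.0)

    def test_ifnar_scaling_leaves_type_iii_arm_unchanged(self, params):
        """With duplicated STAT pools the pathways share no species, so
        IFNAR overexpression cannot touch type III responses."""
        net = build_network("M3", stat_shared=False)
        base = simulate(net, params, StimulusCondition("III", 13.7), GRID)
        ox = simulate(net, params,
                      StimulusCondition("III", 13.7, factor_I=3.0), GRID)
        assert np.allclose(base.fold_change, ox.fold_change, rtol=1e-9)

    def test_overexpression_raises_amplitude_peak_time_stable(
            self, network, params):
        """Receptor overexpression up to 3x strictly increases the peak ISG
        amplitude while the peak stays within one position on the
        experimental grid."""
        for ifn, dose, key in (("I", 0.1, "factor_I"),
                               ("III", 13.7, "factor_III")):
            peaks, times_ = [], []
            for f in (1.0, 2.0, 3.0):
                cond = StimulusCondition(ifn, dose, **{key: f})
                s = kinetic_summary(simulate(network, params, cond, GRID))
                peaks.append(s["peak_fold_change"])
                times_.append(GRID.index(s["peak_time"]))
            assert peaks[0] < peaks[1] < peaks[2]
            assert max(times_) - min(times_) <= 1


class TestMaxInductionRatio:
    def test_symmetric_pathways_give_unit_ratio(self, params, dense_times):
        net = build_network("M1")
        sym = params.symmetric().updated({"r_tot_III": params.r_tot_I})
        for dose in (0.05, 1.0):
            assert max_induction_ratio(net, sym, dose,
                                       times=dense_times) == pytest.approx(
                                           1.0, rel=1e-6)

    def test_ratio_decreases_toward_one_at_low_dose(self, network, params):
        doses = np.geomspace(0.0137, 13.7, 8)
        ratios = np.array([max_induction_ratio(network, params, d)
                           for d in doses])
        # monotone non-decreasing in dose (1% numerical slack)
        assert np.all(np.diff(ratios) >= -0.01 * ratios[:-1])
        assert ratios[-1] > ratios[0]
        assert ratios[0] == pytest.approx(1.0, abs=0.05)

    def test_saturated_ratio_insensitive_to_dose_doubling(self, network,
                                                          params):
        r1 = max_induction_ratio(network, params, 10.0)
        r2 = max_induction_ratio(network, params, 20.0)
        assert r2 == pytest.approx(r1, rel=0.01)

    def test_nonpositive_dose_rejected(self, network, params):
        with pytest.raises(ValueError):
            max_induction_ratio(network, params, 0.0)


class TestKineticOrdering:
    def test_slow_inactivation_delays_and_sustains_type_iii(self, params,
                                                            dense_times):
        """With the type III inactivation rate at one tenth of type I and
        everything else equal, the type III response peaks later and is
        more sustained at 24 h."""
        net = build_network("M3")
        p = params.symmetric().updated(
            {"r_tot_III": params.r_tot_I,
             "k_inact_III": params.k_inact_I / 10.0})
        sI = kinetic_summary(simulate(net, p, StimulusCondition("I", 0.33),
                                      dense_times))
        sIII = kinetic_summary(simulate(net, p,
                                        StimulusCondition("III", 0.33),
                                        dense_times))
        assert sIII["peak_time"] > sI["peak_time"]
        assert (sIII["normalized_profile"][-1]
                > sI["normalized_profile"][-1])


class TestNumericalConsistency:
    def test_tolerance_refinement_changes_little(self, network, params):
        c = StimulusCondition("I", 0.33)
        coarse = simulate(network, params, c, GRID, rtol=1e-8,
                          atol=1e-10).fold_change
        fine = simulate(network, params, c, GRID, rtol=5e-9,
                        atol=5e-11).fold_change
        assert np.max(np.abs(fine - coarse) / coarse) < 1e-4

    def test_trajectory_export_is_tidy(self, network, params):
        traj = simulate(network, params, StimulusCondition("I", 0.33), GRID)
        frame = traj.to_frame()
        assert set(frame.columns) == {"condition_id", "ifn_type", "dose_nM",
                                      "time_h", "species", "value"}
        assert len(frame) == len(GRID) * network.n_species
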