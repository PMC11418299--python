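"""Generator contracts: recovery kinetics, trace construction, cohorts and
thermal trials."""

import numpy as np
import pytest

from aquamet import (
    FishRecord,
    RespirometryProtocol,
    default_cohort_config,
    serialize_cohort,
    simulate_cohort,
    simulate_recovery_mdot,
    simulate_thermal_trial,
    simulate_trace,
    zero_noise_config,
)
from aquamet.records import PHASE_FLUSH, PHASE_MEASURE
from aquamet.synthetic import ThermalTrialTruth, TraceTruth
from aquamet.traces import fit_cycle_slope, segment_cycles


class TestRecoveryKinetics:
    def test_boundary_values(self, truth):
        assert simulate_recovery_mdot(truth, 0.0) == pytest.approx(truth.mmr_true)
        assert simulate_recovery_mdot(truth, 1e9) == pytest.approx(truth.rmr_true)

    def test_hand_evaluated_point(self):
        tr = TraceTruth(rmr_true=3.0, mmr_true=11.0, k_recovery=0.05)
        # 3 + 8 e^{-1}
        assert simulate_recovery_mdot(tr, 20.0) == pytest.approx(3 + 8 * np.exp(-1), rel=1e-12)

    def test_monotone_non_increasing(self, truth):
        t = np.linspace(0, 600, 500)
        y = simulate_recovery_mdot(truth, t)
        assert np.all(np.diff(y) <= 0)

    def test_negative_time_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_recovery_mdot(truth, -1.0)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            TraceTruth(rmr_true=5.0, mmr_true=4.0)
        with pytest.raises(ValueError):
            TraceTruth(rmr_true=2.0, mmr_true=8.0, k_recovery=-0.1)


class TestTraceSimulation:
    def test_deterministic_for_fixed_seed(self, fish, truth, short_protocol):
        a = simulate_trace(fish, truth, short_protocol, seed=7)
        b = simulate_trace(fish, truth, short_protocol, seed=7)
        assert np.array_equal(a.o2, b.o2)
        assert np.array_equal(a.time, b.time)

    def test_different_seeds_differ(self, fish, truth, short_protocol):
        a = simulate_trace(fish, truth, short_protocol, seed=1)
        b = simulate_trace(fish, truth, short_protocol, seed=2)
        assert not np.array_equal(a.o2, b.o2)

    def test_noiseless_slope_inverts_to_programmed_consumption(
        self, fish, clean_truth, short_protocol
    ):
        """The OLS slope of every sealed phase equals -mdot*m/(v_R-v_F)."""
        from aquamet.traces import mdot_from_slope

        trace, tdf = simulate_trace(
            fish, clean_truth, short_protocol, seed=0, return_truth=True
        )
        slices = segment_cycles(trace, short_protocol)
        assert len(slices) == len(tdf)
        for (t, y), row in zip(slices, tdf.itertuples()):
            slope, r2 = fit_cycle_slope(t, y)
            assert r2 == pytest.approx(1.0, abs=1e-9)
            assert mdot_from_slope(slope, fish) == pytest.approx(
                row.mdot_programmed, rel=1e-9
            )

    def test_first_cycle_steepest(self, fish, short_protocol):
        """Monotone recovery implies the post-chase slope beats any overnight
        cycle slope (brute force over all fitted cycles)."""
        tr = TraceTruth(rmr_true=3.0, mmr_true=11.0, k_recovery=0.05)
        trace = simulate_trace(fish, tr, short_protocol, seed=3)
        slopes = [fit_cycle_slope(t, y)[0] for t, y in segment_cycles(trace, short_protocol)]
        assert slopes[0] == min(slopes)

    def test_phase_bookkeeping(self, fish, truth, short_protocol):
        """Flush+measure blocks tile the record: contiguous, alternating,
        no gaps at the 1 Hz grid."""
        trace = simulate_trace(fish, truth, short_protocol, seed=5)
        assert np.all(np.diff(trace.time) == 1.0)
        blocks = []
        for i, p in enumerate(trace.phase):
            if i == 0 or p != trace.phase[i - 1]:
                blocks.append([p, 0])
            blocks[-1][1] += 1
        kinds = [b[0] for b in blocks]
        assert kinds[0] == PHASE_MEASURE
        assert all(k == PHASE_FLUSH for k in kinds[1::2])
        assert all(k == PHASE_MEASURE for k in kinds[2::2])
        assert len(kinds) == 1 + 2 * short_protocol.n_cycles
        # durations match the protocol
        assert blocks[0][1] == short_protocol.first_measure_length * 60
        assert blocks[1][1] == short_protocol.flush_length * 60
        assert blocks[2][1] == short_protocol.measure_length * 60

    def test_programmed_o2_respects_saturation_floor(self, fish, short_protocol):
        tr = TraceTruth(rmr_true=3.0, mmr_true=30.0, noise_sd=0.0, activity_cv=0.0)
        trace, tdf = simulate_trace(fish, tr, short_protocol, seed=0, return_truth=True)
        assert trace.o2.min() >= short_protocol.floor_mg_l - 1e-9
        assert tdf.clamped.iloc[0]  # a 30 mg/kg/min fish must hit the floor

    def test_invalid_geometry_rejected(self, truth, short_protocol):
        with pytest.raises(ValueError, match="geometry"):
            FishRecord(
                fish_id="bad", sex="male", treatment="sham",
                body_mass=60.0, respirometer_volume=54.5,
            )

    def test_noise_scaling_monotone(self, fish, short_protocol):
        """Across-seed sd of the first-cycle slope estimate grows with the
        sensor noise level."""
        sds = []
        for noise in (0.002, 0.01, 0.05):
            tr = TraceTruth(rmr_true=3.0, mmr_true=11.0, noise_sd=noise, activity_cv=0.0)
            slopes = []
            for seed in range(12):
                trace = simulate_trace(fish, tr, short_protocol, seed=seed)
                t, y = segment_cycles(trace, short_protocol)[0]
                slopes.append(fit_cycle_slope(t, y)[0])
            sds.append(np.std(slopes))
        assert sds[0] < sds[1] < sds[2]


class TestThermalTrials:
    def test_linear_inversion_by_hand(self):
        trial = simulate_thermal_trial(
            ThermalTrialTruth(ctmax_true=26.8, start_temp=12.0, ramp_rate=0.1)
        )
        assert trial.t_loe == pytest.approx(148.0)

    def test_one_step_ramp(self):
        trial = simulate_thermal_trial(
            ThermalTrialTruth(ctmax_true=12.1, start_temp=12.0, ramp_rate=0.1)
        )
        assert trial.t_loe == pytest.approx(1.0)

    def test_round_trip_identity(self):
        from aquamet import ctmax_from_ramp

        for ct in (18.0, 25.8, 26.9):
            trial = simulate_thermal_trial(ThermalTrialTruth(ctmax_true=ct))
            assert ctmax_from_ramp(trial) == pytest.approx(ct, abs=1e-9)


class TestCohorts:
    def test_degenerate_noise_recovers_cell_means(self, short_protocol):
        cfg = zero_noise_config(default_cohort_config(seed=1, n_per_cell=1))
        cfg.protocol = short_protocol
        cohort = simulate_cohort(cfg, include_traces=False)
        for (treat, sex), cell in cfg.group_effects.items():
            t = [cohort.truths[f.fish_id] for f in cohort.fish
                 if f.treatment == treat and f.sex == sex][0]
            assert t.rmr_true == pytest.approx(cell.rmr)
            assert t.mmr_true == pytest.approx(cell.mmr)
        for row in cohort.blood.itertuples():
            expected = cfg.blood_means[("pvo2", row.treatment, row.sex, row.time_point)]
            assert row.pvo2 == pytest.approx(expected)
        ct = cohort.thermal_frame.merge(cohort.fish_frame, on="fish_id")
        for row in ct.itertuples():
            assert row.ctmax == pytest.approx(cfg.ctmax_means[row.treatment])

    def test_seeding_contract(self, short_protocol):
        cfg1 = default_cohort_config(seed=1, n_per_cell=3)
        cfg1.protocol = short_protocol
        cfg2 = default_cohort_config(seed=2, n_per_cell=3)
        cfg2.protocol = short_protocol
        a = simulate_cohort(cfg1, include_traces=False)
        b = simulate_cohort(cfg2, include_traces=False)
        assert not np.array_equal(a.blood["pvo2"], b.blood["pvo2"])
        # same expectations: group means within a few sd of each other
        ga = a.blood.groupby("treatment")["pvo2"].mean()
        gb = b.blood.groupby("treatment")["pvo2"].mean()
        assert np.allclose(ga, gb, atol=5.0)

    def test_byte_identical_serialization(self, short_protocol):
        cfg = default_cohort_config(seed=9, n_per_cell=1)
        cfg.protocol = short_protocol
        x = serialize_cohort(simulate_cohort(cfg))
        y = serialize_cohort(simulate_cohort(cfg))
        assert x == y

    def test_missing_cell_rejected(self):
        cfg = default_cohort_config(seed=0)
        ge = dict(cfg.group_effects)
        del ge[("sham", "male")]
        with pytest.raises(ValueError, match="missing CellTruth"):
            from dataclasses import replace

            replace(cfg, group_effects=ge)
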