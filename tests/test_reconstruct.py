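import warnings

import numpy as np
import pandas as pd
import pytest

from kmrecon.errors import ConsistencyError, ReconstructionWarning
from kmrecon.reconstruct import (
    EntryState,
    bin_censor_counts,
    derive_ipd,
    fit_interval,
    initial_censor_guess,
    match_total_events,
    place_censor_times,
    process_last_interval,
    propagate_interval,
    reconstruct,
    round_half_even,
)
from kmrecon.synthetic import (
    CensorDist,
    EventDist,
    TrialSpec,
    exact_digitize,
    make_risk_table,
    pick_risk_times,
    simulate_trial,
)
from kmrecon.types import (
    DigitizedCurve,
    InfoLevel,
    ReconstructionInput,
    RiskTable,
)


class TestInitialCensorGuess:
    def test_example_first_interval(self):
        # round(0.608 * 213) = 130 at-risk under no censoring; 130 - 122 = 8
        assert initial_censor_guess(213, 0.608, 1.0, 122) == 8

    def test_drop_fully_explains_risk_change(self):
        assert initial_censor_guess(100, 0.5, 1.0, 50) == 0

    def test_negative_raw_value_clamped(self):
        with pytest.warns(ReconstructionWarning, match="floored at 0"):
            assert initial_censor_guess(100, 0.9, 1.0, 95) == 0

    def test_degenerate_curve(self):
        with pytest.raises(ConsistencyError, match="degenerate"):
            initial_censor_guess(100, 0.0, 0.0, 50)


class TestPlaceCensorTimes:
    @pytest.mark.parametrize(
        "ncensor, t_lo, t_hi, expected",
        [
            (1, 0.0, 10.0, [5.0]),
            (3, 0.0, 10.0, [2.5, 5.0, 7.5]),
            (8, 0.0, 10.0, [10 * c / 9 for c in range(1, 9)]),
            (0, 0.0, 10.0, []),
        ],
    )
    def test_even_spacing(self, ncensor, t_lo, t_hi, expected):
        np.testing.assert_allclose(
            place_censor_times(ncensor, t_lo, t_hi), expected
        )

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty interval"):
            place_censor_times(2, 5.0, 5.0)

    def test_zero_count_on_empty_interval_allowed(self):
        assert place_censor_times(0, 5.0, 5.0).size == 0


class TestBinCensorCounts:
    def test_midpoint(self):
        curve = DigitizedCurve("a", [0, 4, 6, 10], [1, 0.9, 0.8, 0.7])
        np.testing.assert_array_equal(
            bin_censor_counts([5.0], curve, 1, 3), [0, 1, 0]
        )

    def test_half_open_boundary(self):
        # a censor time exactly on a shared coordinate goes to the later bin
        curve = DigitizedCurve("a", [0, 5, 10, 10], [1, 0.9, 0.8, 0.8])
        np.testing.assert_array_equal(
            bin_censor_counts([2.5, 5.0, 7.5], curve, 1, 2), [1, 2]
        )

    def test_empty_times(self):
        curve = DigitizedCurve("a", [0, 5, 10], [1, 0.9, 0.8])
        np.testing.assert_array_equal(bin_censor_counts([], curve, 1, 2), [0, 0])

    def test_conservation(self, rng):
        curve = DigitizedCurve("a", [0, 1, 3, 7, 9, 12], [1, 0.9, 0.8, 0.7, 0.6, 0.5])
        times = place_censor_times(17, 0.0, 12.0)
        counts = bin_censor_counts(times, curve, 1, 5)
        assert counts.sum() == 17


class TestPropagateInterval:
    def test_example_first_rows(self, example_curve):
        # events implied by drops 1 -> 0.994 -> 0.989 with 213 at risk
        sl = propagate_interval(
            example_curve, 1, 3, EntryState(n_entry=213), np.zeros(3, dtype=int)
        )
        np.testing.assert_array_equal(sl.d, [0, 1, 1])
        np.testing.assert_array_equal(sl.n[:3], [213, 213, 212])
        np.testing.assert_allclose(sl.s_km[1], 212 / 213)

    def test_flat_segment_no_events(self):
        curve = DigitizedCurve("a", [0, 1, 2, 3], [1, 1, 1, 1])
        sl = propagate_interval(curve, 1, 4, EntryState(n_entry=10),
                                np.array([0, 2, 1, 0]))
        assert sl.d.sum() == 0
        np.testing.assert_array_equal(sl.n, [10, 10, 8, 7, 7])

    def test_exact_inverse_step(self):
        # S dropping to exactly (n-1)/n yields exactly one event
        curve = DigitizedCurve("a", [0.0, 1.0], [1.0, 9 / 10])
        sl = propagate_interval(curve, 1, 2, EntryState(n_entry=10),
                                np.zeros(2, dtype=int))
        np.testing.assert_array_equal(sl.d, [0, 1])

    def test_exhausted_risk_set_warns(self):
        curve = DigitizedCurve("a", [0, 1, 2, 3], [1, 0.4, 0.2, 0.1])
        with pytest.warns(ReconstructionWarning, match="exhausted"):
            sl = propagate_interval(curve, 1, 4, EntryState(n_entry=1),
                                    np.zeros(4, dtype=int))
        assert (sl.n >= 0).all()


class TestFitInterval:
    def test_example_boundary_match(self, example_input):
        sl, ncensor, times, iterations, converged = fit_interval(
            example_input.curve, example_input.risk, 1, EntryState(n_entry=213)
        )
        assert converged
        assert sl.exit_state.n_entry == 122

    def test_boundary_censoring_converges_quickly(self):
        # 10 subjects: 5 events at t=1..5, 2 censored in (5, 10), 3 at risk at 10
        times = [0.0, 1, 2, 3, 4, 5, 10]
        surv = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.5]
        curve = DigitizedCurve("a", times, surv)
        risk = RiskTable(trisk=[0, 10], lower=[1, 7], upper=[6, 7], nrisk=[10, 3])
        sl, ncensor, _, iterations, converged = fit_interval(
            curve, risk, 1, EntryState(n_entry=10)
        )
        assert converged
        assert ncensor == 2
        assert iterations <= 2

    def test_flat_curve_stable_risk(self):
        curve = DigitizedCurve("a", [0, 1, 2, 3], [1, 1, 1, 1])
        risk = RiskTable(trisk=[0, 2], lower=[1, 3], upper=[2, 4], nrisk=[10, 10])
        sl, ncensor, _, iterations, converged = fit_interval(
            curve, risk, 1, EntryState(n_entry=10)
        )
        assert converged and ncensor == 0 and iterations == 1

    def test_unattainable_target_warns(self):
        # survival halves but the published risk number does not drop at all
        curve = DigitizedCurve("a", [0, 1, 2, 3], [1, 0.5, 0.5, 0.5])
        risk = RiskTable(trisk=[0, 2], lower=[1, 3], upper=[2, 4], nrisk=[10, 10])
        with pytest.warns(ReconstructionWarning, match="did not reach"):
            sl, ncensor, _, _, converged = fit_interval(
                curve, risk, 1, EntryState(n_entry=10)
            )
        assert not converged
        assert ncensor == 0


class TestProcessLastInterval:
    def _setup(self, surv=None):
        times = [0.0, 25.0, 50.0, 55.0, 65.0]
        surv = surv or [1.0] * 5
        curve = DigitizedCurve("a", times, surv)
        risk = RiskTable(trisk=[0, 55], lower=[1, 4], upper=[3, 5], nrisk=[100, 30])
        return curve, risk

    def test_zero_prior_censoring(self):
        curve, risk = self._setup()
        sl, ncensor, _ = process_last_interval(
            curve, risk, EntryState(n_entry=30), [0]
        )
        assert ncensor == 0

    def test_elapsed_time_weighting(self):
        # prior censorings 20, elapsed 50, span 10 -> round(10/50 * 20) = 4
        curve, risk = self._setup()
        sl, ncensor, times = process_last_interval(
            curve, risk, EntryState(n_entry=30), [20]
        )
        assert ncensor == 4
        assert sl.cen.sum() == 4

    def test_capped_at_number_at_risk(self):
        times = [0.0, 5.0, 10.0, 20.0, 30.0]
        curve = DigitizedCurve("a", times, [1.0] * 5)
        risk = RiskTable(trisk=[0, 20], lower=[1, 4], upper=[3, 5], nrisk=[300, 10])
        sl, ncensor, _ = process_last_interval(
            curve, risk, EntryState(n_entry=10), [200]
        )
        assert ncensor == 10


class TestMatchTotalEvents:
    def test_simulator_event_total_recovered(self):
        spec = TrialSpec(
            n_per_arm=120,
            arms={"a": EventDist.exponential(0.08)},
            censor=CensorDist.uniform(25),
            admin_cutoff=20,
            seed=11,
        )
        trial = simulate_trial(spec)
        ipd = trial.arm_ipd("a")
        curve = exact_digitize(ipd, "a")
        table, tot = make_risk_table(ipd, pick_risk_times(curve, 5), curve)
        res = reconstruct(ReconstructionInput(curve, table, tot))
        assert res.km.total_events == tot
        assert res.diagnostics.total_events_matched

    def test_total_zero_freezes_last_interval(self):
        curve = DigitizedCurve("a", [0, 1, 2, 3, 4], [1, 0.9, 0.8, 0.7, 0.6])
        risk = RiskTable(trisk=[0, 2], lower=[1, 3], upper=[2, 5], nrisk=[10, 8])
        with pytest.warns(ReconstructionWarning, match="already exceed"):
            res = reconstruct(ReconstructionInput(curve, risk, 0))
        last = res.km.d_hat[2:]
        assert (last == 0).all()


class TestReconstructLevels:
    def test_neither_exact_on_uncensored_trial(self):
        spec = TrialSpec(n_per_arm=80, arms={"a": EventDist.exponential(0.1)},
                         seed=5)
        trial = simulate_trial(spec)
        ipd = trial.arm_ipd("a")
        curve = exact_digitize(ipd, "a")
        table, _ = make_risk_table(ipd, [0.0], curve)
        res = reconstruct(ReconstructionInput(curve, table, None, InfoLevel.NEITHER))
        truth = trial.event_counts("a")
        got = pd.Series(res.km.d_hat[1:], index=res.km.times[1:])
        want = truth.set_index("time")["events"]
        np.testing.assert_array_equal(got.values, want.values)
        np.testing.assert_allclose(res.km.s_km[1:], curve.surv[1:])

    def test_no_total_events_matches_all_information_when_consistent(self):
        # when the event-total adjustment is a no-op the two levels agree
        spec = TrialSpec(n_per_arm=100, arms={"a": EventDist.exponential(0.1)},
                         censor=CensorDist.uniform(30), admin_cutoff=20, seed=9)
        trial = simulate_trial(spec)
        ipd = trial.arm_ipd("a")
        curve = exact_digitize(ipd, "a")
        table, tot = make_risk_table(ipd, pick_risk_times(curve, 5), curve)
        full = reconstruct(ReconstructionInput(curve, table, tot))
        if full.diagnostics.total_events_iterations == 0:
            partial = reconstruct(
                ReconstructionInput(curve, table, None, InfoLevel.NO_TOTAL_EVENTS)
            )
            np.testing.assert_array_equal(full.km.d_hat, partial.km.d_hat)
            np.testing.assert_array_equal(full.km.cen_hat, partial.km.cen_hat)

    def test_level_requires_matching_fields(self, example_curve):
        risk = RiskTable(trisk=[0], lower=[1], upper=[31], nrisk=[213])
        from kmrecon.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            ReconstructionInput(example_curve, risk, None,
                                InfoLevel.ALL_INFORMATION)

    def test_conservation_identities(self, example_input):
        res = reconstruct(example_input)
        km = res.km
        np.testing.assert_array_equal(
            km.n_hat[1:], km.n_hat[:-1] - km.d_hat - km.cen_hat
        )
        assert km.total_events + km.total_censored + km.n_after_final == km.n_hat[0]


class TestDeriveIPD:
    def test_two_patient_toy(self):
        curve = DigitizedCurve("a", [0.0, 0.18], [1.0, 0.5])
        risk = RiskTable(trisk=[0], lower=[1], upper=[2], nrisk=[2])
        res = reconstruct(ReconstructionInput(curve, risk, None, InfoLevel.NEITHER))
        records = derive_ipd(res.km, res.plan, curve, "a")
        assert len(records) == 2
        assert sorted((r.time, r.event) for r in records) == [(0.18, 0), (0.18, 1)]

    def test_record_count_equals_initial_at_risk(self, example_input):
        res = reconstruct(example_input)
        records = derive_ipd(res.km, res.plan, example_input.curve)
        assert len(records) == 213

    def test_km_of_derived_ipd_reproduces_s_km(self):
        from kmrecon.survstats import km_curve, surv_prob_at

        spec = TrialSpec(n_per_arm=90, arms={"a": EventDist.exponential(0.12)},
                         censor=CensorDist.uniform(22), admin_cutoff=18, seed=21)
        trial = simulate_trial(spec)
        ipd = trial.arm_ipd("a")
        curve = exact_digitize(ipd, "a")
        table, tot = make_risk_table(ipd, pick_risk_times(curve, 4), curve)
        res = reconstruct(ReconstructionInput(curve, table, tot))
        records = derive_ipd(res.km, res.plan, curve, "a")
        re_km = km_curve(records)
        for k in range(res.km.n_points):
            assert surv_prob_at(re_km, res.km.times[k]).estimate == pytest.approx(
                res.km.s_km[k], abs=1e-12
            )


def test_round_half_even_convention():
    assert [round_half_even(v) for v in (0.5, 1.5, 2.5, 2.51)] == [0, 2, 2, 3]


def test_km_tracking_bound_on_simulated_trials():
    """On perfect digitization the reconstructed KM estimate stays within one
    integer-rounding step of the digitized curve wherever patients remain."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(25):
            spec = TrialSpec(
                n_per_arm=150,
                arms={"a": EventDist.exponential(0.1)},
                censor=CensorDist.uniform(30),
                admin_cutoff=25,
                seed=seed,
            )
            trial = simulate_trial(spec)
            ipd = trial.arm_ipd("a")
            curve = exact_digitize(ipd, "a")
            table, tot = make_risk_table(ipd, pick_risk_times(curve, 5), curve)
            res = reconstruct(ReconstructionInput(curve, table, tot))
            km = res.km
            mask = km.n_hat[: km.n_points] > 0
            err = np.abs(km.s_km[mask] - curve.surv[mask]).max()
            assert err <= 1.0 / km.n_hat[: km.n_points][mask].min()
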