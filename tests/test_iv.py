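"""Peak extraction, decay fits, replicate QC, I-V curves, reversal potentials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghkfit import (
    CurrentTrace,
    DecayFitError,
    IVCurve,
    KineticsSpec,
    NoiseSpec,
    VoltageProtocol,
    analyze_recording_set,
    average_normalize,
    estimate_erev,
    fit_decay,
    ghk_current_density,
    ghk_erev_multi,
    peak_current,
    qc_replicates,
    simulate_experiment,
    simulate_trace,
)


def make_trace(time_ms, current, v=0.0):
    return CurrentTrace("c", 0, v, np.asarray(time_ms, float), np.asarray(current, float))


@pytest.fixture
def decay_trace(protocol):
    """Noise-free constructed decay: peak -80 pA, tau 50 ms, plateau -20 pA."""
    t = protocol.time_axis()
    i = np.zeros_like(t)
    onset = protocol.baseline_duration_ms
    post = t >= onset
    i[post] = -60.0 * np.exp(-(t[post] - onset) / 50.0) - 20.0
    return make_trace(t, i)


class TestPeakCurrent:
    def test_clean_trace_identity(self, decay_trace, protocol):
        assert peak_current(decay_trace, protocol) == pytest.approx(-80.0)

    def test_constructed_mid_window_extremum(self, protocol):
        t = protocol.time_axis()
        i = np.zeros_like(t)
        k = np.searchsorted(t, protocol.baseline_duration_ms + 125.0)
        i[k] = 42.5
        # brute-force maximum over agonist samples
        window = protocol.agonist_window(t)
        brute = i[window][np.argmax(np.abs(i[window]))]
        assert peak_current(make_trace(t, i), protocol) == brute == 42.5

    def test_baseline_subtraction(self, protocol):
        t = protocol.time_axis()
        i = np.full_like(t, 7.0)
        i[t >= protocol.baseline_duration_ms] = -73.0
        assert peak_current(make_trace(t, i), protocol) == pytest.approx(-80.0)

    def test_empty_window_rejected(self):
        proto = VoltageProtocol(baseline_duration_ms=50.0)
        t = np.arange(0, 40.0)
        with pytest.raises(ValueError, match="window"):
            peak_current(make_trace(t, np.zeros_like(t)), proto)


class TestFitDecay:
    def test_noiseless_round_trip(self, decay_trace, protocol):
        fit = fit_decay(decay_trace, protocol)
        assert fit.i_o_pA == pytest.approx(-60.0, rel=0.01)
        assert fit.tau_d_ms == pytest.approx(50.0, rel=0.01)
        assert fit.i_inf_pA == pytest.approx(-20.0, rel=0.01)
        assert fit.rmse_pA < 1e-6

    def test_generator_round_trip(
        self, anion_channel, solutions, protocol, quiet_noise, unity, ctx
    ):
        kin = KineticsSpec(tau_d_ms=50.0, plateau_fraction=0.25)
        rng = np.random.default_rng(0)
        trace = simulate_trace(
            anion_channel, -60.0, solutions["ES1"], solutions["I1"], protocol,
            kin, quiet_noise, rng, activity_model=unity, ctx=ctx,
        )
        peak = peak_current(trace, protocol)
        fit = fit_decay(trace, protocol)
        assert fit.tau_d_ms == pytest.approx(50.0, rel=0.01)
        assert fit.i_inf_pA == pytest.approx(0.25 * peak, rel=0.01)
        assert fit.i_o_pA == pytest.approx(0.75 * peak, rel=0.01)

    def test_noisy_tau_recovery_within_ten_percent(self, decay_trace, protocol):
        rng = np.random.default_rng(42)
        noisy = make_trace(
            decay_trace.time_ms,
            decay_trace.current_pA + rng.normal(0, 1.0, decay_trace.time_ms.shape),
        )
        fit = fit_decay(noisy, protocol)
        assert fit.tau_d_ms == pytest.approx(50.0, rel=0.10)

    def test_constant_trace_unidentifiable(self, protocol):
        t = protocol.time_axis()
        with pytest.raises(DecayFitError, match="unidentifiable"):
            fit_decay(make_trace(t, np.zeros_like(t)), protocol)

    def test_too_few_samples_rejected(self):
        proto = VoltageProtocol(
            baseline_duration_ms=0.0, agonist_duration_ms=5.0, sample_interval_ms=1.0
        )
        t = proto.time_axis()
        i = -np.exp(-t / 2.0)
        with pytest.raises(ValueError, match="10 samples"):
            fit_decay(make_trace(t, i), proto)


class TestQC:
    def test_consistent_replicates_kept(self):
        report = qc_replicates([-100.0, -95.0, -90.0])
        assert report.keep
        assert report.max_relative_difference == pytest.approx(0.10)

    def test_discordant_replicates_discarded(self):
        report = qc_replicates([-100.0, -10.0])
        assert not report.keep
        assert report.max_relative_difference == pytest.approx(0.90)

    def test_threshold_is_strict_inequality(self):
        assert qc_replicates([-100.0, -20.0]).keep          # exactly 80%
        assert not qc_replicates([-100.0, -19.9]).keep      # 80.1%

    def test_single_replicate_kept_with_warning(self):
        report = qc_replicates([-80.0])
        assert report.keep and "single_replicate" in report.flags

    def test_no_response_discarded(self):
        report = qc_replicates([0.0, 0.0, 0.0])
        assert not report.keep and "no response" in report.reason

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.floats(min_value=-200, max_value=-1), min_size=2, max_size=6
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, peaks, rand):
        shuffled = list(peaks)
        rand.shuffle(shuffled)
        a, b = qc_replicates(peaks), qc_replicates(shuffled)
        assert a.keep == b.keep
        assert a.max_relative_difference == pytest.approx(b.max_relative_difference)


class TestAverageNormalize:
    def test_equal_replicates_idempotent(self):
        peaks = {v: [float(v)] * 3 for v in (-60, -20, 20, 60) if v}
        iv = average_normalize(peaks)
        assert iv.i_max_pA == 60.0
        assert dict(zip(iv.potentials_mV, iv.normalized_peaks))[20.0] == pytest.approx(
            20 / 60
        )

    def test_scale_invariance(self):
        base = {-60.0: [-90.0, -85.0], 60.0: [110.0, 100.0]}
        doubled = {v: [2 * p for p in ps] for v, ps in base.items()}
        a, b = average_normalize(base), average_normalize(doubled)
        assert a.normalized_peaks == pytest.approx(b.normalized_peaks)
        assert b.i_max_pA == pytest.approx(2 * a.i_max_pA)

    def test_mean_equals_hand_average_first_n(self):
        peaks = {0.0: [-10.0, -14.0, -12.0, -99.0], 20.0: [30.0, 30.0, 30.0]}
        iv = average_normalize(peaks, n_avg=3)
        means = {0.0: (-10 - 14 - 12) / 3, 20.0: 30.0}
        i_max = 30.0
        got = dict(zip(iv.potentials_mV, iv.normalized_peaks))
        assert got[0.0] == pytest.approx(means[0.0] / i_max)
        assert iv.n_replicates_used == (3, 3)

    def test_short_replicates_used_and_flagged(self):
        iv = average_normalize({-20.0: [-5.0], 20.0: [5.0, 6.0, 7.0]}, n_avg=3)
        assert iv.n_replicates_used == (1, 3)
        assert any("-20" in f for f in iv.flags)


class TestEstimateErev:
    def test_antisymmetric_pair_midpoint(self):
        iv = IVCurve((-20.0, 0.0), (-0.5, 0.5), 10.0, (3, 3))
        assert estimate_erev(iv).value_mV == pytest.approx(-10.0)

    def test_positive_rescaling_invariance(self):
        iv1 = IVCurve((-20.0, 0.0, 20.0), (-0.8, -0.1, 0.6), 10.0, (3, 3, 3))
        iv2 = IVCurve((-20.0, 0.0, 20.0), (-0.4, -0.05, 0.3), 20.0, (3, 3, 3))
        assert estimate_erev(iv1).value_mV == pytest.approx(
            estimate_erev(iv2).value_mV
        )

    def test_noiseless_ghk_iv_matches_closed_form(
        self, anion_channel, solutions, unity, ctx, protocol
    ):
        out, inn = solutions["0.5NaCl"], solutions["I2"]
        potentials = protocol.holding_potentials_mV
        currents = [
            ghk_current_density(anion_channel, v, out, inn, unity, ctx)
            for v in potentials
        ]
        i_max = max(abs(c) for c in currents)
        iv = IVCurve(
            potentials, tuple(c / i_max for c in currents), i_max,
            (3,) * len(potentials),
        )
        closed = ghk_erev_multi(anion_channel, out, inn, unity, ctx).value_mV
        assert estimate_erev(iv).value_mV == pytest.approx(closed, abs=1.5)

    def test_quadratic_refinement_tightens_interpolation(
        self, anion_channel, solutions, unity, ctx, protocol
    ):
        out, inn = solutions["0.5NaCl"], solutions["I2"]
        potentials = protocol.holding_potentials_mV
        currents = [
            ghk_current_density(anion_channel, v, out, inn, unity, ctx)
            for v in potentials
        ]
        i_max = max(abs(c) for c in currents)
        iv = IVCurve(
            potentials, tuple(c / i_max for c in currents), i_max,
            (3,) * len(potentials),
        )
        closed = ghk_erev_multi(anion_channel, out, inn, unity, ctx).value_mV
        lin = abs(estimate_erev(iv, refine="interp").value_mV - closed)
        quad = abs(estimate_erev(iv, refine="quad").value_mV - closed)
        assert quad <= lin + 1e-9

    def test_all_same_sign_rejected(self):
        iv = IVCurve((-20.0, 0.0, 20.0), (0.2, 0.5, 1.0), 10.0, (3, 3, 3))
        with pytest.raises(ValueError, match="outside the protocol"):
            estimate_erev(iv)

    def test_multiple_sign_changes_flagged_nearest_zero(self):
        iv = IVCurve(
            (-60.0, -40.0, -20.0, 0.0, 20.0),
            (0.05, -0.1, -0.4, 0.3, 1.0),
            10.0,
            (3,) * 5,
        )
        est = estimate_erev(iv)
        assert -20.0 < est.value_mV < 0.0
        assert any("sign changes" in f for f in est.flags)


class TestFullChain:
    @pytest.mark.parametrize(
        "channel_fixture,pairs",
        [
            ("anion_channel", [("1NaCl", "I2"), ("0.5NaCl", "I2"), ("0.25NaCl", "I2")]),
            ("cation_channel", [("ES2", "I1"), ("ES4", "I1"), ("ES5", "I1")]),
        ],
    )
    def test_noiseless_pipeline_recovers_analytic_erev(
        self, request, channel_fixture, pairs, solutions, protocol, kinetics,
        quiet_noise, unity, ctx
    ):
        channel = request.getfixturevalue(channel_fixture)
        conditions = [(o, solutions[o], solutions[i]) for o, i in pairs]
        recset = simulate_experiment(
            channel, conditions, protocol, kinetics, quiet_noise,
            n_replicates=3, activity_model=unity, ctx=ctx,
        )
        results = analyze_recording_set(recset, protocol)
        for cid, sol_out, sol_in in conditions:
            analytic = ghk_erev_multi(channel, sol_out, sol_in, unity, ctx).value_mV
            res = results[cid]
            assert res.qc.keep
            assert res.erev.value_mV == pytest.approx(analytic, abs=1.5)

    def test_adversarial_replicate_dispersion_discarded(
        self, anion_channel, solutions, protocol, kinetics, unity, ctx
    ):
        noise = NoiseSpec(trace_noise_sd=0.0, replicate_amplitude_cv=0.0, seed=0)
        recset = simulate_experiment(
            anion_channel, [("ES1", solutions["ES1"], solutions["I1"])],
            protocol, kinetics, noise, n_replicates=2,
            activity_model=unity, ctx=ctx,
        )
        # shrink one replicate's currents by 95% — violates the 80% rule
        for t in recset.traces:
            if t.replicate_id == 1:
                t.current_pA[:] = t.current_pA * 0.05
        results = analyze_recording_set(recset, protocol)
        assert not results["ES1"].qc.keep
        assert results["ES1"].erev is None
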