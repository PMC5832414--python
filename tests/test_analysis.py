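"""Response statistics: evoked dF/F, event detection, responder
classification, distance curves, orientation selectivity, condition tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from holostim.analysis import (
    TraceSet,
    Trial,
    classify_nonresponder,
    compare_conditions,
    deconvolve_stub,
    detect_events,
    ensemble_response_rate,
    nonspecific_vs_distance,
    orientation_selectivity,
    stim_response,
    trial_event_matrix,
)


def _kernel(t, rise=0.2, decay=1.5):
    k = np.where(t >= 0, (1 - np.exp(-np.maximum(t, 0) / rise)) * np.exp(-np.maximum(t, 0) / decay), 0.0)
    return k / k.max()


class TestStimResponse:
    def test_simple_fractional_change(self):
        ts = np.arange(0.0, 10.0, 0.1)
        trace = np.where((ts >= 5.0) & (ts <= 6.0), 1.5, 1.0)
        got = stim_response(trace, ts, 5.0, 6.0)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_flat_trace_zero_response(self):
        ts = np.arange(0.0, 10.0, 0.1)
        assert stim_response(np.full_like(ts, 2.0), ts, 5.0, 6.0) == 0.0

    def test_nonpositive_baseline_rejected(self):
        ts = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="baseline"):
            stim_response(np.zeros_like(ts), ts, 5.0, 6.0)

    def test_known_transient_recovered(self):
        """A kernel-shaped transient of known amplitude on a unit baseline:
        the mean-over-window estimate matches the closed-form window mean
        within 10%."""
        ts = np.arange(0.0, 20.0, 0.02)
        amp = 0.8
        trace = 1.0 + amp * _kernel(ts - 8.0)
        got = stim_response(trace, ts, 8.0, 9.0)
        sel = (ts >= 8.0) & (ts <= 9.0)
        want = amp * _kernel(ts - 8.0)[sel].mean()
        assert got == pytest.approx(want, rel=0.10)

    def test_post_window_mode(self):
        ts = np.arange(0.0, 10.0, 0.1)
        trace = np.where((ts > 6.0) & (ts <= 7.0), 2.0, 1.0)
        got = stim_response(trace, ts, 5.0, 6.0, window="post")
        assert got == pytest.approx(1.0, abs=0.05)


def _traceset(dff, dec, dt=0.1, trials=()):
    n, t = np.atleast_2d(dff).shape
    return TraceSet(
        np.zeros((n, 3)), dff, np.arange(t) * dt, dec, list(trials)
    )


class TestDetectEvents:
    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        dff = rng.normal(0, 1, (3, 500))
        dec = np.abs(rng.normal(0, 1, (3, 500)))
        e1 = detect_events(_traceset(dff, dec))
        e2 = detect_events(_traceset(dff * 37.2, dec * 37.2))
        assert np.array_equal(e1, e2)

    def test_white_noise_event_rate_bounded(self):
        """Independent white-noise deconvolved and dF/F channels at k = 2:
        the joint exceedance rate is at most (1 - Phi(2))^2 plus 3 SE."""
        rng = np.random.default_rng(1)
        n = 10_000
        dff = np.cumsum(rng.normal(0, 1, n))  # derivative is white noise
        dec = np.abs(rng.normal(0, 1, n))
        events = detect_events(_traceset(dff[None, :], dec[None, :]))
        p = stats.norm.sf(2.0) ** 2
        # the half-normal deconvolved channel exceeds mean+2SD slightly less
        # often than a Gaussian; the Gaussian-Gaussian product still bounds it
        bound = p + 3 * np.sqrt(p * (1 - p) / n) + 0.01
        assert events.mean() <= bound

    def test_known_transients_f1(self):
        """20 kernel transients in realistic noise: detection F1 >= 0.9."""
        rng = np.random.default_rng(2)
        dt = 0.15
        ts = np.arange(0, 300, dt)
        onsets = np.sort(rng.choice(np.arange(50, len(ts) - 50), 20, replace=False))
        dff = rng.normal(0, 0.02, len(ts))
        for o in onsets:
            dff[o:] += 1.0 * _kernel(ts[o:] - ts[o])
        dec = deconvolve_stub(dff, dt, 1.5)
        events = detect_events(_traceset(dff[None, :], dec[None, :], dt=dt))[0]
        # one transient = one burst of consecutive event samples
        ev_idx = np.flatnonzero(events)
        bursts = []
        for e in ev_idx:
            if bursts and e - bursts[-1][-1] <= 2:
                bursts[-1].append(e)
            else:
                bursts.append([e])
        starts = np.array([b[0] for b in bursts])
        hits = sum(np.any(np.abs(starts - o) <= 2) for o in onsets)
        spurious = sum(not np.any(np.abs(onsets - s) <= 4) for s in starts)
        precision = hits / max(hits + spurious, 1)
        recall = hits / 20
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9

    def test_constant_trace_warns_no_events(self):
        dff = np.ones((1, 200))
        dec = np.ones((1, 200))
        with pytest.warns(UserWarning, match="constant"):
            events = detect_events(_traceset(dff, dec))
        assert not events.any()

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_positive_rescaling_property(self, scale):
        rng = np.random.default_rng(5)
        dff = rng.normal(0, 1, (2, 300))
        dec = np.abs(rng.normal(0, 1, (2, 300)))
        base = detect_events(_traceset(dff, dec))
        scaled = detect_events(_traceset(dff * scale, dec * scale))
        assert np.array_equal(base, scaled)


class TestResponderClassification:
    def _trials(self, n=8, start=10.0, period=5.0, dur=0.5):
        return [
            Trial(0, i, start + i * period, start + i * period + dur, (0,))
            for i in range(n)
        ]

    def test_event_in_one_trial_is_responder(self):
        ts = np.arange(0, 60, 0.1)
        trials = self._trials()
        events = np.zeros((1, len(ts)), bool)
        idx = np.argmin(np.abs(ts - trials[3].stim_start - 0.2))
        events[0, idx] = True
        assert not classify_nonresponder(events, ts, trials)[0]

    def test_zero_events_is_nonresponder(self):
        ts = np.arange(0, 60, 0.1)
        events = np.zeros((1, len(ts)), bool)
        assert classify_nonresponder(events, ts, self._trials())[0]

    def test_needs_multiple_trials(self):
        ts = np.arange(0, 60, 0.1)
        with pytest.raises(ValueError):
            classify_nonresponder(np.zeros((1, len(ts)), bool), ts, self._trials(1))

    def test_silent_fraction_recovered_in_cohort(self):
        """A cohort with 8% permanently silent cells: the classified
        fraction falls inside the binomial 3-sigma band."""
        rng = np.random.default_rng(3)
        n_cells, n_trials = 200, 8
        silent = rng.random(n_cells) < 0.08
        ts = np.arange(0, 60, 0.1)
        trials = self._trials(n_trials)
        events = np.zeros((n_cells, len(ts)), bool)
        for i in range(n_cells):
            if silent[i]:
                continue
            for tr in trials:
                if rng.random() < 0.82:
                    idx = np.argmin(np.abs(ts - tr.stim_start - 0.2))
                    events[i, idx] = True
        got = classify_nonresponder(events, ts, trials).mean()
        # non-silent cells all respond somewhere with prob 1-(1-.82)^8 ~ 1
        se = np.sqrt(0.08 * 0.92 / n_cells)
        assert abs(got - 0.08) <= 3 * se + (1 - 0.82) ** n_trials


class TestEnsembleRate:
    def test_bounds_and_trivial_cases(self):
        assert ensemble_response_rate(np.ones((5, 10), bool)) == 100.0
        half = np.zeros((4, 10), bool)
        half[:, :5] = True
        assert ensemble_response_rate(half) == 50.0

    def test_monotone_in_responder_sets(self):
        rng = np.random.default_rng(4)
        base = rng.random((6, 12)) < 0.5
        more = base.copy()
        more[0, ~base[0]] = True
        assert ensemble_response_rate(more) >= ensemble_response_rate(base)

    def test_binomial_simulation_recovers_rate(self):
        """Per-cell response probability 0.82: the measured ensemble rate
        lands within 3 SE of 82%."""
        rng = np.random.default_rng(6)
        n_trials, m = 30, 20
        responded = rng.random((n_trials, m)) < 0.82
        rate = ensemble_response_rate(responded)
        se = 100 * np.sqrt(0.82 * 0.18 / (n_trials * m))
        assert abs(rate - 82.0) <= 3 * se


class TestDistanceCurve:
    def _positions(self, n=300, seed=7):
        rng = np.random.default_rng(seed)
        pos = rng.uniform([-120, -120, -50], [120, 120, 50], (n, 3))
        pos[0] = 0.0  # the single targeted cell at the origin
        return pos

    def test_flat_responses_give_unit_curve(self):
        pos = self._positions()
        responses = np.ones(len(pos))
        curve = nonspecific_vs_distance(pos, np.array([0]), responses)
        valid = curve.counts > 0
        np.testing.assert_allclose(curve.values[valid], 1.0)

    def test_exponential_falloff_half_distance(self):
        """Responses exp(-d/12): half-response distance ln2 * 12 um within
        one bin width."""
        lam = 12.0
        pos = self._positions(600)
        d = np.linalg.norm(pos, axis=1)
        responses = np.exp(-d / lam)
        responses[0] = 1.0
        curve = nonspecific_vs_distance(pos, np.array([0]), responses, bin_width_um=10.0)
        assert curve.half_distance_um == pytest.approx(np.log(2) * lam, abs=10.0)

    def test_empty_bins_are_nan_not_zero(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [100.0, 0, 0]])
        curve = nonspecific_vs_distance(pos, np.array([0]), np.array([1.0, 1.0, 0.5]),
                                        bin_width_um=10.0)
        gap = (curve.counts == 0)
        assert gap.any()
        assert np.all(np.isnan(curve.values[gap]))

    def test_requires_positive_targeted_mean(self):
        pos = self._positions(10)
        with pytest.raises(ValueError, match="positive"):
            nonspecific_vs_distance(pos, np.array([0]), np.zeros(10))


class TestOrientationSelectivity:
    def test_arithmetic_cases(self):
        idx, pref = orientation_selectivity(0.3, 0.1)
        assert idx == pytest.approx(0.5)
        assert pref == 90.0
        idx, pref = orientation_selectivity(0.2, 0.2)
        assert idx == 0.0
        idx, pref = orientation_selectivity(0.2, 0.0)
        assert idx == pytest.approx(1.0)
        assert pref == 90.0
        idx, pref = orientation_selectivity(0.1, 0.3)
        assert pref == 0.0

    def test_zero_denominator_flagged(self):
        idx, pref = orientation_selectivity(0.2, -0.2)
        assert np.isnan(idx) and np.isnan(pref)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.001, 10.0), st.floats(0.001, 10.0))
    def test_bounded_and_antisymmetric(self, a, b):
        idx, pref = orientation_selectivity(a, b)
        assert 0.0 <= idx <= 1.0
        idx2, pref2 = orientation_selectivity(b, a)
        assert idx == pytest.approx(idx2)
        if a != b:
            assert {pref, pref2} == {0.0, 90.0}


class TestCompareConditions:
    def test_identical_trials_not_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (5, 20))
        got = compare_conditions(a, a.copy())
        assert not got.significant.any()

    def test_large_shift_detected(self):
        """A 5 SD mean shift with n = 30 per arm has essentially unit
        power; every ROI comes out significant."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, (20, 30))
        b = rng.normal(5, 1, (20, 30))
        got = compare_conditions(a, b)
        assert got.significant.all()

    def test_null_false_positive_rate(self):
        """1000 ROIs under the null: the flagged fraction is alpha within
        3 binomial SE."""
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, (1000, 30))
        b = rng.normal(0, 1, (1000, 30))
        got = compare_conditions(a, b)
        fpr = got.significant.mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(fpr - 0.05) <= 3 * se

    def test_zero_variance_flagged_undefined(self):
        a = np.ones((2, 5))
        got = compare_conditions(a, a)
        assert got.undefined.all()
        assert np.isnan(got.p_values).all()


class TestDeconvolveStub:
    def test_matching_transient_collapses_to_onset(self):
        dt, tau = 0.1, 1.5
        ts = np.arange(0, 20, dt)
        dff = np.where(ts >= 5.0, 2.0 * np.exp(-(ts - 5.0) / tau), 0.0)
        dec = deconvolve_stub(dff, dt, tau)
        onset = int(round(5.0 / dt))
        assert dec[onset] == pytest.approx(2.0)
        assert np.abs(dec[onset + 1 :]).max() < 1e-9

    def test_flat_trace_gives_zeros(self):
        assert not deconvolve_stub(np.zeros(100), 0.1, 1.5).any()

    def test_spike_train_onsets_recovered(self):
        rng = np.random.default_rng(11)
        dt, tau = 0.1, 1.5
        ts = np.arange(0, 100, dt)
        onsets = np.sort(rng.choice(np.arange(10, len(ts) - 10), 15, replace=False))
        dff = np.zeros(len(ts))
        for o in onsets:
            dff[o:] += np.exp(-(ts[o:] - ts[o]) / tau)
        dec = deconvolve_stub(dff, dt, tau)
        got = np.flatnonzero(dec > 0.5)
        for o in onsets:
            assert np.min(np.abs(got - o)) <= 1


class TestTrialEventMatrix:
    def test_window_padding(self):
        ts = np.arange(0, 20, 0.1)
        trials = [Trial(0, 0, 5.0, 5.5, (0,))]
        events = np.zeros((1, len(ts)), bool)
        events[0, np.argmin(np.abs(ts - 5.8))] = True
        assert not trial_event_matrix(events, ts, trials)[0, 0]
        assert trial_event_matrix(events, ts, trials, pad_s=0.5)[0, 0]
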