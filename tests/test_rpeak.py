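import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cardiokit as ck
from cardiokit.core import ECGSignal, ExtremaSequence
from cardiokit.rpeak import (
    detect_rpeaks,
    extract_extrema,
    kmeans_threshold,
    lmmd_cancel,
    pan_tompkins_envelope,
)
from conftest import match_rate


def seq(amps, first_is_max=True):
    n = len(amps)
    kinds = np.array([(i % 2 == 0) == first_is_max for i in range(n)])
    return ExtremaSequence(np.arange(n) * 10, np.asarray(amps, float), kinds)


class TestEnvelope:
    def test_nonnegative_same_length(self, noisy_record):
        sig, _ = noisy_record
        env = pan_tompkins_envelope(sig)
        assert len(env) == len(sig)
        assert np.all(env.samples >= 0)

    def test_constant_input_yields_null_envelope(self):
        env = pan_tompkins_envelope(ECGSignal(np.full(2000, 3.3), 360.0))
        assert np.max(np.abs(env.samples)) < 1e-9

    def test_envelope_maxima_align_with_true_beats(self, clean_record):
        sig, truth = clean_record
        env = pan_tompkins_envelope(sig)
        ext = extract_extrema(env)
        maxima = ext.indices[ext.is_max]
        assert match_rate(maxima, truth.r_indices, tol=18) >= 0.99

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pan_tompkins_envelope(ECGSignal(np.zeros(100) + np.arange(100), 360.0), (15.0, 5.0))


class TestExtrema:
    def test_simple_alternation(self):
        ext = extract_extrema(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))
        assert list(ext.indices) == [1, 3]
        assert list(ext.amplitudes) == [1.0, -1.0]
        assert list(ext.is_max) == [True, False]

    def test_monotone_ramp_has_no_extrema(self):
        assert len(extract_extrema(np.arange(10.0))) == 0

    def test_plateau_maps_to_first_sample(self):
        ext = extract_extrema(np.array([0.0, 2.0, 2.0, 0.0]))
        assert list(ext.indices) == [1]
        assert list(ext.is_max) == [True]

    @given(st.integers(0, 2**31 - 1))
    def test_alternation_invariant_on_random_signals(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        ext = extract_extrema(x)
        if len(ext) > 1:
            assert np.all(ext.is_max[1:] != ext.is_max[:-1])
            assert np.all(np.diff(ext.indices) > 0)


def brute_force_lmmd(amps, kinds, min_persistence):
    """Independent list-scan oracle for the pair-cancellation procedure."""
    amps, kinds = list(amps), list(kinds)
    while len(amps) >= 2:
        diffs = [abs(amps[i + 1] - amps[i]) for i in range(len(amps) - 1)]
        j = int(np.argmin(diffs))
        if diffs[j] >= min_persistence:
            break
        del amps[j : j + 2], kinds[j : j + 2]
    return amps, kinds


class TestLmmdCancel:
    def test_worked_example(self):
        ext = seq([1.0, 0.2, 0.3, -0.8])
        out = lmmd_cancel(ext, 0.2)
        assert list(out.amplitudes) == [1.0, -0.8]
        assert list(out.is_max) == [True, False]

    def test_zero_persistence_is_identity(self):
        ext = seq([1.0, 0.2, 0.3, -0.8])
        out = lmmd_cancel(ext, 0.0)
        assert list(out.amplitudes) == list(ext.amplitudes)

    def test_single_extremum_unchanged(self):
        ext = seq([0.5])
        assert list(lmmd_cancel(ext, 1.0).amplitudes) == [0.5]

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 2.0))
    def test_matches_bruteforce_and_persistence_invariant(self, seed, thr):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(120)
        ext = extract_extrema(x)
        out = lmmd_cancel(ext, thr)
        want_amps, want_kinds = brute_force_lmmd(ext.amplitudes, ext.is_max, thr)
        assert list(out.amplitudes) == want_amps
        assert list(out.is_max) == want_kinds
        assert np.all(out.adjacent_differences() >= thr)


def brute_force_two_means(values):
    """Exhaustive 1-D 2-means oracle: minimal within-cluster SSE over splits."""
    a = np.sort(np.asarray(values, float))
    best = None
    for k in range(1, a.size):
        w0, w1 = a[:k], a[k:]
        cost = np.sum((w0 - w0.mean()) ** 2) + np.sum((w1 - w1.mean()) ** 2)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, w0.max(), w1.min())
    return best


class TestKmeansThreshold:
    def test_obvious_split(self):
        split = kmeans_threshold([0.1, 0.2, 0.8, 1.0])
        assert list(split.w0) == [0.1, 0.2]
        assert list(split.w1) == [0.8, 1.0]
        assert split.th == pytest.approx(0.5)

    def test_two_points(self):
        assert kmeans_threshold([0.0, 1.0]).th == pytest.approx(0.5)

    def test_identical_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="one cluster"):
            kmeans_threshold([0.4, 0.4, 0.4])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 200))
    def test_equals_exhaustive_optimum(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(0.2, 0.05, size=n // 2 + 1),
            rng.normal(1.0, 0.05, size=n - n // 2 - 1 + 1),
        ])
        split = kmeans_threshold(vals)
        cost, w0_max, w1_min = brute_force_two_means(vals)
        got_cost = (
            np.sum((split.w0 - split.w0.mean()) ** 2)
            + np.sum((split.w1 - split.w1.mean()) ** 2)
        )
        assert got_cost == pytest.approx(cost, abs=1e-9)
        assert split.th == pytest.approx((w0_max + w1_min) / 2, abs=1e-9)

    def test_threshold_separates_well_separated_modes(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0.1, 0.02, 120), rng.normal(0.9, 0.02, 80)])
        split = kmeans_threshold(vals)
        assert 0.2 < split.th < 0.8


class TestDetectRpeaks:
    def test_clean_60bpm_count_and_positions(self, clean_record):
        sig, truth = clean_record
        clean = ck.clean(sig)
        peaks = detect_rpeaks(clean)
        assert abs(len(peaks) - len(truth.r_indices)) <= 1
        assert match_rate(peaks.indices, truth.r_indices, tol=18) == 1.0

    def test_polarity_invariance_exact(self, clean_record):
        sig, _ = clean_record
        clean = ck.clean(sig)
        flipped = clean.replace(-clean.samples)
        up = detect_rpeaks(clean)
        down = detect_rpeaks(flipped)
        np.testing.assert_array_equal(up.indices, down.indices)

    def test_flat_signal_yields_empty_set(self):
        with pytest.warns(UserWarning):
            peaks = detect_rpeaks(ECGSignal(np.zeros(3600), 360.0))
        assert len(peaks) == 0

    def test_refractory_period_enforced(self, detected_features):
        _, peaks, _ = detected_features
        assert np.all(np.diff(peaks.indices) >= 0.2 * peaks.fs)
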