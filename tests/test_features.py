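"""Time-domain statistics and the MFCC chain, checked against independent
naive implementations (direct summation DFT, hand-built filterbank and
cosine transform)."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

import nsca
from nsca.features import (LOG_FLOOR, MfccParams, extract_features,
                           frame_signal, hamming_window, hz_to_mel,
                           magnitude_spectrum, mel_filterbank, mel_to_hz,
                           mfcc, pre_emphasize, time_domain_features)
from nsca.io_core import InvariantError


# ---------------------------------------------------------------------------
# independent oracles (naive, O(N^2), written separately from the package)


def dft_magnitude_naive(frame: np.ndarray, n_fft: int) -> np.ndarray:
    x = np.zeros(n_fft)
    x[: len(frame)] = frame
    k = np.arange(n_fft // 2 + 1)
    out = np.empty(k.size)
    for i, kk in enumerate(k):
        acc = 0.0 + 0.0j
        for n in range(n_fft):
            acc += x[n] * np.exp(-2j * np.pi * kk * n / n_fft)
        out[i] = abs(acc)
    return out


def mfcc_naive(signal, fs, p: MfccParams) -> np.ndarray:
    """Same math, separately coded: emphasis, frames, window, DFT by
    summation, triangle filters built from the mel formulas, log, DCT by
    explicit double loop."""
    x = np.asarray(signal, float).copy()
    y = x.copy()
    for n in range(len(x) - 1, 0, -1):
        y[n] = x[n] - p.pre_emphasis * x[n - 1]
    n_frames = int(np.ceil((len(y) - p.frame_length) / p.hop)) + 1
    w = np.array([0.54 - 0.46 * np.cos(2 * np.pi * n / (p.frame_length - 1))
                  for n in range(p.frame_length)])
    # mel points and triangles
    def mel(f):
        return 2595.0 * np.log10(f / p.mel_denominator + 1.0)

    def imel(m):
        return p.mel_denominator * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(0.0, mel(fs / 2.0), p.n_filters + 2))
    bins = np.arange(p.fft_length // 2 + 1) * fs / p.fft_length
    out = np.empty((n_frames, p.n_coeffs))
    for fi in range(n_frames):
        fr = y[fi * p.hop: fi * p.hop + p.frame_length]
        fr = np.pad(fr, (0, p.frame_length - len(fr)))
        spec = dft_magnitude_naive(fr * w, p.fft_length)
        energies = np.empty(p.n_filters)
        for m in range(p.n_filters):
            lo, c, hi = edges[m], edges[m + 1], edges[m + 2]
            weight = np.where(bins <= c,
                              (bins - lo) / (c - lo),
                              (hi - bins) / (hi - c))
            energies[m] = np.sum(np.clip(weight, 0.0, None) * spec)
        log_e = np.log(np.maximum(energies, LOG_FLOOR))
        for j_out in range(p.n_coeffs):
            j = j_out + (1 if p.drop_c0 else 0)
            out[fi, j_out] = np.sqrt(2.0 / p.n_filters) * sum(
                log_e[m - 1] * np.cos(j * np.pi / p.n_filters * (m - 0.5))
                for m in range(1, p.n_filters + 1))
    return out


# ---------------------------------------------------------------------------


class TestTimeDomain:
    def test_simple_vector(self):
        mad, mu, sd, var, m4 = time_domain_features([1.0, 2.0, 3.0])
        assert mu == 2.0
        npt.assert_allclose(mad, 2.0 / 3.0)
        assert var == 1.0 and sd == 1.0
        npt.assert_allclose(m4, 1.0)  # (1 + 0 + 1) / (3 - 1)

    def test_constant_signal_all_zero_dispersion(self):
        mad, mu, sd, var, m4 = time_domain_features([7.0] * 4)
        assert (mad, sd, var, m4) == (0.0, 0.0, 0.0, 0.0)
        assert mu == 7.0

    def test_matches_naive_sums_on_random_vectors(self, rng):
        s = rng.normal(size=50)
        mad, mu, sd, var, m4 = time_domain_features(s)
        sb = s.mean()
        npt.assert_allclose(mad, sum(abs(x - sb) for x in s) / 50)
        npt.assert_allclose(var, sum((x - sb) ** 2 for x in s) / 49)
        npt.assert_allclose(sd, np.sqrt(var))
        npt.assert_allclose(m4, sum((x - sb) ** 4 for x in s) / 49)

    def test_too_short_rejected(self):
        with pytest.raises(InvariantError):
            time_domain_features([1.0])


class TestPreEmphasis:
    def test_zero_coefficient_is_identity(self):
        x = [1.0, -2.0, 3.0]
        npt.assert_array_equal(pre_emphasize(x, 0.0), x)

    def test_impulse_response(self):
        npt.assert_allclose(pre_emphasize([1.0, 0.0, 0.0], 0.9),
                            [1.0, -0.9, 0.0])

    def test_constant_signal(self):
        npt.assert_allclose(pre_emphasize(np.ones(5), 0.97),
                            [1.0, 0.03, 0.03, 0.03, 0.03])

    def test_empty_rejected(self):
        with pytest.raises(InvariantError):
            pre_emphasize([], 0.97)


class TestFraming:
    def test_frame_starts(self):
        frames = frame_signal(np.arange(10.0), 4, 2)
        assert frames.shape == (4, 4)
        npt.assert_array_equal(frames[0], [0, 1, 2, 3])
        npt.assert_array_equal(frames[3], [6, 7, 8, 9])

    def test_single_full_frame(self):
        frames = frame_signal(np.arange(6.0), 6, 3)
        assert frames.shape == (1, 6)

    def test_partial_frame_zero_padded(self):
        frames = frame_signal(np.arange(5.0), 4, 4)
        npt.assert_array_equal(frames[1], [4, 0, 0, 0])

    def test_nonpositive_hop_rejected(self):
        with pytest.raises(InvariantError):
            frame_signal(np.arange(5.0), 4, 0)


class TestHamming:
    def test_length_three(self):
        npt.assert_allclose(hamming_window(3), [0.08, 1.0, 0.08])

    def test_symmetric(self):
        w = hamming_window(17)
        npt.assert_allclose(w, w[::-1])

    def test_odd_center_is_one(self):
        assert hamming_window(65)[32] == pytest.approx(1.0)

    def test_length_one_limit(self):
        npt.assert_array_equal(hamming_window(1), [1.0])


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert hz_to_mel(0.0, "log10_2595") == 0.0
        assert hz_to_mel(0.0, "ln_1127") == 0.0

    def test_printed_formula_at_denominator(self):
        npt.assert_allclose(hz_to_mel(100.0, "log10_2595", 100.0),
                            2595.0 * np.log10(2.0))

    def test_variants_agree_within_a_hundredth_percent(self):
        f = np.linspace(0.1, 10000.0, 500)
        a = hz_to_mel(f, "log10_2595")
        b = hz_to_mel(f, "ln_1127")
        assert np.max(np.abs(a - b) / a) < 1e-4

    @given(st.floats(min_value=0.0, max_value=5e4))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, f):
        for variant in ("log10_2595", "ln_1127"):
            back = float(mel_to_hz(hz_to_mel(f, variant), variant))
            assert back == pytest.approx(f, rel=1e-9, abs=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(InvariantError):
            hz_to_mel(-1.0)


class TestFilterbank:
    def test_single_filter_is_one_triangle(self):
        fb = mel_filterbank(1, 64, 250.0)
        assert fb.shape == (1, 33)
        assert fb.max() > 0 and np.all(fb >= 0)

    def test_every_row_has_positive_mass(self):
        fb = mel_filterbank(20, 128, 250.0)
        assert np.all(fb.sum(axis=1) > 0)

    def test_centers_monotone_in_hz(self):
        fb = mel_filterbank(10, 256, 250.0)
        centers = np.argmax(fb, axis=1)
        assert np.all(np.diff(centers) >= 0)

    def test_too_many_filters_rejected(self):
        with pytest.raises(InvariantError, match="no FFT bin"):
            mel_filterbank(60, 16, 250.0)


class TestSpectrumOracle:
    @pytest.mark.parametrize("n", [8, 16, 64])
    def test_fft_matches_direct_summation(self, n, rng):
        frame = rng.normal(size=n)
        fast = magnitude_spectrum(frame, n)
        slow = dft_magnitude_naive(frame, n)
        npt.assert_allclose(fast, slow, atol=1e-9)


class TestMfcc:
    def test_coefficient_count(self, rng):
        out = mfcc(rng.normal(size=500), 250.0, MfccParams())
        assert out.shape[1] == 12

    def test_deterministic(self, rng):
        sig = rng.normal(size=300)
        npt.assert_array_equal(mfcc(sig, 250.0), mfcc(sig, 250.0))

    def test_silent_signal_never_raises(self):
        out = mfcc(np.zeros(256), 250.0, MfccParams())
        assert np.all(np.isfinite(out))

    def test_matches_independent_naive_implementation(self, rng):
        sig = rng.normal(size=250)  # 1 s at 250 Hz
        p = MfccParams(n_filters=12, fft_length=64)
        ours = mfcc(sig, 250.0, p)
        ref = mfcc_naive(sig, 250.0, p)
        npt.assert_allclose(ours, ref, rtol=1e-6)


class TestExtract:
    def test_dimension_bookkeeping(self, small_session):
        fm = extract_features(small_session, MfccParams(), "both")
        assert fm.n_features == 22 * (5 + 12)  # = 374
        assert fm.values.shape[0] == len(small_session)

    def test_time_only_dimensions(self, small_session):
        fm = extract_features(small_session, MfccParams(), "time")
        assert fm.n_features == 22 * 5

    def test_deterministic(self, small_session):
        a = extract_features(small_session, MfccParams(), "mfcc")
        b = extract_features(small_session, MfccParams(), "mfcc")
        npt.assert_array_equal(a.values, b.values)

    def test_unknown_domain_rejected(self, small_session):
        with pytest.raises(ValueError):
            extract_features(small_session, MfccParams(), "wavelet")
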