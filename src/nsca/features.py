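"""Per-channel feature extraction: time-domain statistics and MFCCs.

Each EEG epoch is summarized channel by channel.  The time-domain block is
five scalar statistics (mean absolute deviation, mean, sample standard
deviation, sample variance and the unnormalized fourth central moment).
The spectral block is a mel-frequency cepstral coefficient (MFCC) variant:
pre-emphasis, framing with overlap, Hamming windowing, magnitude spectrum,
a triangular mel filterbank, log compression and a cosine transform.

Two details differ from common speech-processing MFCCs and are deliberate:
the mel map defaults to ``2595*log10(1 + f/100)`` (denominator 100, not
the usual 700; 700 is selectable), and the fourth moment is not normalized
by sigma^4, so it is a central moment rather than excess kurtosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import EpochSet, FeatureMatrix, InvariantError

TIME_FEATURE_NAMES = ("mad", "mean", "std", "var", "m4")

LOG_FLOOR = 1e-10  # floor on filterbank energies before the log


@dataclass
class MfccParams:
    """MFCC configuration.

    mel_variant selects between the base-10 map ``2595*log10(1 + f/d)`` and
    the natural-log map ``1127*ln(1 + f/d)``; the two agree to ~0.01%
    because 2595/ln(10) ~= 1127.  ``mel_denominator`` d defaults to 100.
    """

    n_coeffs: int = 12
    n_filters: int = 20
    frame_length: int = 64
    hop: int = 32
    pre_emphasis: float = 0.97
    mel_denominator: float = 100.0
    fft_length: int = 128
    drop_c0: bool = True
    mel_variant: str = "log10_2595"

    def __post_init__(self) -> None:
        if not 12 <= self.n_coeffs <= 20:
            warnings.warn(
                f"n_coeffs={self.n_coeffs} is outside the customary 12..20 "
                "range", stacklevel=2,
            )
        if self.hop > self.frame_length:
            raise InvariantError("hop must not exceed frame_length")
        if self.hop <= 0:
            raise InvariantError("hop must be positive")
        if self.fft_length < self.frame_length:
            raise InvariantError("fft_length must be >= frame_length")
        if self.fft_length % 2:
            raise InvariantError("fft_length must be even")


# ---------------------------------------------------------------------------
# time domain


def time_domain_features(signal: np.ndarray) -> np.ndarray:
    """(MAD, mean, std, var, m4) of a 1-D signal.

    std/var use the n-1 denominator; m4 is (1/(n-1)) * sum((s - mean)^4),
    an unnormalized fourth central moment.
    """
    s = np.asarray(signal, dtype=float)
    n = s.size
    if n < 2:
        raise InvariantError("time_domain_features needs at least 2 samples")
    mean = s.mean()
    dev = s - mean
    mad = np.abs(dev).mean()
    var = (dev ** 2).sum() / (n - 1)
    std = np.sqrt(var)
    m4 = (dev ** 4).sum() / (n - 1)
    return np.array([mad, mean, std, var, m4])


# ---------------------------------------------------------------------------
# MFCC building blocks


def pre_emphasize(signal: np.ndarray, a: float) -> np.ndarray:
    """First-order FIR high-pass y[n] = x[n] - a*x[n-1]; y[0] = x[0]."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InvariantError("cannot pre-emphasize an empty signal")
    if not 0 <= a < 1:
        raise InvariantError("pre-emphasis coefficient must be in [0, 1)")
    if a != 0 and not 0.9 <= a <= 0.99:
        warnings.warn(
            f"pre-emphasis a={a} is outside the customary [0.9, 0.99] range",
            stacklevel=2,
        )
    y = x.copy()
    y[1:] -= a * x[:-1]
    return y


def frame_signal(signal: np.ndarray, frame_length: int, hop: int
                 ) -> np.ndarray:
    """Split into overlapping frames starting at 0, hop, 2*hop, ...

    The final partial frame is zero-padded, so the frame count is
    ``ceil((len - frame_length)/hop) + 1``.
    """
    x = np.asarray(signal, dtype=float)
    if hop <= 0:
        raise InvariantError("hop must be positive")
    if frame_length > x.size:
        raise InvariantError("frame_length exceeds signal length")
    n_frames = int(np.ceil((x.size - frame_length) / hop)) + 1
    frames = np.zeros((n_frames, frame_length))
    for i in range(n_frames):
        chunk = x[i * hop: i * hop + frame_length]
        frames[i, : chunk.size] = chunk
    return frames


def hamming_window(length: int) -> np.ndarray:
    """w[n] = 0.54 - 0.46*cos(2*pi*n/(length-1)); length 1 -> [1.0]."""
    if length < 1:
        raise InvariantError("window length must be >= 1")
    if length == 1:
        return np.ones(1)
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))


def hz_to_mel(f, variant: str = "log10_2595",
              mel_denominator: float = 100.0):
    """Frequency warp Hz -> mel; monotone increasing, mel(0) = 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvariantError("frequency must be non-negative")
    if variant == "log10_2595":
        return 2595.0 * np.log10(f / mel_denominator + 1.0)
    if variant == "ln_1127":
        return 1127.0 * np.log(f / mel_denominator + 1.0)
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_to_hz(m, variant: str = "log10_2595",
              mel_denominator: float = 100.0):
    """Exact inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=float)
    if variant == "log10_2595":
        return mel_denominator * (10.0 ** (m / 2595.0) - 1.0)
    if variant == "ln_1127":
        return mel_denominator * (np.exp(m / 1127.0) - 1.0)
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_filterbank(n_filters: int, fft_length: int, sampling_rate_hz: float,
                   mel_denominator: float = 100.0,
                   variant: str = "log10_2595") -> np.ndarray:
    """Triangular filters equally spaced on the mel axis from 0 to Nyquist.

    Returns an ``n_filters x (fft_length//2 + 1)`` weight matrix.  Filter m
    rises linearly from edge m-1 to its center and falls to edge m+1.
    """
    if n_filters < 1:
        raise InvariantError("need at least one filter")
    if fft_length % 2:
        raise InvariantError("fft_length must be even")
    nyquist = sampling_rate_hz / 2.0
    mel_pts = np.linspace(
        0.0,
        float(hz_to_mel(nyquist, variant, mel_denominator)),
        n_filters + 2,
    )
    hz_pts = mel_to_hz(mel_pts, variant, mel_denominator)
    n_bins = fft_length // 2 + 1
    bin_hz = np.arange(n_bins) * sampling_rate_hz / fft_length
    fb = np.zeros((n_filters, n_bins))
    for m in range(1, n_filters + 1):
        left, center, right = hz_pts[m - 1], hz_pts[m], hz_pts[m + 1]
        up = (bin_hz - left) / (center - left)
        down = (right - bin_hz) / (right - center)
        fb[m - 1] = np.clip(np.minimum(up, down), 0.0, None)
    empty = ~(fb > 0).any(axis=1)
    if empty.any():
        raise InvariantError(
            f"filters {np.where(empty)[0].tolist()} cover no FFT bin; "
            "reduce n_filters or increase fft_length"
        )
    return fb


def magnitude_spectrum(frame: np.ndarray, fft_length: int) -> np.ndarray:
    """|DFT| of one frame on the non-negative frequency bins."""
    return np.abs(np.fft.rfft(frame, n=fft_length))


def _dct_basis(n_coeffs: int, n_filters: int, drop_c0: bool) -> np.ndarray:
    """Cosine transform c_j = sqrt(2/N_f) sum_m log(S_m) cos(j*pi/N_f*(m-0.5)).

    Rows are j = 1..n_coeffs when drop_c0 (the zeroth coefficient, the mean
    log energy, is discarded), else j = 0..n_coeffs-1.
    """
    j0 = 1 if drop_c0 else 0
    j = np.arange(j0, j0 + n_coeffs)[:, None]
    m = np.arange(1, n_filters + 1)[None, :]
    return np.sqrt(2.0 / n_filters) * np.cos(j * np.pi / n_filters * (m - 0.5))


def mfcc(signal: np.ndarray, sampling_rate_hz: float,
         p: MfccParams | None = None) -> np.ndarray:
    """Per-frame MFCC matrix (n_frames x n_coeffs) of a 1-D signal.

    Pipeline: pre-emphasis, framing, Hamming window, magnitude spectrum,
    mel filterbank energies, log (floored at 1e-10 so silent frames never
    raise), cosine transform.  Deterministic: no hidden randomness.
    """
    p = p or MfccParams()
    x = pre_emphasize(signal, p.pre_emphasis)
    frames = frame_signal(x, p.frame_length, p.hop)
    frames = frames * hamming_window(p.frame_length)
    spec = np.abs(np.fft.rfft(frames, n=p.fft_length, axis=1))
    fb = mel_filterbank(p.n_filters, p.fft_length, sampling_rate_hz,
                        p.mel_denominator, p.mel_variant)
    energies = spec @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    basis = _dct_basis(p.n_coeffs, p.n_filters, p.drop_c0)
    return log_e @ basis.T


# ---------------------------------------------------------------------------
# epoch-level extraction


def extract_features(es: EpochSet, p: MfccParams | None = None,
                     domains: str = "both") -> FeatureMatrix:
    """Concatenate per-channel features over all epochs.

    Order is fixed: channels in ``es.channel_names`` order; within a
    channel, time-domain statistics first (when requested) then MFCC
    coefficients 1..n averaged over frames.  Feature names look like
    ``ch03.mad`` / ``ch03.mfcc07``.
    """
    p = p or MfccParams()
    if domains not in ("time", "mfcc", "both"):
        raise ValueError(f"unknown feature domain {domains!r}")
    want_time = domains in ("time", "both")
    want_mfcc = domains in ("mfcc", "both")

    names: list[str] = []
    for ci in range(es.n_channels):
        tag = f"ch{ci:02d}"
        if want_time:
            names.extend(f"{tag}.{n}" for n in TIME_FEATURE_NAMES)
        if want_mfcc:
            j0 = 1 if p.drop_c0 else 0
            names.extend(f"{tag}.mfcc{j + j0:02d}" for j in range(p.n_coeffs))

    rows = np.empty((len(es), len(names)))
    for ri, ep in enumerate(es.epochs):
        parts = []
        for ci in range(es.n_channels):
            sig = ep.samples[ci]
            if want_time:
                parts.append(time_domain_features(sig))
            if want_mfcc:
                coeffs = mfcc(sig, es.sampling_rate_hz, p)
                parts.append(coeffs.mean(axis=0))  # mean over frames
        rows[ri] = np.concatenate(parts)
    if not np.all(np.isfinite(rows)):
        raise InvariantError("non-finite feature value produced")
    return FeatureMatrix(
        values=rows,
        feature_names=names,
        epoch_ids=[ep.epoch_id for ep in es.epochs],
        labels=None if np.any(es.labels() < 0) else es.labels(),
    )
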