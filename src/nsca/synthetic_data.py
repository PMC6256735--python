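"""Synthetic four-class motor-imagery EEG sessions.

Emulates an epoched 22-channel, 250 Hz recording session: per trial a
4-second imagery window whose class is betrayed by narrowband
oscillations (mu/beta-range rhythms) on a class-specific channel subset,
buried in Gaussian white noise on every channel.  The four default
signatures use disjoint channel groups and distinct center frequencies so
classes are separable in principle; the noise level controls how hard the
pipeline has to work.  Label balance is exact (epochs_per_class each) and
generation is fully deterministic given the seed.

Noise is white rather than 1/f: simpler, and sufficient to exercise
separability; a pink-noise option would be a natural extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Epoch, EpochSet, InvariantError


@dataclass
class ClassSignature:
    channels: tuple[int, ...]
    center_freq_hz: float
    bandwidth_hz: float
    amplitude: float


@dataclass
class SimParams:
    n_channels: int = 22
    sampling_rate_hz: float = 250.0
    window_s: tuple[float, float] = (2.0, 6.0)
    epochs_per_class: int = 72  # 288 trials per session / 4 classes
    class_signatures: dict[int, ClassSignature] | None = None
    noise_sd: float = 0.5
    amplitude_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_per_class < 1:
            raise InvariantError("epochs_per_class must be >= 1")
        if self.class_signatures is None:
            self.class_signatures = default_signatures()
        nyq = self.sampling_rate_hz / 2.0
        for cls, sig in self.class_signatures.items():
            if sig.center_freq_hz >= nyq:
                raise InvariantError(
                    f"class {cls} frequency {sig.center_freq_hz} Hz is at or "
                    f"above Nyquist ({nyq} Hz)"
                )


def default_signatures() -> dict[int, ClassSignature]:
    """Four mutually distinguishable signatures on disjoint channel groups.

    Frequencies sit in the mu (10, 12 Hz) and beta (20, 24 Hz) bands where
    real motor rhythms live; amplitudes are equal across classes.
    """
    return {
        1: ClassSignature(channels=(0, 1, 2, 3, 4), center_freq_hz=10.0,
                          bandwidth_hz=0.0, amplitude=1.0),
        2: ClassSignature(channels=(5, 6, 7, 8, 9), center_freq_hz=12.0,
                          bandwidth_hz=0.0, amplitude=1.0),
        3: ClassSignature(channels=(10, 11, 12, 13, 14), center_freq_hz=20.0,
                          bandwidth_hz=0.0, amplitude=1.0),
        4: ClassSignature(channels=(15, 16, 17, 18, 19), center_freq_hz=24.0,
                          bandwidth_hz=0.0, amplitude=1.0),
    }


def generate_session(p: SimParams | None = None) -> EpochSet:
    """One labeled session: epochs_per_class trials of each class.

    Per class-k epoch, every signature channel carries
    ``A * (1 + jitter) * sin(2*pi*f*t + phase)`` with a uniformly random
    phase, an amplitude jittered by a centered uniform factor, and a
    frequency drawn uniformly inside the signature band; independent
    Gaussian noise of sd ``noise_sd`` is added on all channels.

    Signal and noise use separate seeded streams so sessions differing
    only in ``noise_sd`` share the identical underlying signal.
    """
    p = p or SimParams()
    sig_ss, noise_ss = np.random.SeedSequence(p.seed).spawn(2)
    rng_sig = np.random.default_rng(sig_ss)
    rng_noise = np.random.default_rng(noise_ss)
    n_s = int(round((p.window_s[1] - p.window_s[0]) * p.sampling_rate_hz))
    t = np.arange(n_s) / p.sampling_rate_hz
    epochs = []
    idx = 0
    for cls in sorted(p.class_signatures):
        sig = p.class_signatures[cls]
        for _ in range(p.epochs_per_class):
            samples = np.zeros((p.n_channels, n_s))
            for ch in sig.channels:
                phase = rng_sig.uniform(0.0, 2.0 * np.pi)
                amp = sig.amplitude * (
                    1.0 + p.amplitude_jitter * rng_sig.uniform(-1.0, 1.0)
                )
                freq = sig.center_freq_hz
                if sig.bandwidth_hz > 0:
                    freq += rng_sig.uniform(-0.5, 0.5) * sig.bandwidth_hz
                samples[ch] += amp * np.sin(2.0 * np.pi * freq * t + phase)
            samples += p.noise_sd * rng_noise.standard_normal(samples.shape)
            epochs.append(Epoch(f"ep{idx:04d}", cls, samples))
            idx += 1
    return EpochSet(
        epochs=epochs,
        channel_names=[f"EEG{c:02d}" for c in range(p.n_channels)],
        sampling_rate_hz=p.sampling_rate_hz,
        window_s=p.window_s,
        provenance={"generator": "nsca.synthetic_data", "seed": p.seed,
                    "noise_sd": p.noise_sd,
                    "epochs_per_class": p.epochs_per_class},
    )


def snr_sweep(p: SimParams, noise_levels: list[float]) -> list[EpochSet]:
    """One session per noise level, sharing the identical signal component."""
    if not noise_levels:
        raise InvariantError("need at least one noise level")
    sessions = []
    for level in noise_levels:
        q = SimParams(
            n_channels=p.n_channels,
            sampling_rate_hz=p.sampling_rate_hz,
            window_s=p.window_s,
            epochs_per_class=p.epochs_per_class,
            class_signatures=p.class_signatures,
            noise_sd=level,
            amplitude_jitter=p.amplitude_jitter,
            seed=p.seed,
        )
        sessions.append(generate_session(q))
    return sessions
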