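"""Optional adapter for GDF recordings (BCI Competition IV dataset 2a).

Delegates parsing to MNE (optional dependency, ``pip install nsca[gdf]``)
and extracts the 2.0-6.0 s post-cue imagery window of each cued trial.
The core pipeline never depends on this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io_core import Epoch, EpochSet, FormatError

# standard Graz 2a event codes for the four cues
CUE_EVENTS = {"769": 1, "770": 2, "771": 3, "772": 4}


def load_gdf_epochs(path, window_s: tuple[float, float] = (2.0, 6.0),
                    n_eeg_channels: int = 22) -> EpochSet:
    """Epoch a Graz 2a GDF recording into the post-cue imagery window."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "the GDF adapter requires mne; install the 'gdf' extra"
        ) from e
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing {path}")
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    picks = raw.ch_names[:n_eeg_channels]  # EOG channels trail the montage
    fs = float(raw.info["sfreq"])
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_to_class = {
        code: cls for name, cls in CUE_EVENTS.items()
        for key, code in event_id.items() if key == name
    }
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    n_s = int(round((window_s[1] - window_s[0]) * fs))
    epochs = []
    for i, (onset, _, code) in enumerate(events):
        cls = code_to_class.get(code)
        if cls is None:
            continue
        start = onset + int(round(window_s[0] * fs))
        if start + n_s > data.shape[1]:
            continue
        epochs.append(
            Epoch(f"trial{i:04d}", cls,
                  np.array(data[:, start:start + n_s]))
        )
    return EpochSet(
        epochs=epochs,
        channel_names=list(picks),
        sampling_rate_hz=fs,
        window_s=window_s,
        provenance={"source": str(path), "reader": "mne"},
    )
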