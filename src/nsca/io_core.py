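"""Data containers, interchange formats and configuration.

The pipeline operates on epoched multichannel EEG: an :class:`EpochSet`
holds labeled trials (channels x time, microvolts), a :class:`FeatureMatrix`
holds one real-valued feature vector per trial, and :class:`PipelineConfig`
collects every tunable knob of the feature -> autoencoder -> detector chain.

Interchange is plain text: a long-format ``epochs.csv``
(``epoch_id,label,channel,sample_index,value``) next to a ``meta.json``
carrying channel names, sampling rate, analysis window and provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

VALID_LABELS = (1, 2, 3, 4)


class FormatError(ValueError):
    """Malformed interchange file."""


class InvariantError(ValueError):
    """A container invariant is violated."""


@dataclass
class Epoch:
    epoch_id: str
    label: int | None  # 1..4, or None when unlabeled
    samples: np.ndarray  # channels x time, microvolts


@dataclass
class EpochSet:
    """Ordered collection of equally shaped labeled EEG epochs."""

    epochs: list[Epoch]
    channel_names: list[str]
    sampling_rate_hz: float
    window_s: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvariantError("sampling_rate_hz must be positive")
        start, end = self.window_s
        expected = int(round((end - start) * self.sampling_rate_hz))
        n_ch = len(self.channel_names)
        for ep in self.epochs:
            ep.samples = np.asarray(ep.samples, dtype=float)
            if ep.samples.ndim != 2:
                raise InvariantError(f"epoch {ep.epoch_id}: samples must be 2-D")
            if ep.samples.shape[0] != n_ch:
                raise InvariantError(
                    f"epoch {ep.epoch_id}: {ep.samples.shape[0]} channels, "
                    f"expected {n_ch}"
                )
            if ep.samples.shape[1] != expected:
                raise InvariantError(
                    f"epoch {ep.epoch_id}: {ep.samples.shape[1]} samples, "
                    f"expected {expected} for window {self.window_s} at "
                    f"{self.sampling_rate_hz} Hz"
                )
            if ep.label is not None and ep.label not in VALID_LABELS:
                raise InvariantError(
                    f"epoch {ep.epoch_id}: label {ep.label} not in 1..4"
                )

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        start, end = self.window_s
        return int(round((end - start) * self.sampling_rate_hz))

    def labels(self) -> np.ndarray:
        return np.array(
            [-1 if ep.label is None else ep.label for ep in self.epochs]
        )


@dataclass
class FeatureMatrix:
    """Per-epoch feature vectors; rows follow epoch order.

    ``normalization_bounds`` is a ``(2, Q)`` array of per-dimension
    ``(min, max)`` recorded at training time so test rows can be rescaled
    with the same affine map.
    """

    values: np.ndarray  # n_epochs x Q
    feature_names: list[str]
    epoch_ids: list[str]
    labels: np.ndarray | None = None  # per-row class 1..4, or None
    normalization_bounds: np.ndarray | None = None  # 2 x Q (min row, max row)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvariantError("values must be 2-D (rows x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise InvariantError("feature_names length must match columns")
        if self.values.shape[0] != len(self.epoch_ids):
            raise InvariantError("epoch_ids length must match rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise InvariantError("labels length must match rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            epoch_ids=[self.epoch_ids[i] for i in np.atleast_1d(idx)],
            labels=None if self.labels is None else self.labels[idx],
            normalization_bounds=self.normalization_bounds,
        )

    def select_columns(self, cols: Sequence[int], names: list[str] | None = None
                       ) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_names=[self.feature_names[c] for c in cols],
            epoch_ids=list(self.epoch_ids),
            labels=self.labels,
            normalization_bounds=(
                None if self.normalization_bounds is None
                else self.normalization_bounds[:, cols]
            ),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "epoch_id", self.epoch_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "epoch_id" not in df.columns:
            raise FormatError(f"{path}: missing epoch_id column")
        labels = None
        feature_cols = [c for c in df.columns if c not in ("epoch_id", "label")]
        if "label" in df.columns:
            labels = df["label"].to_numpy(dtype=int)
        return cls(
            values=df[feature_cols].to_numpy(dtype=float),
            feature_names=feature_cols,
            epoch_ids=[str(e) for e in df["epoch_id"]],
            labels=labels,
        )


@dataclass
class PipelineConfig:
    """Flat bag of hyperparameters for the whole pipeline.

    Serializes to/from a flat snake_case YAML mapping.
    """

    # MFCC
    n_coeffs: int = 12
    n_filters: int = 20
    frame_length: int = 64
    hop: int = 32
    pre_emphasis: float = 0.97
    mel_denominator: float = 100.0
    fft_length: int = 128
    drop_c0: bool = True
    # SAE
    h1: int = 16
    h2: int = 8
    weight_decay: float = 1e-4  # lambda
    sparsity_weight: float = 0.1  # beta
    sparsity_target: float = 0.05  # rho
    sae_epochs: int = 500
    learning_rate: float = 0.1
    sae_seed: int = 0
    # GA / detectors
    population_size: int = 50
    generations: int = 100
    crossover_points: int = 2
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1/chromosome_bits
    bits_per_gene: int = 16
    delta: float = 1.0
    elitism_count: int = 1
    r_self: float = 0.05
    n_detectors: int = 30
    ga_seed: int = 0
    # decision / evaluation
    decision_rule: str = "match_means_class"
    holdout_fraction: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n_coeffs", "n_filters", "frame_length", "hop",
                     "fft_length", "h1", "h2", "sae_epochs",
                     "population_size", "generations", "bits_per_gene",
                     "n_detectors"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be positive")
        if not 0 < self.holdout_fraction < 1:
            raise InvariantError("holdout_fraction must be in (0, 1)")
        if not 0.9 <= self.pre_emphasis <= 0.99:
            warnings.warn(
                f"pre_emphasis={self.pre_emphasis} is outside the customary "
                "[0.9, 0.99] range",
                stacklevel=2,
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# epochs.csv + meta.json interchange


def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to ``path/epochs.csv`` + ``path/meta.json``.

    Values are written with 17 significant digits so the round trip is
    bit-exact for doubles.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_ch, n_s = es.n_channels, es.n_samples
    rows = []
    for ep in es.epochs:
        label = "" if ep.label is None else ep.label
        ch_idx = np.repeat(np.arange(n_ch), n_s)
        s_idx = np.tile(np.arange(n_s), n_ch)
        rows.append(pd.DataFrame({
            "epoch_id": ep.epoch_id,
            "label": label,
            "channel": np.asarray(es.channel_names)[ch_idx],
            "sample_index": s_idx,
            "value": ep.samples.ravel(),
        }))
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["epoch_id", "label", "channel", "sample_index", "value"]
        )
    df.to_csv(path / "epochs.csv", index=False, float_format="%.17g")
    meta = {
        "channel_names": list(es.channel_names),
        "sampling_rate_hz": es.sampling_rate_hz,
        "window_s": list(es.window_s),
        "provenance": es.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path, format: str = "csv_long",
                **adapter_kw) -> EpochSet:
    """Load an EpochSet from disk.

    ``format='csv_long'`` reads the ``epochs.csv`` + ``meta.json`` pair.
    ``format='gdf_adapter'`` delegates to an external GDF reader (optional
    dependency) and extracts the 2.0-6.0 s post-cue imagery window.
    """
    if format == "gdf_adapter":
        from .gdf_adapter import load_gdf_epochs

        return load_gdf_epochs(path, **adapter_kw)
    if format != "csv_long":
        raise ValueError(f"unknown format {format!r}")

    path = Path(path)
    csv_path, meta_path = path / "epochs.csv", path / "meta.json"
    if not csv_path.exists():
        raise FormatError(f"missing {csv_path}")
    if not meta_path.exists():
        raise FormatError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("channel_names", "sampling_rate_hz", "window_s"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key {key!r}")
    channel_names = list(meta["channel_names"])
    fs = float(meta["sampling_rate_hz"])
    window = tuple(float(x) for x in meta["window_s"])

    df = pd.read_csv(csv_path, dtype={"epoch_id": str})
    required = {"epoch_id", "label", "channel", "sample_index", "value"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{csv_path}: header must contain {sorted(required)}"
        )
    n_s = int(round((window[1] - window[0]) * fs))
    ch_pos = {name: i for i, name in enumerate(channel_names)}
    epochs: list[Epoch] = []
    if len(df):
        for epoch_id, grp in df.groupby("epoch_id", sort=False):
            labels = grp["label"].dropna().unique()
            if len(labels) > 1:
                raise FormatError(
                    f"{csv_path}: epoch {epoch_id} has conflicting labels"
                )
            label = None
            if len(labels) == 1 and str(labels[0]) != "":
                label = int(float(labels[0]))
                if label not in VALID_LABELS:
                    raise InvariantError(
                        f"{csv_path}: epoch {epoch_id} label {label} not in 1..4"
                    )
            samples = np.full((len(channel_names), n_s), np.nan)
            try:
                ci = grp["channel"].map(ch_pos).to_numpy()
            except KeyError as e:  # pragma: no cover - map returns NaN instead
                raise FormatError(f"{csv_path}: unknown channel {e}") from e
            if np.any(pd.isna(ci)):
                bad = grp.loc[pd.isna(ci), "channel"].iloc[0]
                raise FormatError(
                    f"{csv_path}: epoch {epoch_id} references unknown "
                    f"channel {bad!r}"
                )
            si = grp["sample_index"].to_numpy(dtype=int)
            if si.min() < 0 or si.max() >= n_s:
                raise FormatError(
                    f"{csv_path}: epoch {epoch_id} sample_index out of range"
                )
            samples[ci.astype(int), si] = grp["value"].to_numpy(dtype=float)
            if np.any(np.isnan(samples)):
                raise FormatError(
                    f"{csv_path}: epoch {epoch_id} is missing samples"
                )
            epochs.append(Epoch(str(epoch_id), label, samples))
    return EpochSet(
        epochs=epochs,
        channel_names=channel_names,
        sampling_rate_hz=fs,
        window_s=window,  # type: ignore[arg-type]
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# normalization


def normalize_features(fm: FeatureMatrix,
                       bounds: np.ndarray | None = None) -> FeatureMatrix:
    """Rescale every feature dimension to [0, 1].

    When ``bounds`` is None the per-dimension min/max are computed from the
    input rows (training behaviour) and stored on the result; otherwise the
    supplied training bounds are reused and out-of-range values are clipped
    to [0, 1] so detector geometry stays inside the unit hypercube.
    Constant dimensions map to 0.5.
    """
    if fm.values.shape[0] == 0:
        raise InvariantError("cannot normalize an empty FeatureMatrix")
    if bounds is None:
        lo = fm.values.min(axis=0)
        hi = fm.values.max(axis=0)
        bounds = np.vstack([lo, hi])
    else:
        bounds = np.asarray(bounds, dtype=float)
        lo, hi = bounds[0], bounds[1]
    span = hi - lo
    if np.any(span < 0):
        raise InvariantError("normalization bounds have max < min")
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (fm.values - lo) / safe_span
    scaled[:, constant] = 0.5
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        values=scaled,
        feature_names=list(fm.feature_names),
        epoch_ids=list(fm.epoch_ids),
        labels=fm.labels,
        normalization_bounds=bounds,
    )
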