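"""End-to-end four-class negative-selection classification.

Training chains the stages: normalize features to [0, 1], fit the stacked
autoencoder, reduce, then evolve one GA-optimized detector set per class.
Under the default ``match_means_class`` convention the SELF set for class
k is the reduced rows of the OTHER three classes, so set-k detectors tile
class-k territory and a monitoring match directly predicts class k.  The
alternative ``match_means_nonself`` convention (SELF = class k itself) is
retained behind a flag.

Classification normalizes a sample with the training bounds, reduces it,
monitors it against all four sets and picks the set with the largest
margin (max over detectors of radius - distance); when nothing matches,
the least negative margin wins, residual ties going to the lowest class
label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (FeatureMatrix, InvariantError, PipelineConfig,
                      normalize_features)
from .feature_selection import holdout_split
from . import sae
from .nsa_core import DetectorSet, SelfSet, monitor_batch
from .ga_optimizer import GaParams, generate_detector_set

CLASSES = (1, 2, 3, 4)


@dataclass
class ConfusionMatrix:
    """4x4 count matrix; rows = true class, columns = predicted, order 1..4."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise InvariantError("confusion matrix must be 4x4")
        if np.any(self.counts < 0):
            raise InvariantError("confusion counts must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts,
                     index=[f"true_{c}" for c in CLASSES],
                     columns=[f"pred_{c}" for c in CLASSES]
                     ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        return cls(pd.read_csv(path, index_col=0).to_numpy())


@dataclass
class NscaModel:
    stack: sae.AutoencoderStack
    normalization_bounds: np.ndarray  # 2 x Q
    detector_sets: dict[int, DetectorSet]  # class label -> set
    decision_rule: str
    config: PipelineConfig

    def __post_init__(self) -> None:
        if sorted(self.detector_sets) != list(CLASSES):
            raise InvariantError("need exactly one detector set per class 1..4")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        sae.save_stack(self.stack, path / "stack")
        np.savetxt(path / "bounds.txt", self.normalization_bounds,
                   fmt="%.17g")
        for cls, ds in self.detector_sets.items():
            ds.to_json(path / f"detectors_class{cls}.json")
        (path / "model.json").write_text(json.dumps({
            "decision_rule": self.decision_rule,
            "config": asdict(self.config),
        }, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NscaModel":
        path = Path(path)
        header = json.loads((path / "model.json").read_text())
        return cls(
            stack=sae.load_stack(path / "stack"),
            normalization_bounds=np.loadtxt(path / "bounds.txt", ndmin=2),
            detector_sets={
                c: DetectorSet.from_json(path / f"detectors_class{c}.json")
                for c in CLASSES
            },
            decision_rule=header["decision_rule"],
            config=PipelineConfig(**header["config"]),
        )


def _ga_params(cfg: PipelineConfig, seed: int) -> GaParams:
    return GaParams(
        population_size=cfg.population_size,
        generations=cfg.generations,
        crossover_points=cfg.crossover_points,
        crossover_rate=cfg.crossover_rate,
        mutation_rate=cfg.mutation_rate,
        bits_per_gene=cfg.bits_per_gene,
        delta=cfg.delta,
        elitism_count=cfg.elitism_count,
        seed=seed,
    )


def train(fm: FeatureMatrix, cfg: PipelineConfig | None = None,
          seed: int = 0) -> NscaModel:
    """Fit normalization, the autoencoder stack and four detector sets."""
    cfg = cfg or PipelineConfig()
    if fm.labels is None:
        raise InvariantError("training needs labeled rows")
    present = set(np.unique(fm.labels))
    if not set(CLASSES) <= present:
        raise InvariantError(
            f"missing class(es): {sorted(set(CLASSES) - present)}"
        )
    norm = normalize_features(fm)
    hyper = sae.SaeHyper(
        weight_decay=cfg.weight_decay,
        sparsity_weight=cfg.sparsity_weight,
        sparsity_target=cfg.sparsity_target,
        epochs=cfg.sae_epochs,
        learning_rate=cfg.learning_rate,
    )
    stack = sae.fit_stack(norm, cfg.h1, cfg.h2, hyper,
                          seed=cfg.sae_seed + 1000003 * seed)
    reduced = sae.reduce(norm, stack)
    sets: dict[int, DetectorSet] = {}
    for cls in CLASSES:
        if cfg.decision_rule == "match_means_class":
            self_rows = reduced.values[reduced.labels != cls]
            convention = "self_is_rest"
        elif cfg.decision_rule == "match_means_nonself":
            self_rows = reduced.values[reduced.labels == cls]
            convention = "self_is_target"
        else:
            raise InvariantError(
                f"unknown decision rule {cfg.decision_rule!r}"
            )
        self_set = SelfSet(rows=self_rows, r_self=cfg.r_self)
        rng = np.random.default_rng(
            (cfg.ga_seed + 1000003 * seed + 7919 * cls) % (2 ** 31)
        )
        sets[cls] = generate_detector_set(
            self_set, cfg.n_detectors, _ga_params(cfg, seed), rng,
            class_label=cls, self_convention=convention,
        )
    return NscaModel(
        stack=stack,
        normalization_bounds=norm.normalization_bounds,
        detector_sets=sets,
        decision_rule=cfg.decision_rule,
        config=cfg,
    )


def _reduced_margins(X: np.ndarray, model: NscaModel) -> np.ndarray:
    """n_samples x 4 margin matrix in class order 1..4."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.normalization_bounds.shape[1]:
        raise InvariantError(
            f"sample dimension {X.shape[1]} != model input "
            f"{model.normalization_bounds.shape[1]}"
        )
    lo, hi = model.normalization_bounds
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    Z = np.clip((X - lo) / span, 0.0, 1.0)
    Z[:, hi - lo == 0] = 0.5
    R = sae.reduce_rows(Z, model.stack)
    margins = np.empty((X.shape[0], 4))
    for j, cls in enumerate(CLASSES):
        _, margins[:, j] = monitor_batch(R, model.detector_sets[cls])
    return margins


def classify(sample: np.ndarray, model: NscaModel
             ) -> tuple[int, np.ndarray]:
    """(predicted class, per-class margins) for one raw feature vector."""
    margins = _reduced_margins(np.asarray(sample, float)[None, :], model)[0]
    return int(CLASSES[int(np.argmax(margins))]), margins


def classify_batch(fm: FeatureMatrix | np.ndarray, model: NscaModel
                   ) -> np.ndarray:
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    margins = _reduced_margins(X, model)
    return np.asarray(CLASSES)[np.argmax(margins, axis=1)]


def evaluate(fm: FeatureMatrix, model: NscaModel) -> ConfusionMatrix:
    """Confusion matrix of the model on labeled rows."""
    if fm.labels is None:
        raise InvariantError("evaluate needs labeled rows")
    pred = classify_batch(fm, model)
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(fm.labels, pred):
        counts[t - 1, p - 1] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    total = cm.counts.sum()
    if total == 0:
        raise InvariantError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def detection_accuracy(fm: FeatureMatrix, ds: DetectorSet,
                       model: NscaModel) -> float:
    """Agreement between match outcome and self/nonself status for one set.

    Under ``self_is_rest`` a set-k detector should match exactly the
    class-k samples; under ``self_is_target`` exactly the non-k samples.
    """
    if fm.labels is None:
        raise InvariantError("detection_accuracy needs labeled rows")
    lo, hi = model.normalization_bounds
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    Z = np.clip((fm.values - lo) / span, 0.0, 1.0)
    Z[:, hi - lo == 0] = 0.5
    R = sae.reduce_rows(Z, model.stack)
    matched, _ = monitor_batch(R, ds)
    if ds.self_convention == "self_is_rest":
        should_match = fm.labels == ds.class_label
    else:
        should_match = fm.labels != ds.class_label
    return float(np.mean(matched == should_match))


@dataclass
class GridResult:
    table: pd.DataFrame  # columns h1, h2, n_detectors, detection_accuracy
    best: tuple[int, int, int]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def grid_cells(h1_range=range(15, 20), h2_range=range(6, 11),
               nd_range=range(25, 71, 5)) -> list[tuple[int, int, int]]:
    """Enumerate every (H1, H2, N_d) combination of the search grid."""
    return list(product(h1_range, h2_range, nd_range))


def grid_search(fm: FeatureMatrix, h1_range=range(15, 20),
                h2_range=range(6, 11), nd_range=range(25, 71, 5),
                cfg: PipelineConfig | None = None, seed: int = 0
                ) -> GridResult:
    """Evaluate every grid cell on a stratified holdout split.

    Each cell trains the full model on the training side and scores the
    mean per-class detection accuracy on the validation side.  Ties break
    toward smaller N_d, then smaller H1 + H2, then enumeration order.
    """
    cfg = cfg or PipelineConfig()
    cells = grid_cells(h1_range, h2_range, nd_range)
    if not cells:
        raise InvariantError("empty grid")
    tr, va = holdout_split(fm, cfg.holdout_fraction, seed)
    fm_tr, fm_va = fm.select_rows(tr), fm.select_rows(va)
    records = []
    best_key, best = None, None
    for i, (h1, h2, nd) in enumerate(cells):
        cell_cfg = cfg.with_overrides(h1=h1, h2=h2, n_detectors=nd)
        model = train(fm_tr, cell_cfg, seed=seed)
        acc = float(np.mean([
            detection_accuracy(fm_va, model.detector_sets[c], model)
            for c in CLASSES
        ]))
        records.append({"h1": h1, "h2": h2, "n_detectors": nd,
                        "detection_accuracy": acc})
        key = (-acc, nd, h1 + h2, i)
        if best_key is None or key < best_key:
            best_key, best = key, (h1, h2, nd)
    return GridResult(table=pd.DataFrame.from_records(records), best=best)


def summarize_runs(accuracies: list[float]
                   ) -> tuple[float, float, float, int, bool]:
    """(mean, sample SD, max, 1-based argmax, degenerate flag).

    The SD uses the n-1 denominator; a singleton list reports SD 0 with
    the degenerate flag set.
    """
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise InvariantError("no accuracies to summarize")
    degenerate = a.size == 1
    sd = 0.0 if degenerate else float(np.std(a, ddof=1))
    return (float(a.mean()), sd, float(a.max()),
            int(np.argmax(a)) + 1, degenerate)
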