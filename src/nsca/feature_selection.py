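"""Wrapper-style feature subset selection.

Candidate feature sets (by default the domain-level groups: time-domain
statistics, MFCCs, or both) are each handed to an induction algorithm as a
black box; the candidate whose classifier reaches the highest holdout
validation accuracy wins.  The default evaluator is a multiclass
max-margin classifier (SVM with library defaults), but any callable
mapping (train, validation) feature matrices to an accuracy works — the
negative-selection classifier itself can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_core import FeatureMatrix, InvariantError


@dataclass
class CandidateSet:
    name: str
    columns: list[int]

    def __post_init__(self) -> None:
        if not self.columns:
            raise InvariantError(f"candidate {self.name!r} is empty")
        if len(set(self.columns)) != len(self.columns):
            raise InvariantError(f"candidate {self.name!r} repeats columns")


def domain_candidates(fm: FeatureMatrix) -> list[CandidateSet]:
    """The three standard candidates: time statistics, MFCCs, both."""
    time_cols = [i for i, n in enumerate(fm.feature_names)
                 if ".mfcc" not in n]
    mfcc_cols = [i for i, n in enumerate(fm.feature_names) if ".mfcc" in n]
    cands = []
    if time_cols:
        cands.append(CandidateSet("time", time_cols))
    if mfcc_cols:
        cands.append(CandidateSet("mfcc", mfcc_cols))
    if time_cols and mfcc_cols:
        cands.append(CandidateSet("both", time_cols + mfcc_cols))
    return cands


def holdout_split(fm: FeatureMatrix, train_fraction: float, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation row indices; exact partition.

    Per class, ``round(train_fraction * n_class)`` rows go to training
    (shuffled with the seeded generator), the rest to validation; both
    sides keep at least one row per class.
    """
    if fm.labels is None:
        raise InvariantError("holdout_split needs labeled rows")
    if not 0 < train_fraction < 1:
        raise InvariantError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(fm.labels):
        rows = np.where(fm.labels == cls)[0]
        if rows.size < 2:
            raise InvariantError(
                f"class {cls} has {rows.size} row(s); need >= 2 to split"
            )
        n_train = int(round(train_fraction * rows.size))
        n_train = min(max(n_train, 1), rows.size - 1)
        perm = rng.permutation(rows)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def svm_evaluator(train: FeatureMatrix, val: FeatureMatrix, **svc_kw) -> float:
    """Default induction algorithm: SVC fit on train, accuracy on validation."""
    clf = SVC(**svc_kw)
    clf.fit(train.values, train.labels)
    return float(np.mean(clf.predict(val.values) == val.labels))


Evaluator = Callable[[FeatureMatrix, FeatureMatrix], float]


def wrapper_select(fm: FeatureMatrix,
                   candidates: Sequence[CandidateSet] | None = None,
                   evaluator: Evaluator = svm_evaluator,
                   train_fraction: float = 0.7,
                   seed: int = 0) -> tuple[CandidateSet, pd.DataFrame]:
    """Evaluate every candidate on one stratified holdout split.

    Returns the winning candidate and a report with one accuracy per
    candidate.  Ties go to the candidate with fewer columns, then to input
    order.
    """
    if candidates is None:
        candidates = domain_candidates(fm)
    if not candidates:
        raise InvariantError("no candidate feature sets supplied")
    tr, va = holdout_split(fm, train_fraction, seed)
    records = []
    best_key, best_i = None, None
    for i, cand in enumerate(candidates):
        sub = fm.select_columns(cand.columns)
        acc = float(evaluator(sub.select_rows(tr), sub.select_rows(va)))
        records.append(
            {"candidate": cand.name, "n_features": len(cand.columns),
             "accuracy": acc}
        )
        key = (-acc, len(cand.columns), i)
        if best_key is None or key < best_key:
            best_key, best_i = key, i
    report = pd.DataFrame.from_records(records)
    return candidates[best_i], report
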