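"""Real-valued negative selection: affinity, censoring and monitoring.

A detector is a hypersphere (center, radius) living in the normalized
feature space [0, 1]^Q.  The self set is the collection of training
vectors the detectors must tolerate, each padded by a self radius R_self.
Censoring rejects candidate detectors that would cover a self sample;
monitoring tests unseen samples against the mature detector set, a sample
matching when its Euclidean distance to some center is strictly below
that detector's radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import InvariantError

R_MIN = 1e-3  # minimum useful detector radius in normalized space


@dataclass
class Detector:
    center: np.ndarray
    radius: float
    fitness: float = np.nan
    id: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise InvariantError("detector radius must be positive")
        if np.any(self.center < 0) or np.any(self.center > 1):
            raise InvariantError("detector center must lie in [0, 1]^Q")


@dataclass
class SelfSet:
    """Training vectors a detector set must tolerate, with self radius."""

    rows: np.ndarray  # K x Q, in [0, 1]
    r_self: float = 0.05

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] == 0:
            raise InvariantError("self set is empty")
        if np.any(self.rows < 0) or np.any(self.rows > 1):
            raise InvariantError("self rows must lie in [0, 1]^Q")


@dataclass
class DetectorSet:
    detectors: list[Detector]
    class_label: int
    r_self: float = 0.05
    self_convention: str = "self_is_rest"

    def __post_init__(self) -> None:
        dims = {d.center.size for d in self.detectors}
        if len(dims) > 1:
            raise InvariantError("detectors disagree on dimension")

    def __len__(self) -> int:
        return len(self.detectors)

    def centers(self) -> np.ndarray:
        return np.vstack([d.center for d in self.detectors])

    def radii(self) -> np.ndarray:
        return np.array([d.radius for d in self.detectors])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "class_label": self.class_label,
            "R_self": self.r_self,
            "convention": self.self_convention,
            "detectors": [
                {"id": d.id, "center": d.center.tolist(),
                 "radius": d.radius, "fitness": d.fitness}
                for d in self.detectors
            ],
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "DetectorSet":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        data = json.loads(text)
        return cls(
            detectors=[
                Detector(np.array(d["center"]), d["radius"],
                         d.get("fitness", np.nan), d.get("id", i))
                for i, d in enumerate(data["detectors"])
            ],
            class_label=data["class_label"],
            r_self=data["R_self"],
            self_convention=data.get("convention", "self_is_rest"),
        )


def affinity(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvariantError("affinity arguments must have equal length")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def max_safe_radius(center: np.ndarray, self_set: SelfSet) -> float:
    """Largest radius keeping every self sample outside the detector.

    min_k dist(center, self_k) - R_self; can be <= 0 when the candidate
    overlaps the padded self region.
    """
    center = np.atleast_2d(np.asarray(center, dtype=float))
    d = cdist(center, self_set.rows).min()
    return float(d - self_set.r_self)


def censor(candidate: Detector, self_set: SelfSet) -> bool:
    """True (accepted) iff the candidate clears the self region by > R_MIN.

    Accepted candidates must not reach any self sample: their radius is
    capped at the maximal safe radius.
    """
    safe = max_safe_radius(candidate.center, self_set)
    if safe <= R_MIN:
        return False
    if candidate.radius > safe:
        candidate.radius = safe
    return True


def monitor(sample: np.ndarray, ds: DetectorSet
            ) -> tuple[bool, int, float]:
    """(matched, best_detector_id, margin) for one sample.

    A match requires distance strictly below the detector's radius.  The
    best detector maximizes (radius - distance); that maximum is the
    margin (negative when nothing matches).  Ties go to the lowest id.
    """
    if len(ds) == 0:
        raise InvariantError("empty detector set")
    sample = np.asarray(sample, dtype=float)
    centers = ds.centers()
    if sample.size != centers.shape[1]:
        raise InvariantError("sample dimension mismatch")
    d = cdist(sample[None, :], centers)[0]
    margins = ds.radii() - d
    best = int(np.argmax(margins))  # argmax returns the first (lowest id)
    margin = float(margins[best])
    matched = bool(d[best] < ds.detectors[best].radius)
    return matched, ds.detectors[best].id, margin


def monitor_batch(samples: np.ndarray, ds: DetectorSet
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(matched bool array, margin array) for a batch of samples."""
    if len(ds) == 0:
        raise InvariantError("empty detector set")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    margins = ds.radii()[None, :] - cdist(samples, ds.centers())
    best = margins.max(axis=1)
    return best > 0, best
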