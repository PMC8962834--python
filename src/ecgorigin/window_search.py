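"""Exhaustive beat-window-size search with a fixed random-forest evaluator.

The first stage of the experiment: for every candidate window width
(by default 200..1,000 samples in steps of 10, i.e. 100..500 ms at
2 kHz), build R-peak-referenced features for the training and
validation cohorts, fit a seeded random forest with fixed default
hyperparameters, and record the validation accuracy.  The best window
is the argmax, ties broken toward the smallest window (cheaper
features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ecg_data import Dataset
from .preprocess import WindowConfig, build_feature_matrix

__all__ = [
    "WindowSearchResult",
    "candidate_windows",
    "evaluate_window",
    "search_best_window",
]

#: Fixed evaluator hyperparameters (forest size; remaining sklearn defaults).
EVALUATOR_TREES = 100


@dataclass
class WindowSearchResult:
    candidates: tuple[int, ...]
    scores: tuple[float, ...]
    best_window: int
    evaluator_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.scores):
            raise ValueError("candidates/scores length mismatch")
        if self.best_window not in self.candidates:
            raise ValueError("best_window must be one of the candidates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window": self.candidates, "accuracy": self.scores})


def candidate_windows(min_w: int = 200, max_w: int = 1000,
                      step: int = 10) -> list[int]:
    """Arithmetic candidate grid, inclusive of ``max_w`` when it divides.

    A step not dividing the range truncates at the last value <= max_w.
    """
    if min_w < 1 or max_w < min_w:
        raise ValueError(f"invalid window bounds ({min_w}, {max_w})")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    return list(range(min_w, max_w + 1, step))


def evaluate_window(W: int, train: Dataset, val: Dataset, seed: int = 0,
                    denoise: bool = False,
                    n_estimators: int = EVALUATOR_TREES) -> float:
    """Validation accuracy of the fixed forest evaluator at window W."""
    if len(val) == 0:
        raise ValueError("validation set is empty")
    cfg = WindowConfig(W)
    fm_train = build_feature_matrix(train, cfg, denoise=denoise)
    fm_val = build_feature_matrix(val, cfg, denoise=denoise)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(fm_train.values, fm_train.labels)
    return float(forest.score(fm_val.values, fm_val.labels))


def search_best_window(candidates: list[int], train: Dataset, val: Dataset,
                       seed: int = 0, denoise: bool = False,
                       n_estimators: int = EVALUATOR_TREES) -> WindowSearchResult:
    """Evaluate every candidate; argmax with smallest-window tie break."""
    if not candidates:
        raise ValueError("candidate list is empty")
    scores = [evaluate_window(W, train, val, seed=seed, denoise=denoise,
                              n_estimators=n_estimators)
              for W in candidates]
    top = max(scores)
    best = min(W for W, s in zip(candidates, scores) if s == top)
    return WindowSearchResult(
        candidates=tuple(candidates), scores=tuple(scores),
        best_window=best,
        evaluator_config={"n_estimators": n_estimators, "seed": seed,
                          "denoise": denoise, "model": "random_forest"})
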