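"""Feature-importance heat maps and average beat morphology curves.

Tree ensembles expose impurity-based per-feature importances; reshaped
to the 12 x W (lead x window-offset) grid they show *where in the beat*
the discriminative voltage lies — clinically, lead V1 around the R peak
dominates origin discrimination.  Offsets are reported in the window
convention: the reference-line sample is point 1, so "the 10th point
after the reference line" is window offset +10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_data import LEAD_NAMES
from .model_zoo import FittedModel
from .preprocess import WindowConfig, feature_names_for

__all__ = [
    "ImportanceMap",
    "importance_map",
    "top_features",
    "average_morphology",
    "describe_offset",
]


@dataclass
class ImportanceMap:
    """12 x W nonnegative importance grid summing to 1."""

    matrix: np.ndarray
    window: WindowConfig

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (12, self.window.W):
            raise ValueError(
                f"expected shape (12, {self.window.W}), got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("importances must be nonnegative")
        if abs(self.matrix.sum() - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")

    def flat(self) -> np.ndarray:
        """Round-trip back to the flat per-feature vector (lead-major)."""
        return self.matrix.ravel()

    def plot(self, ax=None):
        """Render the heat map (leads on x, window offsets on y)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        offsets = self.window.offsets
        im = ax.imshow(self.matrix.T, aspect="auto", origin="lower",
                       extent=(-0.5, 11.5, offsets[0], offsets[-1]))
        ax.set_xticks(range(12), LEAD_NAMES)
        ax.set_xlabel("lead")
        ax.set_ylabel("window offset (reference = +1)")
        plt.colorbar(im, ax=ax, label="importance")
        return ax


def importance_map(model: FittedModel) -> ImportanceMap:
    """Impurity-based importances reshaped to the lead x offset grid.

    Only tree families expose ``feature_importances_``; wrapped or
    non-tree models raise an unsupported-family error (permutation
    importance is deliberately out of scope).
    """
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError(
            f"family {model.family!r} (wrapper {model.meta_wrapper!r}) does "
            "not expose impurity importances; use an unwrapped tree family "
            "or compute permutation importance externally")
    imp = np.asarray(est.feature_importances_, dtype=float)
    W = imp.size // 12
    if imp.size != 12 * W:
        raise ValueError("importance vector is not divisible into 12 leads")
    total = imp.sum()
    if total <= 0:
        raise ValueError("model has all-zero feature importances")
    return ImportanceMap(imp.reshape(12, W) / total, WindowConfig(W))


def describe_offset(offset: int) -> str:
    """Human naming: the reference sample is point 1 after the line."""
    o = int(offset)
    if o == 0:
        raise ValueError("offset 0 does not exist; the reference sample is +1")
    if o > 0:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(o % 10 if o % 100 not in (11, 12, 13) else 0, "th")
        return f"{o}{suffix} point after the reference line"
    m = -o
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(m % 10 if m % 100 not in (11, 12, 13) else 0, "th")
    return f"{m}{suffix} point before the reference line"


def top_features(imp: ImportanceMap, k: int) -> list[tuple[str, str, float]]:
    """The k most important (lead, offset-description, value) triples.

    Descending by importance; ties resolved by (lead order, offset).
    Requests beyond 12 W are truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = feature_names_for(imp.window)
    flat = imp.flat()
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    out = []
    for i in order[:min(k, flat.size)]:
        lead, off = names[i]
        out.append((lead, describe_offset(off), float(flat[i])))
    return out


def average_morphology(beats: np.ndarray, bandwidth: float = 5.0) -> np.ndarray:
    """Smoothed mean beat: pointwise mean + Gaussian kernel regression.

    ``beats`` is n x W (one lead, windowed).  The smoother is
    Nadaraya-Watson over the sample index with a Gaussian kernel of the
    given bandwidth (samples); as bandwidth -> 0 the output approaches
    the pointwise mean itself.
    """
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    if beats.shape[0] < 1:
        raise ValueError("need at least one beat")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    mean = beats.mean(axis=0)
    W = mean.size
    if bandwidth < 1e-6:
        return mean
    idx = np.arange(W)
    weights = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2 * bandwidth ** 2))
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ mean
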