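"""Denoising, R-peak reference location, beat windowing, feature assembly.

The model input is a fixed-width window of smoothed voltages around the
lead-II R-wave peak, concatenated across the 12 leads.  Window columns
are addressed by a signed offset relative to the reference line, with
the reference sample itself counted as the *first* point after it
(offset ``+1``); offset ``0`` does not exist.  A window of width ``W``
spans offsets ``-pre .. -1, +1 .. +post`` with ``pre = floor(W/2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import _wavelet
from .ecg_data import Dataset, ECGRecording, LEAD_NAMES

__all__ = [
    "WindowConfig",
    "FeatureMatrix",
    "denoise_lead",
    "denoise_recording",
    "locate_reference",
    "extract_window",
    "build_feature_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Beat window of ``W`` samples straddling the reference line.

    ``pre`` samples precede the reference; the reference sample and the
    ``post - 1`` samples after it follow.
    """

    W: int

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError(f"window length must be >= 1, got {self.W}")

    @property
    def pre(self) -> int:
        return self.W // 2

    @property
    def post(self) -> int:
        return self.W - self.pre

    @property
    def offsets(self) -> np.ndarray:
        """Signed window offsets: ``-pre .. -1, 1 .. post`` (no zero)."""
        return np.concatenate([np.arange(-self.pre, 0),
                               np.arange(1, self.post + 1)])


@dataclass
class FeatureMatrix:
    """n_recordings x (12 W) matrix of windowed voltages.

    ``feature_names`` are (lead, offset) pairs following the window
    offset convention; rows align 1:1 with the source recordings.
    """

    values: np.ndarray
    feature_names: list[tuple[str, int]]
    labels: list[str]
    recording_ids: list[str]
    patient_ids: list[str]
    window: WindowConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if p != 12 * self.window.W:
            raise ValueError(f"expected {12 * self.window.W} columns, got {p}")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")
        if not (len(self.labels) == len(self.recording_ids)
                == len(self.patient_ids) == n):
            raise ValueError("row metadata length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column_of(self, lead: str, offset: int) -> int:
        """Flat column index of feature (lead, offset)."""
        return self.feature_names.index((lead, int(offset)))

    def subset(self, row_index: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(row_index)
        return FeatureMatrix(
            self.values[idx], self.feature_names,
            [self.labels[i] for i in idx],
            [self.recording_ids[i] for i in idx],
            [self.patient_ids[i] for i in idx], self.window)

    # -- persistence --------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.attrs["W"] = self.window.W
            str_dt = h5py.string_dtype()
            fh.create_dataset("labels", data=self.labels, dtype=str_dt)
            fh.create_dataset("recording_ids", data=self.recording_ids, dtype=str_dt)
            fh.create_dataset("patient_ids", data=self.patient_ids, dtype=str_dt)

    @classmethod
    def from_hdf5(cls, path) -> "FeatureMatrix":
        with h5py.File(path, "r") as fh:
            cfg = WindowConfig(int(fh.attrs["W"]))
            return cls(
                fh["values"][...],
                feature_names_for(cfg),
                [s.decode() for s in fh["labels"][...]],
                [s.decode() for s in fh["recording_ids"][...]],
                [s.decode() for s in fh["patient_ids"][...]],
                cfg)

    def to_csv(self, path) -> None:
        cols = [f"{lead}_{off:+d}" for lead, off in self.feature_names]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "recording_id", self.recording_ids)
        df.insert(1, "patient_id", self.patient_ids)
        df.insert(2, "label", self.labels)
        df.to_csv(path, index=False)


def feature_names_for(cfg: WindowConfig) -> list[tuple[str, int]]:
    return [(lead, int(off)) for lead in LEAD_NAMES for off in cfg.offsets]


def denoise_lead(x: np.ndarray, wavelet_name: str = "coif5",
                 level: int | None = None) -> np.ndarray:
    """Wavelet denoising of one lead: coif5, per-level SURE soft threshold.

    Length-preserving; the approximation band is untouched, so baseline
    morphology survives while high-frequency noise is attenuated.
    """
    return _wavelet.denoise(np.asarray(x, dtype=float), wavelet_name, level)


def denoise_recording(rec: ECGRecording, wavelet_name: str = "coif5",
                      level: int | None = None) -> ECGRecording:
    """Denoise each of the 12 leads independently; metadata unchanged."""
    cleaned = np.vstack([denoise_lead(row, wavelet_name, level)
                         for row in rec.signal])
    return ECGRecording(
        patient_id=rec.patient_id, recording_id=rec.recording_id,
        signal=cleaned, sampling_rate=rec.sampling_rate,
        r_peak_index=rec.r_peak_index, label=rec.label)


def locate_reference(rec: ECGRecording) -> int:
    """Reference-line sample: annotated lead-II R peak, else argmax |lead II|.

    The fallback takes the first maximizer of the absolute lead-II
    voltage (each recording contains a single QRS complex, so the global
    extremum is the R wave).
    """
    if rec.r_peak_index is not None:
        return rec.r_peak_index
    return int(np.argmax(np.abs(rec.lead("II"))))


def extract_window(rec: ECGRecording, cfg: WindowConfig) -> np.ndarray:
    """Slice the 12 x W window ``[r - pre, r + post)`` around the reference.

    Overruns past either end of the recording are filled by edge-value
    padding, so any window size up to the search maximum is admissible
    even for beats near record boundaries.
    """
    r = locate_reference(rec)
    cols = np.clip(np.arange(r - cfg.pre, r + cfg.post), 0, rec.n_samples - 1)
    return rec.signal[:, cols]


def build_feature_matrix(ds: Dataset, cfg: WindowConfig,
                         denoise: bool = True) -> FeatureMatrix:
    """Windowed 12-lead voltages for every recording, one row each.

    Row i is the concatenation of recording i's 12 windowed leads in
    canonical lead order; unlabeled recordings are rejected.
    """
    names = feature_names_for(cfg)
    rows, labels, rec_ids, pat_ids = [], [], [], []
    for rec in ds:
        if rec.label is None:
            raise ValueError(f"recording {rec.recording_id!r} has no label")
        if denoise:
            rec = denoise_recording(rec)
        rows.append(extract_window(rec, cfg).ravel())
        labels.append(rec.label)
        rec_ids.append(rec.recording_id)
        pat_ids.append(rec.patient_id)
    values = (np.vstack(rows) if rows
              else np.empty((0, 12 * cfg.W)))
    return FeatureMatrix(values, names, labels, rec_ids, pat_ids, cfg)
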