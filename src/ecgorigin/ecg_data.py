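"""Domain types and file I/O for labeled 12-lead ECG recordings.

A recording is one PVC/VT beat context: a 12 x T voltage matrix sampled
at (nominally) 2,000 Hz, annotated with patient and recording IDs, an
optional lead-II R-peak sample index, and an origin-site label from the
21-code taxonomy in :mod:`ecgorigin.anatomy`.

The on-disk dialect is a plain CSV: ``#``-prefixed ``key=value`` metadata
lines, then a header naming the 12 leads, then one row per sample.
Voltage units are arbitrary-but-consistent; the downstream tree models
are insensitive to per-feature monotone rescaling, so no unit conversion
is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anatomy import LEAF_SITES

__all__ = [
    "LEAD_NAMES",
    "ECGRecording",
    "Dataset",
    "read_recording_csv",
    "write_recording_csv",
    "load_dataset",
    "write_dataset",
]

#: Canonical lead order; permuted file headers are re-ordered on read.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


class ECGFormatError(ValueError):
    """Malformed recording file (wrong columns, bad cells, bad metadata)."""


@dataclass
class ECGRecording:
    """One 12-lead beat recording.

    Parameters
    ----------
    signal
        12 x T voltage matrix, rows in :data:`LEAD_NAMES` order.
    r_peak_index
        Optional sample index of the lead-II R-wave peak in ``[0, T)``.
    label
        Origin-site code (one of the 21 leaf codes) or ``None``.
    """

    patient_id: str
    recording_id: str
    signal: np.ndarray
    sampling_rate: float = 2000.0
    r_peak_index: int | None = None
    label: str | None = None
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise ECGFormatError(
                f"signal must be 12 x T, got shape {self.signal.shape}")
        if self.signal.shape[1] < 1:
            raise ECGFormatError("signal must have at least one sample")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise ECGFormatError("lead_names must be the canonical 12-lead order")
        if self.r_peak_index is not None:
            self.r_peak_index = int(self.r_peak_index)
            if not 0 <= self.r_peak_index < self.n_samples:
                raise ValueError(
                    f"r_peak_index {self.r_peak_index} outside [0, {self.n_samples})")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[LEAD_NAMES.index(name)]


@dataclass
class Dataset:
    """A collection of recordings plus a label vocabulary and provenance."""

    recordings: list[ECGRecording]
    label_vocabulary: tuple[str, ...] = LEAF_SITES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.recordings:
            if rec.recording_id in seen:
                raise ValueError(f"duplicate recording_id: {rec.recording_id!r}")
            seen.add(rec.recording_id)
            if rec.label is not None and rec.label not in self.label_vocabulary:
                raise ValueError(
                    f"label {rec.label!r} of recording {rec.recording_id!r} "
                    "is not in the label vocabulary")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def patient_ids(self) -> list[str]:
        return sorted({r.patient_id for r in self.recordings})

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.recordings]

    def subset(self, recording_ids: Iterable[str]) -> "Dataset":
        wanted = set(recording_ids)
        return Dataset([r for r in self.recordings if r.recording_id in wanted],
                       self.label_vocabulary, dict(self.provenance))


# ---------------------------------------------------------------------------
# CSV dialect

_META_KEYS = ("patient_id", "recording_id", "sampling_rate", "r_peak_index", "label")


def read_recording_csv(path) -> ECGRecording:
    """Parse one recording from the package's CSV dialect.

    Metadata lines look like ``# key=value`` and precede the lead
    header.  Files with permuted lead headers are re-ordered, never
    rejected; missing or extra lead columns are an error naming the
    offending columns.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        header = [c.strip() for c in line.strip().split(",")]
        missing = sorted(set(LEAD_NAMES) - set(header))
        extra = sorted(set(header) - set(LEAD_NAMES))
        if missing or extra:
            raise ECGFormatError(
                f"{path}: bad lead columns (missing: {missing or 'none'}, "
                f"unexpected: {extra or 'none'})")
        rows = []
        for i, raw in enumerate(fh):
            if not raw.strip():
                continue
            cells = raw.strip().split(",")
            if len(cells) != 12:
                raise ECGFormatError(f"{path}: row {i} has {len(cells)} cells")
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise ECGFormatError(
                    f"{path}: non-numeric cell in data row {i}") from None
    if not rows:
        raise ECGFormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float).T  # lead x sample, file order
    order = [header.index(name) for name in LEAD_NAMES]
    signal = data[order]
    r_peak = meta.get("r_peak_index")
    return ECGRecording(
        patient_id=meta.get("patient_id", path.stem),
        recording_id=meta.get("recording_id", path.stem),
        signal=signal,
        sampling_rate=float(meta.get("sampling_rate", 2000.0)),
        r_peak_index=int(r_peak) if r_peak is not None else None,
        label=meta.get("label"),
    )


def write_recording_csv(rec: ECGRecording, path) -> Path:
    """Write a recording in the dialect read by :func:`read_recording_csv`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# patient_id={rec.patient_id}\n")
        fh.write(f"# recording_id={rec.recording_id}\n")
        fh.write(f"# sampling_rate={rec.sampling_rate:g}\n")
        if rec.r_peak_index is not None:
            fh.write(f"# r_peak_index={rec.r_peak_index}\n")
        if rec.label is not None:
            fh.write(f"# label={rec.label}\n")
        fh.write(",".join(LEAD_NAMES) + "\n")
        writer = csv.writer(fh)
        for row in rec.signal.T:
            writer.writerow([repr(float(v)) for v in row])
    return path


def load_dataset(manifest_path,
                 label_vocabulary: Sequence[str] | None = LEAF_SITES) -> Dataset:
    """Load a dataset from a manifest CSV.

    Manifest columns: ``path`` (relative to the manifest's directory or
    absolute), ``patient_id``, ``label``, optional ``r_peak_index``
    override.  The vocabulary defaults to the 21 anatomical leaf codes;
    pass ``None`` to infer it from the manifest labels (synthetic
    rosters).  WFDB record pairs (``.hea``) are accepted when the
    optional ``wfdb`` dependency is installed.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if label_vocabulary is None:
        label_vocabulary = tuple(sorted(
            {l for l in table.get("label", []) if isinstance(l, str)}))
    if len(table) == 0:
        return Dataset([], tuple(label_vocabulary),
                       provenance={"manifest": str(manifest_path)})
    missing = [str(p) for p in table["path"]
               if not (manifest_path.parent / p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    recordings = []
    for row in table.itertuples(index=False):
        fpath = manifest_path.parent / row.path
        if fpath.suffix == ".hea":
            rec = _read_wfdb(fpath)
        else:
            rec = read_recording_csv(fpath)
        updates: dict = {}
        if getattr(row, "patient_id", None) is not None:
            updates["patient_id"] = str(row.patient_id)
        label = getattr(row, "label", None)
        if isinstance(label, str):
            if label not in label_vocabulary:
                raise ValueError(f"manifest label {label!r} not in vocabulary")
            updates["label"] = label
        rpi = getattr(row, "r_peak_index", None)
        if rpi is not None and not pd.isna(rpi):
            updates["r_peak_index"] = int(rpi)
        recordings.append(replace(rec, **updates))
    return Dataset(recordings, tuple(label_vocabulary),
                   provenance={"manifest": str(manifest_path)})


def write_dataset(ds: Dataset, out_dir) -> Path:
    """Write every recording plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in ds.recordings:
        fname = f"{rec.recording_id}.csv"
        write_recording_csv(rec, out_dir / fname)
        rows.append({"path": fname, "patient_id": rec.patient_id,
                     "label": rec.label, "r_peak_index": rec.r_peak_index})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _read_wfdb(hea_path: Path) -> ECGRecording:
    try:
        import wfdb  # type: ignore
    except ImportError:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "convert to the CSV dialect instead") from None
    record = wfdb.rdrecord(str(hea_path.with_suffix("")))  # pragma: no cover
    sig = record.p_signal.T  # pragma: no cover
    order = [record.sig_name.index(n) for n in LEAD_NAMES]  # pragma: no cover
    return ECGRecording(  # pragma: no cover
        patient_id=hea_path.stem, recording_id=hea_path.stem,
        signal=sig[order], sampling_rate=float(record.fs))
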