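"""Patient-level cohort construction and training-set oversampling.

Recordings from one patient are highly correlated, so the train /
validation / test partition is made at the *patient* level: all of a
patient's recordings land in the same cohort, which is what makes the
held-out accuracy an honest estimate.  The split is stratified by the
finest-scheme origin label so a single assignment can serve all four
label schemes.

Because patients contribute unequal numbers of beats, training class
counts are imbalanced; the training cohort (only) is rebalanced by
duplicating minority-class recordings with replacement until every
class matches the majority class count.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_data import Dataset

__all__ = [
    "COHORTS",
    "CohortAssignment",
    "split_patients",
    "allocate_recordings",
    "oversample_training",
    "balance_counts",
    "apply_exclusions",
    "DEFAULT_SCREENING",
]

log = logging.getLogger(__name__)

COHORTS: tuple[str, str, str] = ("train", "validation", "test")

#: Patient-screening removals of the reference clinical study, in order:
#: incomplete/mismatched records, arrhythmia recurrence within follow-up,
#: structural/ischemic comorbidity, multiple ablation sites.
DEFAULT_SCREENING: tuple[int, ...] = (109, 76, 5, 12)


def apply_exclusions(initial: int,
                     removals: tuple[int, ...] = DEFAULT_SCREENING) -> list[int]:
    """Sequential screening arithmetic: cohort size after each exclusion.

    Returns the running cohort sizes, starting with ``initial`` and
    ending with the final enrolled count.
    """
    sizes = [int(initial)]
    for r in removals:
        nxt = sizes[-1] - int(r)
        if nxt < 0:
            raise ValueError("exclusions exceed the remaining cohort")
        sizes.append(nxt)
    return sizes


@dataclass
class CohortAssignment:
    """Patient-level partition plus per-cohort recording sets.

    ``oversampled_train`` is a multiset (list with repeats) of training
    recording ids; validation and test are never oversampled.
    """

    patient_to_cohort: dict[str, str]
    recordings_per_cohort: dict[str, list[str]] = field(
        default_factory=lambda: {c: [] for c in COHORTS})
    oversampled_train: list[str] = field(default_factory=list)
    seed: int | None = None

    def cohort_of_recording(self, recording_id: str) -> str:
        for cohort, ids in self.recordings_per_cohort.items():
            if recording_id in ids:
                return cohort
        raise KeyError(recording_id)

    def to_frame(self, ds: Dataset) -> pd.DataFrame:
        mult = Counter(self.oversampled_train)
        rows = []
        for rec in ds:
            cohort = self.patient_to_cohort.get(rec.patient_id)
            rows.append({
                "recording_id": rec.recording_id,
                "patient_id": rec.patient_id,
                "label": rec.label,
                "cohort": cohort,
                "multiplicity": (mult.get(rec.recording_id, 0)
                                 if cohort == "train" else 1),
            })
        return pd.DataFrame(rows)


def _cohort_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Cohort sizes for one stratum of ``n`` patients.

    Largest-remainder rounding with ties broken toward the earlier
    cohort (train, validation, test), then a minimum-one guarantee for
    validation and test whenever the stratum has at least 3 patients
    (taken from training).  This reproduces 545 -> 436/55/54 and
    5 -> 3/1/1.
    """
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in range(remainder):
        counts[order[i % 3]] += 1
    if n >= 3:
        for c in (1, 2):
            if counts[c] == 0:
                counts[c] += 1
                counts[0] -= 1
    return counts


def _patient_strata(ds: Dataset) -> dict[str, list[str]]:
    """Patients grouped by their (majority) finest-scheme label."""
    label_votes: dict[str, Counter] = defaultdict(Counter)
    order: dict[str, None] = {}
    for rec in ds:
        label_votes[rec.patient_id][rec.label] += 1
        order.setdefault(rec.patient_id, None)
    strata: dict[str, list[str]] = defaultdict(list)
    for pid in order:  # dataset order, deterministic
        label = label_votes[pid].most_common(1)[0][0]
        strata[label].append(pid)
    return strata


def split_patients(ds: Dataset,
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> CohortAssignment:
    """Stratified patient-level 80/10/10 split.

    Within each origin-class stratum patients are shuffled with the
    seed and dealt to cohorts per :func:`_cohort_counts`.  A stratum
    with a single patient goes entirely to training with a warning
    (held-out coverage for that class is impossible).
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    patient_to_cohort: dict[str, str] = {}
    for label, patients in sorted(_patient_strata(ds).items()):
        patients = list(patients)
        rng.shuffle(patients)
        if len(patients) < 3:
            log.warning(
                "class %s has only %d patient(s); assigning to training, "
                "validation/test coverage impossible", label, len(patients))
        counts = _cohort_counts(len(patients), fractions)
        start = 0
        for cohort, k in zip(COHORTS, counts):
            for pid in patients[start:start + k]:
                patient_to_cohort[pid] = cohort
            start += k
    return allocate_recordings(ds, patient_to_cohort, fractions, seed=seed)


def allocate_recordings(ds: Dataset, patient_map: dict[str, str],
                        fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                        seed: int | None = None) -> CohortAssignment:
    """Recordings inherit their patient's cohort.

    Patient-level assignment constrains recording-level shares; when a
    class's realized share deviates from the target fraction by more
    than 2 percentage points a warning reports the deviation.
    """
    per_cohort: dict[str, list[str]] = {c: [] for c in COHORTS}
    class_cohort: dict[str, Counter] = defaultdict(Counter)
    for rec in ds:
        cohort = patient_map[rec.patient_id]
        per_cohort[cohort].append(rec.recording_id)
        class_cohort[rec.label][cohort] += 1
    for label, tally in sorted(class_cohort.items()):
        total = sum(tally.values())
        for cohort, frac in zip(COHORTS, fractions):
            share = tally[cohort] / total
            if abs(share - frac) > 0.02:
                log.warning(
                    "class %s: %s share %.1f%% deviates from target %.0f%% "
                    "(patient-level split constrains exactness)",
                    label, cohort, 100 * share, 100 * frac)
    return CohortAssignment(patient_to_cohort=dict(patient_map),
                            recordings_per_cohort=per_cohort, seed=seed)


def balance_counts(counts: dict[str, int]) -> dict[str, int]:
    """Majority-matching target counts: every class -> max class count."""
    if not counts:
        return {}
    target = max(counts.values())
    return {label: target for label in counts}


def oversample_training(assignment: CohortAssignment, ds: Dataset,
                        seed: int = 0,
                        labels: dict[str, str] | None = None) -> CohortAssignment:
    """Duplicate minority-class training recordings up to the majority count.

    ``labels`` maps recording_id to the class label of the active
    scheme; by default the finest-scheme labels are used.  Sampling is
    with replacement, seeded; only the training cohort is modified.
    """
    if labels is None:
        labels = {rec.recording_id: rec.label for rec in ds}
    train_ids = assignment.recordings_per_cohort["train"]
    if not train_ids:
        raise ValueError("training set is empty")
    by_class: dict[str, list[str]] = defaultdict(list)
    for rid in train_ids:
        by_class[labels[rid]].append(rid)
    targets = balance_counts({c: len(ids) for c, ids in by_class.items()})
    rng = np.random.default_rng(seed)
    multiset = list(train_ids)
    for label in sorted(by_class):
        pool = by_class[label]
        extra = targets[label] - len(pool)
        if extra > 0:
            multiset.extend(rng.choice(pool, size=extra, replace=True))
    return CohortAssignment(
        patient_to_cohort=assignment.patient_to_cohort,
        recordings_per_cohort=assignment.recordings_per_cohort,
        oversampled_train=multiset, seed=assignment.seed)
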