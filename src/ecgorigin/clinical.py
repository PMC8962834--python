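"""Reference clinical cohort bookkeeping shipped as data.

The package was designed around a single-center catheter-ablation
cohort whose per-site sample distribution (finest scheme, 21 sites) is
reproduced here: patients, ECG recordings, and the 80/10/10
train/validation/test recording allocation.  These numbers serve as

* the default imbalance profile emulated by :mod:`ecgorigin.synthetic`,
* inputs to arithmetic self-checks (screening flow, oversampling
  targets, test-cohort denominators).

They are study bookkeeping, not measurements made by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_distribution", "INITIAL_PATIENTS", "ENROLLED_PATIENTS",
           "PATIENT_SPLIT"]

#: Screening head-count: patients assessed, and enrolled after exclusions.
INITIAL_PATIENTS = 747
ENROLLED_PATIENTS = 545

#: Printed patient-level cohort sizes (train, validation, test).
PATIENT_SPLIT = (436, 55, 54)

_ROWS = [
    # site, patients, recordings, train, validation, test
    ("LC", 67, 2118, 1694, 212, 212),
    ("RVOT posterior septal", 43, 1848, 1478, 185, 185),
    ("LCC", 41, 588, 470, 59, 59),
    ("AC", 38, 1079, 863, 108, 108),
    ("RVOT free wall", 32, 1287, 1029, 129, 129),
    ("RVOT anterior septal", 32, 1014, 812, 101, 101),
    ("Right His bundle", 31, 705, 563, 71, 71),
    ("RC", 24, 353, 283, 35, 35),
    ("AMC", 23, 1434, 1146, 144, 144),
    ("LPF", 18, 913, 731, 91, 91),
    ("TV", 18, 563, 451, 56, 56),
    ("LAF", 13, 885, 707, 89, 89),
    ("LCC-RCC commissure", 11, 172, 138, 17, 17),
    ("Epicardium of LV summit", 10, 351, 281, 35, 35),
    ("LPPM", 9, 677, 541, 68, 68),
    ("MV", 8, 330, 264, 33, 33),
    ("LAPM", 8, 192, 154, 19, 19),
    ("RCC", 7, 51, 41, 5, 5),
    ("Summit", 5, 31, 25, 3, 3),
    ("Left His bundle", 3, 149, 119, 15, 15),
    ("RAPM", 2, 14, 12, 1, 1),
]


def cohort_distribution() -> pd.DataFrame:
    """Per-site sample distribution of the reference cohort.

    Columns: ``site``, ``patients``, ``recordings``, ``train``,
    ``validation``, ``test``.  Indexed by ``site``.
    """
    df = pd.DataFrame(
        _ROWS, columns=["site", "patients", "recordings",
                        "train", "validation", "test"])
    return df.set_index("site")
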