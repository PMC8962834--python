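"""Anatomical taxonomy of ventricular arrhythmia origin sites.

Idiopathic PVC/VT origins are named by the successful catheter-ablation
site.  Clinically the estimate proceeds hierarchically: first the gross
region (left ventricular endocardium, right ventricular endocardium, or
the epicardium of the LV summit), then outflow-tract vs non-outflow-tract,
then progressively finer anatomical structures down to 21 leaf sites
(valve cusps, fascicles, papillary muscles, septal subdivisions, ...).

This module encodes that hierarchy as a four-level tree and exposes the
four label "schemes" used throughout the package:

======  =======  =========================================
scheme  classes  granularity
======  =======  =========================================
1       3        gross region
2       5        outflow / non-outflow tract (+ epicardium)
3       18       anatomical group
4       21       leaf site (identity)
======  =======  =========================================

plus a partial-credit matrix used by the adjusted-accuracy metric, which
awards credit to confusions between sites whose ablation treatment is
essentially interchangeable (sibling sites under the same group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnatomyNode",
    "SchemeMap",
    "CreditMatrix",
    "LEAF_SITES",
    "SITE_TABLE",
    "build_hierarchy",
    "scheme_map",
    "collapse_labels",
    "partial_credit_matrix",
]

# Each leaf: code -> (region, tract, group).  Group equals the leaf code
# whenever the finest and second-finest schemes agree on that site.
_REGION_LV = "LV endocardium"
_REGION_RV = "RV endocardium"
_REGION_EPI = "Epicardium of LV summit"

_LVOT = "LV outflow tract"
_LVNOT = "LV non-outflow tract"
_RVOT = "RV outflow tract"
_RVNOT = "RV non-outflow tract"

SITE_TABLE: dict[str, tuple[str, str, str]] = {
    # LV outflow tract
    "LCC": (_REGION_LV, _LVOT, "LCC"),
    "RCC": (_REGION_LV, _LVOT, "RCC"),
    "AMC": (_REGION_LV, _LVOT, "AMC"),
    "Summit": (_REGION_LV, _LVOT, "Summit"),
    "LCC-RCC commissure": (_REGION_LV, _LVOT, "LCC-RCC commissure"),
    # LV non-outflow tract
    "Left His bundle": (_REGION_LV, _LVNOT, "Left His bundle"),
    "MV": (_REGION_LV, _LVNOT, "MV"),
    "LAF": (_REGION_LV, _LVNOT, "Left Septal"),
    "LPF": (_REGION_LV, _LVNOT, "Left Septal"),
    "LAPM": (_REGION_LV, _LVNOT, "Papillary Muscle"),
    "LPPM": (_REGION_LV, _LVNOT, "Papillary Muscle"),
    # RV outflow tract
    "AC": (_REGION_RV, _RVOT, "AC"),
    "LC": (_REGION_RV, _RVOT, "LC"),
    "RC": (_REGION_RV, _RVOT, "RC"),
    "RVOT posterior septal": (_REGION_RV, _RVOT, "RVOT septal"),
    "RVOT anterior septal": (_REGION_RV, _RVOT, "RVOT septal"),
    "RVOT free wall": (_REGION_RV, _RVOT, "RVOT free wall"),
    # RV non-outflow tract
    "Right His bundle": (_REGION_RV, _RVNOT, "Right His bundle"),
    "TV": (_REGION_RV, _RVNOT, "TV"),
    "RAPM": (_REGION_RV, _RVNOT, "RAPM"),
    # Epicardium is its own branch at every level
    "Epicardium of LV summit": (_REGION_EPI, _REGION_EPI, _REGION_EPI),
}

LEAF_SITES: tuple[str, ...] = tuple(SITE_TABLE)


@dataclass
class AnatomyNode:
    """One node of the origin-site hierarchy.

    ``level`` is one of ``region``, ``tract``, ``group``, ``leaf``.  The
    epicardial branch carries the same code at every level; nodes are
    therefore identified by ``(code, level)``, not by code alone.
    """

    code: str
    level: str
    parent: "AnatomyNode | None" = None
    children: list["AnatomyNode"] = field(default_factory=list)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AnatomyNode({self.code!r}, {self.level!r})"


@dataclass(frozen=True)
class SchemeMap:
    """A label-collapse scheme: leaf site -> class at the scheme's level."""

    scheme_id: int
    classes: tuple[str, ...]
    collapse: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.collapse.values()) != set(self.classes):
            raise ValueError("collapse map is not surjective onto classes")


def build_hierarchy() -> list[AnatomyNode]:
    """Build the four-level origin-site tree.

    Returns the three region roots; traverse ``children`` downwards.
    Leaves are exactly the 21 finest-scheme site codes.
    """
    roots: dict[str, AnatomyNode] = {}
    tracts: dict[tuple[str, str], AnatomyNode] = {}
    groups: dict[tuple[str, str], AnatomyNode] = {}
    for leaf, (region, tract, group) in SITE_TABLE.items():
        rnode = roots.get(region)
        if rnode is None:
            rnode = roots[region] = AnatomyNode(region, "region")
        tnode = tracts.get((region, tract))
        if tnode is None:
            tnode = tracts[(region, tract)] = AnatomyNode(tract, "tract", parent=rnode)
            rnode.children.append(tnode)
        gnode = groups.get((tract, group))
        if gnode is None:
            gnode = groups[(tract, group)] = AnatomyNode(group, "group", parent=tnode)
            tnode.children.append(gnode)
        gnode.children.append(AnatomyNode(leaf, "leaf", parent=gnode))
    return list(roots.values())


def _level_index(scheme_id: int) -> int:
    if scheme_id not in (1, 2, 3, 4):
        raise ValueError(f"scheme_id must be 1..4, got {scheme_id}")
    return scheme_id - 1  # (region, tract, group) columns; 4 = leaf identity


def scheme_map(scheme_id: int) -> SchemeMap:
    """The collapse map for one of the four classification schemes."""
    if scheme_id == 4:
        collapse = {leaf: leaf for leaf in LEAF_SITES}
    else:
        col = _level_index(scheme_id)
        collapse = {leaf: SITE_TABLE[leaf][col] for leaf in LEAF_SITES}
    classes = tuple(dict.fromkeys(collapse.values()))  # first-seen order
    return SchemeMap(scheme_id=scheme_id, classes=classes, collapse=collapse)


def collapse_labels(labels: Iterable[str], scheme: SchemeMap | int) -> list[str]:
    """Map leaf-site labels to the classes of a coarser scheme."""
    if isinstance(scheme, int):
        scheme = scheme_map(scheme)
    out = []
    for lab in labels:
        try:
            out.append(scheme.collapse[lab])
        except KeyError:
            raise KeyError(f"unknown origin-site code: {lab!r}") from None
    return out


@dataclass(frozen=True)
class CreditMatrix:
    """Partial-credit weights for the adjusted-accuracy metric.

    ``weights[i, j]`` is the credit awarded when class ``classes[i]`` is
    the true site and ``classes[j]`` the predicted one.  Diagonal is 1.
    """

    scheme_id: int
    classes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        k = len(self.classes)
        if w.shape != (k, k):
            raise ValueError("weights shape does not match class count")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("credit matrix diagonal must be 1")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("credit weights must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, index=list(self.classes),
                     columns=list(self.classes)).to_csv(path)

    @classmethod
    def from_csv(cls, path, scheme_id: int) -> "CreditMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(scheme_id=scheme_id, classes=tuple(df.columns),
                   weights=df.to_numpy(dtype=float))


def partial_credit_matrix(scheme: SchemeMap | int,
                          sibling_weight: float = 0.5) -> CreditMatrix:
    """Sibling-based partial credit for the two finest schemes.

    Two distinct classes earn ``sibling_weight`` when they share the same
    immediate parent in the hierarchy (e.g. the two RVOT septal
    subdivisions, or the two left fascicles) — sites whose confusion
    leads to essentially the same ablation approach.  All other
    confusions earn 0.  Fully overridable via ``CreditMatrix.from_csv``.
    """
    if isinstance(scheme, int):
        scheme = scheme_map(scheme)
    if scheme.scheme_id not in (3, 4):
        raise ValueError("partial credit is defined for schemes 3 and 4 only")
    if not 0.0 <= sibling_weight <= 1.0:
        raise ValueError(f"sibling_weight must be in [0, 1], got {sibling_weight}")
    # Immediate parent of a scheme's class: group -> tract, leaf -> group.
    parent_col = 1 if scheme.scheme_id == 3 else 2
    parent_of: dict[str, str] = {}
    for leaf, cols in SITE_TABLE.items():
        cls_code = scheme.collapse[leaf]
        parent_of[cls_code] = cols[parent_col]
    k = len(scheme.classes)
    w = np.zeros((k, k))
    for i, a in enumerate(scheme.classes):
        for j, b in enumerate(scheme.classes):
            if a == b:
                w[i, j] = 1.0
            elif parent_of[a] == parent_of[b]:
                w[i, j] = sibling_weight
    return CreditMatrix(scheme_id=scheme.scheme_id, classes=scheme.classes, weights=w)


def schemes_to_json(path) -> None:
    """Serialize all four scheme maps to a plain JSON document."""
    doc = {
        str(s): {"classes": list(scheme_map(s).classes),
                 "collapse": scheme_map(s).collapse}
        for s in (1, 2, 3, 4)
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
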