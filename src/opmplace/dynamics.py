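"""Unit-class dynamics across OPM trial transitions and object-vector analysis.

Units are classified per transition by the 3-Hz peak-rate activity boundary
(active / emerging / vanishing / inactive); active units are split into
stable and unstable at a 7-cm COM shift.  The vector index quantifies how a
field's between-trial COM displacement relates to the object's displacement:
it is the magnitude of the vector difference between the object's move
vector and the field's COM displacement vector, zero when the field moves
exactly with the object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ComPoint, RateSummary

ACTIVE_THRESHOLD_HZ = 3.0
STABILITY_BOUNDARY_CM = 7.0

TRANSITIONS = ("T1->T2", "T2->T3")
CLASSES = ("active", "emerging", "vanishing", "inactive")


@dataclass(frozen=True)
class ClassLabel:
    transition: str
    label: str  # active | emerging | vanishing | inactive
    stability: str | None = None  # stable | unstable, for active units only

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        if self.stability is not None and self.label != "active":
            raise ValueError("stability is defined only for active units")


@dataclass(frozen=True)
class VectorIndexRecord:
    unit_id: int
    move_vector: tuple[float, float]
    com_vector: tuple[float, float]
    vector_index: float
    t2_distance_to_moving_object: float
    com_shift: float
    stability: str | None = None


def classify_activity(summary: RateSummary, threshold_hz: float = ACTIVE_THRESHOLD_HZ) -> str:
    """'active' iff the peak rate reaches the threshold (3 Hz inclusive)."""
    if summary.peak_rate < 0:
        raise ValueError("peak rate cannot be negative")
    return "active" if summary.peak_rate >= threshold_hz else "inactive"


def classify_transition(
    before: RateSummary,
    after: RateSummary,
    transition: str = "T1->T2",
    threshold_hz: float = ACTIVE_THRESHOLD_HZ,
    com_shift_cm: float | None = None,
    stability_boundary_cm: float = STABILITY_BOUNDARY_CM,
) -> ClassLabel:
    """Classify a unit over one trial transition.

    active (both trials at/above threshold), emerging (crosses upward),
    vanishing (crosses downward), inactive (below in both).  When a COM
    shift is supplied, active units also get a stable/unstable tag.
    """
    a = classify_activity(before, threshold_hz) == "active"
    b = classify_activity(after, threshold_hz) == "active"
    label = {(True, True): "active", (False, True): "emerging",
             (True, False): "vanishing", (False, False): "inactive"}[(a, b)]
    stability = None
    if label == "active" and com_shift_cm is not None:
        stability = split_stability(com_shift_cm, stability_boundary_cm)
    return ClassLabel(transition=transition, label=label, stability=stability)


def split_stability(shift_cm: float, boundary_cm: float = STABILITY_BOUNDARY_CM) -> str:
    """'stable' below the boundary (7 cm), 'unstable' at or above it."""
    if shift_cm < 0:
        raise ValueError("COM shift cannot be negative")
    return "stable" if shift_cm < boundary_cm else "unstable"


def vector_index(
    com_t2: ComPoint, com_t3: ComPoint, move_vector: tuple[float, float]
) -> float:
    """|move_vector - (COM_T3 - COM_T2)|, in cm.

    Zero exactly when the field's COM displaces along the same vector as
    the object; a stationary field scores the full object displacement.
    """
    dx = com_t3.x - com_t2.x
    dy = com_t3.y - com_t2.y
    return math.hypot(move_vector[0] - dx, move_vector[1] - dy)


def cohort_table(
    labels: Mapping[int, ClassLabel] | Sequence[tuple[int, ClassLabel]],
    groups: Mapping[int, str],
) -> pd.DataFrame:
    """Class-frequency table: one row per (group, class) with count and percent."""
    items = labels.items() if isinstance(labels, Mapping) else list(labels)
    rows = []
    for uid, lab in items:
        if uid not in groups:
            raise ValueError(f"unit {uid} has no group assignment")
        rows.append({"unit_id": uid, "group": groups[uid], "label": lab.label})
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows)
    out = []
    for group, gdf in df.groupby("group"):
        n = len(gdf)
        for cls in CLASSES:
            count = int((gdf["label"] == cls).sum())
            out.append(
                {"group": group, "class": cls, "count": count, "percent": 100.0 * count / n}
            )
    return pd.DataFrame(out)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> dict:
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": n, "computable": False}
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": n, "computable": True}


def object_vector_analysis(records: Iterable[VectorIndexRecord]) -> dict:
    """Correlations among COM shift, vector index, and T2 object distance.

    Reported for all records pooled and separately for the stable and
    unstable subsets: r(COM shift, T2 distance), r(vector index, COM shift),
    r(vector index, T2 distance).
    """
    recs = list(records)
    if not recs:
        raise ValueError("no vector-index records")

    def correlations(subset: list[VectorIndexRecord]) -> dict:
        shift = np.array([r.com_shift for r in subset])
        vidx = np.array([r.vector_index for r in subset])
        dist = np.array([r.t2_distance_to_moving_object for r in subset])
        return {
            "com_shift_vs_t2_distance": _safe_pearson(shift, dist),
            "vector_index_vs_com_shift": _safe_pearson(vidx, shift),
            "vector_index_vs_t2_distance": _safe_pearson(vidx, dist),
        }

    out = {"all": correlations(recs)}
    for sub in ("stable", "unstable"):
        chosen = [r for r in recs if r.stability == sub]
        out[sub] = correlations(chosen) if chosen else {
            k: {"r": float("nan"), "p": float("nan"), "n": 0, "computable": False}
            for k in out["all"]
        }
    return out
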