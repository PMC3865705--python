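"""Object-exploration and locomotion scoring from nose-position tracks.

A visit is a maximal run of frames in which the nose lies within an
object's circular zone (base diameter plus a 1-cm proximity band, i.e.
6.5 cm for the standard 4.5-cm object).  From per-object visit times the
sample-trial exploration ratio and the choice-trial OPM ratio are derived;
percent time moving uses a configurable instantaneous-speed threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .synthetic_data import ObjectLayout, ObjectSpec, Trajectory

DEFAULT_SPEED_THRESHOLD_CM_S = 2.0


@dataclass(frozen=True)
class VisitEpisode:
    object_label: str
    start_s: float
    end_s: float  # end of the last in-zone frame period

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RatioResult:
    """Both conventions of the two-object preference ratio.

    ``quotient`` is right/(left+right) in [0, 1]; ``discrimination`` is
    (right-left)/(left+right) in [-1, 1] and is the headline form (the
    only one consistent with negative reported group values).
    """

    quotient: float
    discrimination: float


def detect_object_visits(
    nose: Trajectory,
    objects: ObjectLayout | Sequence[ObjectSpec],
    trial: str = "T2",
    min_episode_frames: int = 1,
) -> list[VisitEpisode]:
    """Maximal in-zone frame runs per object, time-ordered."""
    objs = objects.objects(trial) if isinstance(objects, ObjectLayout) else tuple(objects)
    if not objs:
        raise ValueError("object layout is empty")
    for a, b in combinations(objs, 2):
        gap = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
        if gap < a.zone_radius + b.zone_radius:
            raise ValueError(f"object zones of {a.label!r} and {b.label!r} overlap")
    dt = 1.0 / nose.frame_rate
    episodes: list[VisitEpisode] = []
    for obj in objs:
        inside = np.hypot(nose.x - obj.center[0], nose.y - obj.center[1]) <= obj.zone_radius
        if not inside.any():
            continue
        padded = np.diff(np.concatenate(([0], inside.astype(int), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)  # exclusive
        for s, e in zip(starts, ends):
            if e - s < min_episode_frames:
                continue
            episodes.append(
                VisitEpisode(
                    object_label=obj.label,
                    start_s=float(nose.t[s]),
                    end_s=float(nose.t[e - 1]) + dt,
                )
            )
    return sorted(episodes, key=lambda ep: (ep.start_s, ep.object_label))


def total_visit_time(episodes: Sequence[VisitEpisode], label: str) -> float:
    return float(sum(ep.duration for ep in episodes if ep.object_label == label))


def visit_count(episodes: Sequence[VisitEpisode], label: str) -> int:
    return sum(1 for ep in episodes if ep.object_label == label)


def exploration_ratio(time_left: float, time_right: float) -> RatioResult:
    """Sample-trial (T2) preference between the left and right objects."""
    if time_left < 0 or time_right < 0:
        raise ValueError("visit times cannot be negative")
    total = time_left + time_right
    if total <= 0:
        raise ValueError("not computable: no object exploration time")
    return RatioResult(
        quotient=time_right / total,
        discrimination=(time_right - time_left) / total,
    )


def opm_ratio(time_moved: float, time_stable: float) -> float:
    """(moved - stable) / (moved + stable) on the choice trial (T3)."""
    if time_moved < 0 or time_stable < 0:
        raise ValueError("visit times cannot be negative")
    total = time_moved + time_stable
    if total <= 0:
        raise ValueError("not computable: no object exploration time")
    return (time_moved - time_stable) / total


def percent_time_moving(
    trajectory: Trajectory, speed_threshold: float = DEFAULT_SPEED_THRESHOLD_CM_S
) -> float:
    """Percent of frame intervals with instantaneous speed at/above threshold."""
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames to compute speed")
    speeds = trajectory.speeds()
    return 100.0 * float(np.mean(speeds >= speed_threshold))
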