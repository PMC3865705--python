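"""Synthetic object-place-memory (OPM) sessions with known ground truth.

This module generates everything a tetrode recording session would provide
to the analysis side of the package: a locomotion trajectory in a 40-cm
square arena sampled at 30 frames/s, per-trial object layouts (two objects
introduced on the sample trial, one displaced to an adjacent quadrant on the
choice trial), and spike trains from Gaussian-tuned place cells fired as
inhomogeneous Poisson processes along the trajectory.  Each simulated unit
carries a ground-truth tuning specification and a per-transition dynamics
label (stable / unstable / emerging / vanishing / inactive), so every
downstream stage — rate maps, spatial metrics, unit classification,
behavior scoring, group statistics — can be tested against a known answer.

Randomness is organised as one named stream per component (trajectory,
unit assignment, per-unit spiking), all derived from the session seed, so
that e.g. changing the number of units never perturbs the trajectory.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Arena and object geometry
# ---------------------------------------------------------------------------

TRIAL_NAMES = ("T1", "T2", "T3")
#: transition dynamics labels; "stable"/"unstable" are active-in-both classes
DYNAMICS_CLASSES = ("stable", "unstable", "emerging", "vanishing", "inactive")


@dataclass(frozen=True)
class ArenaSpec:
    """Square open-field arena; origin at the SW corner, x East, y North."""

    side_length: float = 40.0  # cm
    bin_size: float = 2.0  # cm

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n = self.side_length / self.bin_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("side_length must be divisible by bin_size")

    @property
    def n_bins(self) -> int:
        return int(round(self.side_length / self.bin_size))

    @property
    def center(self) -> tuple[float, float]:
        return (self.side_length / 2.0, self.side_length / 2.0)

    @property
    def quadrant_centers(self) -> dict[str, tuple[float, float]]:
        """Centers of the SW/SE/NW/NE quadrants (candidate object sites)."""
        q = self.side_length / 4.0
        return {
            "SW": (q, q),
            "SE": (3 * q, q),
            "NW": (q, 3 * q),
            "NE": (3 * q, 3 * q),
        }

    def contains(self, x, y) -> np.ndarray:
        return (
            (np.asarray(x) >= 0)
            & (np.asarray(x) <= self.side_length)
            & (np.asarray(y) >= 0)
            & (np.asarray(y) <= self.side_length)
        )


@dataclass(frozen=True)
class ObjectSpec:
    """One physical object: a cylinder base plus a visit-detection zone.

    The zone diameter equals the base diameter plus twice the snout-proximity
    threshold (1 cm), i.e. the default 4.5-cm base carries a 6.5-cm zone.
    """

    label: str
    center: tuple[float, float]
    base_diameter: float = 4.5
    proximity_cm: float = 1.0

    @property
    def zone_diameter(self) -> float:
        return self.base_diameter + 2.0 * self.proximity_cm

    @property
    def zone_radius(self) -> float:
        return self.zone_diameter / 2.0


@dataclass(frozen=True)
class ObjectLayout:
    """Per-trial object placement for the OPM task.

    T1 has no objects; T2 has two identical objects at quadrant centers;
    on T3 one object ("moved") is displaced to the adjacent quadrant while
    the other ("stable") stays.  ``move_vector`` is the T2->T3 displacement
    of the moving object.
    """

    objects_by_trial: Mapping[str, tuple[ObjectSpec, ...]]
    move_vector: tuple[float, float]

    def objects(self, trial: str) -> tuple[ObjectSpec, ...]:
        return tuple(self.objects_by_trial.get(trial, ()))

    @property
    def moving_object_t2(self) -> ObjectSpec:
        """The T2 position of the object that moves on T3."""
        moved_t3 = next(o for o in self.objects("T3") if o.label == "moved")
        x = moved_t3.center[0] - self.move_vector[0]
        y = moved_t3.center[1] - self.move_vector[1]
        for obj in self.objects("T2"):
            if math.isclose(obj.center[0], x, abs_tol=1e-9) and math.isclose(
                obj.center[1], y, abs_tol=1e-9
            ):
                return obj
        raise ValueError("move_vector does not connect a T2 object to the T3 'moved' object")


_ADJACENT = {
    "SW": ("SE", "NW"),
    "SE": ("SW", "NE"),
    "NW": ("NE", "SW"),
    "NE": ("NW", "SE"),
}


def standard_layout(
    arena: ArenaSpec | None = None,
    *,
    t2_quadrants: tuple[str, str] = ("NW", "NE"),
    moved: str = "NE",
    target_quadrant: str | None = None,
    base_diameter: float = 4.5,
) -> ObjectLayout:
    """Build the canonical two-object layout on quadrant centers.

    The moved object's destination is an adjacent quadrant not already
    occupied (object separation on T3 stays one quadrant spacing), so the
    displacement length is always ``side_length / 2`` (20 cm by default).
    """
    arena = arena or ArenaSpec()
    qc = arena.quadrant_centers
    qa, qb = t2_quadrants
    if qa == qb or qa not in qc or qb not in qc:
        raise ValueError(f"t2_quadrants must name two distinct quadrants, got {t2_quadrants}")
    if moved not in (qa, qb):
        raise ValueError("'moved' must be one of the T2 quadrants")
    stable_q = qb if moved == qa else qa
    if target_quadrant is None:
        candidates = [q for q in _ADJACENT[moved] if q != stable_q]
        if not candidates:
            raise ValueError("no free adjacent quadrant for the moved object")
        target_quadrant = candidates[0]
    if target_quadrant not in _ADJACENT[moved]:
        raise ValueError(f"{target_quadrant} is not adjacent to {moved}")
    # left/right by x-coordinate, as in the behavioral scoring convention
    (left_q, right_q) = sorted((qa, qb), key=lambda q: qc[q][0])
    t2 = (
        ObjectSpec("left", qc[left_q], base_diameter),
        ObjectSpec("right", qc[right_q], base_diameter),
    )
    t3 = (
        ObjectSpec("stable", qc[stable_q], base_diameter),
        ObjectSpec("moved", qc[target_quadrant], base_diameter),
    )
    mv = (
        qc[target_quadrant][0] - qc[moved][0],
        qc[target_quadrant][1] - qc[moved][1],
    )
    return ObjectLayout(objects_by_trial={"T2": t2, "T3": t3}, move_vector=mv)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """Timestamped 2-D path of the animal's nose in arena coordinates (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        for name in ("t", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total tracked time: one frame period per sample."""
        return self.n_frames / self.frame_rate

    def speeds(self) -> np.ndarray:
        """Instantaneous speed per frame interval (cm/s), length n_frames-1."""
        dt = np.diff(self.t)
        return np.hypot(np.diff(self.x), np.diff(self.y)) / dt


@dataclass(frozen=True)
class MotionParams:
    """Persistent-random-walk locomotion parameters.

    Speed follows an Ornstein-Uhlenbeck process (mean ``mean_speed_cm_s``,
    stationary s.d. ``speed_sd_cm_s``, relaxation time ``speed_tau_s``)
    clipped at zero; heading diffuses with angular noise ``heading_sd_rad``
    per sqrt-second and is steered away from walls inside ``wall_margin_cm``.
    """

    mean_speed_cm_s: float = 8.0
    speed_sd_cm_s: float = 4.0
    speed_tau_s: float = 1.0
    heading_sd_rad: float = 1.8
    wall_margin_cm: float = 3.0
    wall_turn_gain: float = 2.5


@dataclass(frozen=True)
class ObjectBias:
    """Optional dwell bias: steer toward objects and slow down in the zone."""

    objects: tuple[ObjectSpec, ...]
    dwell_gain: float = 1.0
    attraction_radius_cm: float = 12.0


def generate_trajectory(
    duration: float,
    arena: ArenaSpec | None = None,
    frame_rate: float = 30.0,
    motion: MotionParams | None = None,
    object_bias: ObjectBias | None = None,
    seed: int | np.random.Generator = 0,
    t_start: float = 0.0,
) -> Trajectory:
    """Simulate confined locomotion in the arena.

    Returns one sample per frame, all strictly inside the arena; the same
    seed always yields the same path.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    arena = arena or ArenaSpec()
    motion = motion or MotionParams()
    rng = np.random.default_rng(seed)

    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    side = arena.side_length
    eps = 1e-6

    # draw all noise up front; the integration loop is then branch-light
    speed_noise = rng.standard_normal(n)
    heading_noise = rng.standard_normal(n)

    x = np.empty(n)
    y = np.empty(n)
    px = rng.uniform(0.25 * side, 0.75 * side)
    py = rng.uniform(0.25 * side, 0.75 * side)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    speed = max(0.0, motion.mean_speed_cm_s + motion.speed_sd_cm_s * rng.standard_normal())

    tau = motion.speed_tau_s
    sig_v = motion.speed_sd_cm_s * math.sqrt(2.0 * dt / tau)
    sig_h = motion.heading_sd_rad * math.sqrt(dt)
    margin = motion.wall_margin_cm

    bias_centers = None
    if object_bias is not None and object_bias.objects:
        bias_centers = np.array([o.center for o in object_bias.objects])
        bias_radii = np.array([o.zone_radius for o in object_bias.objects])

    for k in range(n):
        speed += (motion.mean_speed_cm_s - speed) * dt / tau + sig_v * speed_noise[k]
        speed = max(0.0, speed)
        heading += sig_h * heading_noise[k]

        step = speed * dt
        if bias_centers is not None:
            d = np.hypot(bias_centers[:, 0] - px, bias_centers[:, 1] - py)
            j = int(np.argmin(d))
            if d[j] < object_bias.attraction_radius_cm:
                target = math.atan2(bias_centers[j, 1] - py, bias_centers[j, 0] - px)
                delta = math.atan2(math.sin(target - heading), math.cos(target - heading))
                heading += object_bias.dwell_gain * delta * dt
                if d[j] < bias_radii[j]:  # linger inside the zone
                    step /= 1.0 + object_bias.dwell_gain

        # steer away from nearby walls
        if px < margin:
            heading = _steer_toward(heading, 0.0, motion.wall_turn_gain * dt)
        elif px > side - margin:
            heading = _steer_toward(heading, math.pi, motion.wall_turn_gain * dt)
        if py < margin:
            heading = _steer_toward(heading, math.pi / 2, motion.wall_turn_gain * dt)
        elif py > side - margin:
            heading = _steer_toward(heading, -math.pi / 2, motion.wall_turn_gain * dt)

        px += step * math.cos(heading)
        py += step * math.sin(heading)
        # specular reflection keeps the path inside the box
        if px < 0:
            px = -px
            heading = math.pi - heading
        elif px > side:
            px = 2 * side - px
            heading = math.pi - heading
        if py < 0:
            py = -py
            heading = -heading
        elif py > side:
            py = 2 * side - py
            heading = -heading
        x[k] = min(max(px, eps), side - eps)
        y[k] = min(max(py, eps), side - eps)
        px, py = x[k], y[k]

    t = t_start + np.arange(n) / frame_rate
    return Trajectory(t=t, x=x, y=y, frame_rate=frame_rate)


def _steer_toward(heading: float, target: float, gain: float) -> float:
    delta = math.atan2(math.sin(target - heading), math.cos(target - heading))
    return heading + min(1.0, gain) * delta


def nearest_frame_index(times: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Index of the temporally nearest frame for each time; ties -> earlier frame."""
    times = np.asarray(times, dtype=float)
    hi = np.searchsorted(frame_times, times)
    hi = np.clip(hi, 1, len(frame_times) - 1)
    lo = hi - 1
    # strict '<' sends exact midpoints to the earlier frame
    pick_hi = (frame_times[hi] - times) < (times - frame_times[lo])
    return np.where(pick_hi, hi, lo)


# ---------------------------------------------------------------------------
# Place-cell tuning and spiking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TuningSpec:
    """Gaussian spatial tuning of one unit, plus its dynamics tag."""

    center: tuple[float, float]
    width_sigma: float
    peak_rate: float
    baseline_rate: float = 0.0
    dynamics: str = "stable"

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.baseline_rate < 0 or self.peak_rate < self.baseline_rate:
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.dynamics not in DYNAMICS_CLASSES:
            raise ValueError(f"unknown dynamics tag {self.dynamics!r}")


def evaluate_tuning(
    spec: TuningSpec, position: tuple[float, float], arena: ArenaSpec | None = None
) -> float:
    """Firing rate (Hz) of the tuning curve at a position inside the arena."""
    arena = arena or ArenaSpec()
    x, y = position
    if not bool(np.all(arena.contains(x, y))):
        raise ValueError(f"position {position} outside the arena")
    return float(_rate_at(spec, np.asarray(x), np.asarray(y)))


def _rate_at(spec: TuningSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d2 = (x - spec.center[0]) ** 2 + (y - spec.center[1]) ** 2
    return spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * np.exp(
        -d2 / (2.0 * spec.width_sigma**2)
    )


def simulate_spikes(
    spec: TuningSpec,
    trajectory: Trajectory,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spike timestamps from an inhomogeneous Poisson process along the path.

    Uses Lewis-Shedler thinning: candidates from a homogeneous process at
    the tuning's maximum rate are kept with probability rate/max-rate, the
    rate being evaluated at the temporally nearest trajectory frame.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory is empty")
    rng = np.random.default_rng(seed)
    lam_max = max(spec.peak_rate, spec.baseline_rate)
    t0 = float(trajectory.t[0])
    span = trajectory.duration
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * span)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t0 + span, size=n_cand))
    idx = nearest_frame_index(cand, trajectory.t)
    rates = _rate_at(spec, trajectory.x[idx], trajectory.y[idx])
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rates / lam_max
    return cand[keep]


# ---------------------------------------------------------------------------
# Condition (drug) effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionEffect:
    """Perturbation applied to every tuning curve under a drug condition.

    The NMDAR-antagonist condition (CPP) is modelled as wider fields
    (``width_multiplier`` > 1), attenuated peaks, and field centers pulled
    toward the arena center; saline (SAL) is the identity.
    """

    condition: str = "SAL"
    width_multiplier: float = 1.0
    peak_attenuation: float = 1.0
    com_pull_to_center: float = 0.0

    def __post_init__(self) -> None:
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if not 0 < self.peak_attenuation <= 1:
            raise ValueError("peak_attenuation must be in (0, 1]")
        if not 0 <= self.com_pull_to_center <= 1:
            raise ValueError("com_pull_to_center must be in [0, 1]")

    @classmethod
    def saline(cls) -> "ConditionEffect":
        return cls("SAL", 1.0, 1.0, 0.0)

    @classmethod
    def cpp(
        cls,
        width_multiplier: float = 1.8,
        peak_attenuation: float = 0.75,
        com_pull_to_center: float = 0.3,
    ) -> "ConditionEffect":
        return cls("CPP", width_multiplier, peak_attenuation, com_pull_to_center)


def apply_condition(
    spec: TuningSpec, effect: ConditionEffect, arena: ArenaSpec | None = None
) -> TuningSpec:
    """Return the tuning under the condition effect (SAL is the identity)."""
    arena = arena or ArenaSpec()
    cx, cy = arena.center
    x = spec.center[0] + effect.com_pull_to_center * (cx - spec.center[0])
    y = spec.center[1] + effect.com_pull_to_center * (cy - spec.center[1])
    peak = spec.baseline_rate + effect.peak_attenuation * (spec.peak_rate - spec.baseline_rate)
    return dataclasses.replace(
        spec,
        center=(x, y),
        width_sigma=spec.width_sigma * effect.width_multiplier,
        peak_rate=peak,
    )


# ---------------------------------------------------------------------------
# Whole-session generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSpec:
    name: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SessionManifest:
    trials: tuple[TrialSpec, ...]
    condition: str
    seed: int
    arena: ArenaSpec
    layout: ObjectLayout

    def trial(self, name: str) -> TrialSpec:
        for tr in self.trials:
            if tr.name == name:
                return tr
        raise KeyError(f"no trial named {name!r} in manifest")


@dataclass(frozen=True)
class UnitGroundTruth:
    unit_id: int
    class_t1_t2: str
    class_t2_t3: str
    tuning_by_trial: Mapping[str, TuningSpec]
    spike_width_us: float = 320.0
    has_refractory_gap: bool = True


@dataclass(frozen=True)
class SessionDataset:
    manifest: SessionManifest
    trajectories: Mapping[str, Trajectory]
    spike_trains: Mapping[int, np.ndarray]
    ground_truth: Mapping[int, UnitGroundTruth]


def _normalized_probs(probs: Mapping[str, float], where: str) -> dict[str, float]:
    p = {c: float(probs.get(c, 0.0)) for c in DYNAMICS_CLASSES}
    if any(v < 0 or v > 1 for v in p.values()):
        raise ValueError(f"{where}: probabilities must lie in [0, 1]")
    total = sum(p.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{where}: class probabilities must sum to 1, got {total}")
    return p


@dataclass(frozen=True)
class CohortSpec:
    """Population-level recipe for one simulated session.

    ``class_probs_t1_t2`` / ``class_probs_t2_t3`` are marginal distributions
    over the five dynamics classes per transition.  The second transition is
    resampled consistently with each unit's activity state at the end of T2
    (restricted to compatible classes and renormalised).  When the class
    distributions are omitted they are built from ``fraction_inactive``:
    that mass is split between emerging and never-active units, and the
    active mass between stable, unstable, and vanishing cells.
    """

    n_units: int = 100
    fraction_inactive: float = 0.35
    class_probs_t1_t2: Mapping[str, float] | None = None
    class_probs_t2_t3: Mapping[str, float] | None = None
    condition_effect: ConditionEffect = field(default_factory=ConditionEffect.saline)
    # tuning population
    sigma_range_cm: tuple[float, float] = (3.0, 5.0)
    active_peak_log_mean: float = math.log(8.0)
    active_peak_log_sd: float = 0.4
    active_peak_floor_hz: float = 4.0
    inactive_peak_log_mean: float = math.log(1.0)
    inactive_peak_log_sd: float = 0.4
    inactive_peak_cap_hz: float = 2.5
    baseline_rate_hz: float = 0.05
    center_margin_cm: float = 5.0
    # unstable-unit displacement rule (near-follows / far-opposes)
    unstable_shift_range_cm: tuple[float, float] = (8.0, 14.0)
    near_cutoff_cm: float = 15.0
    # session structure
    trial_durations_s: tuple[float, float, float] = (900.0, 300.0, 300.0)
    inter_trial_delay_s: float = 600.0
    frame_rate: float = 30.0
    motion: MotionParams = field(default_factory=MotionParams)
    object_dwell_gain: float = 0.0

    def resolved_class_probs(self) -> tuple[dict[str, float], dict[str, float]]:
        if self.class_probs_t1_t2 is not None:
            p12 = _normalized_probs(self.class_probs_t1_t2, "class_probs_t1_t2")
        else:
            fi = self.fraction_inactive
            p12 = {
                "stable": 0.70 * (1 - fi),
                "unstable": 0.15 * (1 - fi),
                "vanishing": 0.15 * (1 - fi),
                "emerging": 0.55 * fi,
                "inactive": 0.45 * fi,
            }
        if self.class_probs_t2_t3 is not None:
            p23 = _normalized_probs(self.class_probs_t2_t3, "class_probs_t2_t3")
        else:
            p23 = {
                "stable": 0.45,
                "unstable": 0.20,
                "vanishing": 0.08,
                "emerging": 0.07,
                "inactive": 0.20,
            }
        return p12, p23


_ACTIVE_AFTER = {"stable", "unstable", "emerging"}
_ACTIVE_BEFORE = {"stable", "unstable", "vanishing"}


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_opm_session(
    cohort: CohortSpec,
    arena: ArenaSpec | None = None,
    layout: ObjectLayout | None = None,
    seed: int = 0,
) -> SessionDataset:
    """Generate a full OPM session (trajectories, spikes, ground truth)."""
    arena = arena or ArenaSpec()
    layout = layout or standard_layout(arena)
    if cohort.n_units <= 0:
        raise ValueError("n_units must be positive")
    if not 0 <= cohort.fraction_inactive <= 1:
        raise ValueError("fraction_inactive must be in [0, 1]")
    p12, p23 = cohort.resolved_class_probs()

    # --- manifest -----------------------------------------------------------
    trials = []
    t0 = 0.0
    for name, dur in zip(TRIAL_NAMES, cohort.trial_durations_s):
        trials.append(TrialSpec(name, t0, t0 + dur))
        t0 += dur + cohort.inter_trial_delay_s
    manifest = SessionManifest(
        trials=tuple(trials),
        condition=cohort.condition_effect.condition,
        seed=seed,
        arena=arena,
        layout=layout,
    )

    # --- trajectories (stream 0, fixed per trial) ---------------------------
    trajectories: dict[str, Trajectory] = {}
    for i, tr in enumerate(trials):
        bias = None
        objs = layout.objects(tr.name)
        if cohort.object_dwell_gain > 0 and objs:
            bias = ObjectBias(objects=objs, dwell_gain=cohort.object_dwell_gain)
        trajectories[tr.name] = generate_trajectory(
            duration=tr.duration,
            arena=arena,
            frame_rate=cohort.frame_rate,
            motion=cohort.motion,
            object_bias=bias,
            seed=_stream(seed, 0, i),
            t_start=tr.t_start,
        )

    # --- unit assignment (stream 1) -----------------------------------------
    rng_u = _stream(seed, 1)
    classes = list(DYNAMICS_CLASSES)
    mv = np.asarray(layout.move_vector, dtype=float)
    mv_unit = mv / np.linalg.norm(mv)
    moving_t2 = np.asarray(layout.moving_object_t2.center, dtype=float)
    lo, hi = cohort.center_margin_cm, arena.side_length - cohort.center_margin_cm

    ground_truth: dict[int, UnitGroundTruth] = {}
    for uid in range(cohort.n_units):
        sigma = rng_u.uniform(*cohort.sigma_range_cm)
        active_peak = max(
            cohort.active_peak_floor_hz,
            float(rng_u.lognormal(cohort.active_peak_log_mean, cohort.active_peak_log_sd)),
        )
        inactive_peak = min(
            cohort.inactive_peak_cap_hz,
            float(rng_u.lognormal(cohort.inactive_peak_log_mean, cohort.inactive_peak_log_sd)),
        )
        inactive_peak = max(inactive_peak, cohort.baseline_rate_hz)
        c1 = np.array([rng_u.uniform(lo, hi), rng_u.uniform(lo, hi)])

        label12 = rng_u.choice(classes, p=[p12[c] for c in classes])
        active_t2 = label12 in _ACTIVE_AFTER
        allowed = _ACTIVE_BEFORE if active_t2 else {"emerging", "inactive"}
        w = np.array([p23[c] if c in allowed else 0.0 for c in classes])
        if w.sum() <= 0:
            raise ValueError(
                "class_probs_t2_t3 leaves no admissible class for a unit "
                f"{'active' if active_t2 else 'inactive'} at the end of T2"
            )
        label23 = rng_u.choice(classes, p=w / w.sum())

        c2 = c1.copy()
        if label12 == "unstable":
            ang = rng_u.uniform(0.0, 2.0 * math.pi)
            mag = rng_u.uniform(*cohort.unstable_shift_range_cm)
            c2 = c1 + mag * np.array([math.cos(ang), math.sin(ang)])
            c2 = np.clip(c2, lo, hi)
        c3 = c2.copy()
        if label23 == "unstable":
            d_obj = float(np.linalg.norm(c2 - moving_t2))
            direction = mv_unit if d_obj < cohort.near_cutoff_cm else -mv_unit
            mag = rng_u.uniform(*cohort.unstable_shift_range_cm)
            c3 = np.clip(c2 + mag * direction, lo, hi)

        active_by_trial = {
            "T1": label12 in _ACTIVE_BEFORE,
            "T2": active_t2,
            "T3": label23 in _ACTIVE_AFTER,
        }
        centers = {"T1": c1, "T2": c2, "T3": c3}
        tuning = {}
        for name in TRIAL_NAMES:
            peak = active_peak if active_by_trial[name] else inactive_peak
            base = TuningSpec(
                center=(float(centers[name][0]), float(centers[name][1])),
                width_sigma=sigma,
                peak_rate=peak,
                baseline_rate=cohort.baseline_rate_hz,
                dynamics=label12 if name != "T3" else label23,
            )
            tuning[name] = apply_condition(base, cohort.condition_effect, arena)
        ground_truth[uid] = UnitGroundTruth(
            unit_id=uid,
            class_t1_t2=str(label12),
            class_t2_t3=str(label23),
            tuning_by_trial=tuning,
        )

    # --- spiking (stream 2 per unit) ----------------------------------------
    spike_trains: dict[int, np.ndarray] = {}
    for uid, gt in ground_truth.items():
        pieces = []
        for j, name in enumerate(TRIAL_NAMES):
            pieces.append(
                simulate_spikes(
                    gt.tuning_by_trial[name],
                    trajectories[name],
                    seed=_stream(seed, 2, uid, j),
                )
            )
        spike_trains[uid] = np.concatenate(pieces) if pieces else np.empty(0)

    return SessionDataset(
        manifest=manifest,
        trajectories=trajectories,
        spike_trains=spike_trains,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# On-disk session format (plain text, matching what the analysis reads)
# ---------------------------------------------------------------------------


def write_session(dataset: SessionDataset, outdir: str | Path) -> Path:
    """Write a session in the analysis input format.

    Layout: ``manifest.yaml``, ``tracking_<trial>.csv`` (time_s,x_cm,y_cm),
    ``spikes/unit_<id>.csv`` (time_s), and a ``ground_truth.csv`` sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = dataset.manifest
    manifest_doc = {
        "condition": m.condition,
        "seed": int(m.seed),
        "arena": {"side_length_cm": m.arena.side_length, "bin_size_cm": m.arena.bin_size},
        "trials": [
            {"name": tr.name, "t_start_s": float(tr.t_start), "t_end_s": float(tr.t_end)}
            for tr in m.trials
        ],
        "objects": {
            trial: [
                {
                    "label": o.label,
                    "x_cm": float(o.center[0]),
                    "y_cm": float(o.center[1]),
                    "base_diameter_cm": float(o.base_diameter),
                }
                for o in m.layout.objects(trial)
            ]
            for trial in TRIAL_NAMES
            if m.layout.objects(trial)
        },
        "move_vector_cm": [float(v) for v in m.layout.move_vector],
        "units": sorted(int(u) for u in dataset.spike_trains),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest_doc, sort_keys=True))

    for name, traj in dataset.trajectories.items():
        df = pd.DataFrame({"time_s": traj.t, "x_cm": traj.x, "y_cm": traj.y})
        df.to_csv(outdir / f"tracking_{name}.csv", index=False, float_format="%.6f")

    spikes_dir = outdir / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for uid, train in dataset.spike_trains.items():
        pd.DataFrame({"time_s": np.asarray(train)}).to_csv(
            spikes_dir / f"unit_{uid:04d}.csv", index=False, float_format="%.6f"
        )

    rows = []
    for uid in sorted(dataset.ground_truth):
        gt = dataset.ground_truth[uid]
        row = {"unit_id": uid, "class_t1_t2": gt.class_t1_t2, "class_t2_t3": gt.class_t2_t3}
        for name in TRIAL_NAMES:
            tu = gt.tuning_by_trial[name]
            row.update(
                {
                    f"{name}_center_x_cm": tu.center[0],
                    f"{name}_center_y_cm": tu.center[1],
                    f"{name}_sigma_cm": tu.width_sigma,
                    f"{name}_peak_hz": tu.peak_rate,
                    f"{name}_baseline_hz": tu.baseline_rate,
                }
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    return outdir


def read_session(indir: str | Path) -> SessionDataset:
    """Read a session written by :func:`write_session` (ground truth optional)."""
    indir = Path(indir)
    doc = yaml.safe_load((indir / "manifest.yaml").read_text())
    arena = ArenaSpec(
        side_length=float(doc["arena"]["side_length_cm"]),
        bin_size=float(doc["arena"]["bin_size_cm"]),
    )
    objects_by_trial = {
        trial: tuple(
            ObjectSpec(
                label=o["label"],
                center=(float(o["x_cm"]), float(o["y_cm"])),
                base_diameter=float(o["base_diameter_cm"]),
            )
            for o in objs
        )
        for trial, objs in doc.get("objects", {}).items()
    }
    layout = ObjectLayout(
        objects_by_trial=objects_by_trial,
        move_vector=tuple(float(v) for v in doc["move_vector_cm"]),
    )
    trials = tuple(
        TrialSpec(tr["name"], float(tr["t_start_s"]), float(tr["t_end_s"]))
        for tr in doc["trials"]
    )
    manifest = SessionManifest(
        trials=trials,
        condition=str(doc["condition"]),
        seed=int(doc["seed"]),
        arena=arena,
        layout=layout,
    )
    trajectories = {}
    for tr in trials:
        df = pd.read_csv(indir / f"tracking_{tr.name}.csv")
        t = df["time_s"].to_numpy()
        frame_rate = round(1.0 / float(np.median(np.diff(t)))) if len(t) > 1 else 30.0
        trajectories[tr.name] = Trajectory(
            t=t, x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy(), frame_rate=float(frame_rate)
        )
    spike_trains = {}
    for uid in doc["units"]:
        df = pd.read_csv(indir / "spikes" / f"unit_{uid:04d}.csv")
        spike_trains[int(uid)] = df["time_s"].to_numpy()

    ground_truth: dict[int, UnitGroundTruth] = {}
    gt_path = indir / "ground_truth.csv"
    if gt_path.exists():
        gdf = pd.read_csv(gt_path)
        for _, row in gdf.iterrows():
            uid = int(row["unit_id"])
            tuning = {
                name: TuningSpec(
                    center=(float(row[f"{name}_center_x_cm"]), float(row[f"{name}_center_y_cm"])),
                    width_sigma=float(row[f"{name}_sigma_cm"]),
                    peak_rate=float(row[f"{name}_peak_hz"]),
                    baseline_rate=float(row[f"{name}_baseline_hz"]),
                    dynamics=str(row["class_t1_t2"]) if name != "T3" else str(row["class_t2_t3"]),
                )
                for name in TRIAL_NAMES
            }
            ground_truth[uid] = UnitGroundTruth(
                unit_id=uid,
                class_t1_t2=str(row["class_t1_t2"]),
                class_t2_t3=str(row["class_t2_t3"]),
                tuning_by_trial=tuning,
            )
    return SessionDataset(
        manifest=manifest,
        trajectories=trajectories,
        spike_trains=spike_trains,
        ground_truth=ground_truth,
    )
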