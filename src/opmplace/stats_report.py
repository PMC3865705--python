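"""Group statistics and the end-to-end analysis pipeline.

The statistical scheme mirrors common systems-neuroscience practice: each
sample is gated through a Shapiro-Wilk normality test; normally distributed
pairs are compared with Student's t-test (described as mean +/- s.e.m.),
non-normal pairs with a two-sample Kolmogorov-Smirnov or Mann-Whitney U
test (median +/- IQR).  Class-frequency differences between groups use the
chi-square test on the group x class contingency table.  No multiple-testing
correction is applied; the report counts the tests it ran.

``run_pipeline`` glues the whole package together: generate or load OPM
sessions, build rate maps, compute per-unit and per-transition metrics,
classify dynamics, score behavior, and write a deterministic report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior as beh
from . import dynamics as dyn
from . import metrics as met
from . import ratemap as rm
from . import synthetic_data as sd

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    groups: tuple[str, str]
    n: tuple[int, int]
    normal: tuple[bool, bool]
    test: str  # 't' | 'KS' | 'Mann-Whitney' | 'chi-square' | 'ANOVA'
    statistic: float
    p: float
    descriptives: tuple[dict, dict]

    @property
    def significant(self) -> bool:
        return self.p < DEFAULT_ALPHA


def _mean_sem(x: np.ndarray) -> dict:
    return {
        "family": "mean±sem",
        "center": float(np.mean(x)),
        "spread": float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0,
    }


def _median_iqr(x: np.ndarray) -> dict:
    q1, q3 = np.percentile(x, [25, 75])
    return {"family": "median±IQR", "center": float(np.median(x)), "spread": float(q3 - q1)}


def compare_groups(
    a,
    b,
    metric: str = "metric",
    groups: tuple[str, str] = ("A", "B"),
    alpha: float = DEFAULT_ALPHA,
    nonparam_test: str = "KS",
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Both samples pass Shapiro-Wilk at ``alpha`` -> Student's t-test with
    mean +/- s.e.m. descriptives; otherwise the configured nonparametric
    test ('KS' or 'Mann-Whitney') with median +/- IQR.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    if nonparam_test not in ("KS", "Mann-Whitney"):
        raise ValueError("nonparam_test must be 'KS' or 'Mann-Whitney'")
    normal_a = bool(stats.shapiro(a).pvalue > alpha) if np.ptp(a) > 0 else False
    normal_b = bool(stats.shapiro(b).pvalue > alpha) if np.ptp(b) > 0 else False
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        test, desc = "t", (_mean_sem(a), _mean_sem(b))
    elif nonparam_test == "KS":
        res = stats.ks_2samp(a, b)
        test, desc = "KS", (_median_iqr(a), _median_iqr(b))
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test, desc = "Mann-Whitney", (_median_iqr(a), _median_iqr(b))
    return GroupComparison(
        metric=metric,
        groups=groups,
        n=(len(a), len(b)),
        normal=(normal_a, normal_b),
        test=test,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        descriptives=desc,
    )


def anova_groups(*samples, metric: str = "metric") -> dict:
    """One-way ANOVA across 2+ groups (used for the behavior report only)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    res = stats.f_oneway(*[np.asarray(s, dtype=float) for s in samples])
    return {"metric": metric, "test": "ANOVA", "F": float(res.statistic), "p": float(res.pvalue)}


def class_frequency_test(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int], groups: tuple[str, str] = ("A", "B")
) -> GroupComparison:
    """Chi-square test on the group x class contingency table.

    Computed without continuity correction, so the statistic equals the
    textbook sum of (O-E)^2/E over all cells.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("both groups must count the same class set")
    classes = sorted(counts_a)
    table = np.array([[counts_a[c] for c in classes], [counts_b[c] for c in classes]], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two classes with nonzero totals; merge classes")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("zero expected count; merge sparse classes before testing")
    na, nb = int(table[0].sum()), int(table[1].sum())
    return GroupComparison(
        metric="class frequencies",
        groups=groups,
        n=(na, nb),
        normal=(False, False),
        test="chi-square",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        descriptives=({"family": "counts", "center": na, "spread": 0.0},
                      {"family": "counts", "center": nb, "spread": 0.0}),
    )


def gate_type_one_error(
    n_per_group: int = 30,
    n_reps: int = 2000,
    alpha: float = DEFAULT_ALPHA,
    nonparam_test: str = "KS",
    seed: int = 0,
) -> float:
    """Empirical type-I error of the full gated procedure under a normal null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        if compare_groups(a, b, nonparam_test=nonparam_test, alpha=alpha).p < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# Session analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis thresholds in one place (every value is logged)."""

    min_occupancy_s: float = rm.DEFAULT_MIN_OCCUPANCY_S
    kernel_radius_bins: int = 2
    kernel_sigma_bins: float = 1.0
    active_threshold_hz: float = dyn.ACTIVE_THRESHOLD_HZ
    stability_boundary_cm: float = dyn.STABILITY_BOUNDARY_CM
    speed_threshold_cm_s: float = beh.DEFAULT_SPEED_THRESHOLD_CM_S
    similarity_on: str = "smoothed"  # or "raw"
    nonparam_test: str = "KS"
    alpha: float = DEFAULT_ALPHA


def analyze_session(
    dataset: sd.SessionDataset, config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run rate maps -> metrics -> dynamics -> behavior for one session.

    Returns tidy tables: ``unit_trial`` (per unit per trial), ``transitions``
    (per unit per transition), and ``behavior`` (one row per trial).
    """
    cfg = config or AnalysisConfig()
    if not dataset.spike_trains:
        raise ValueError("empty cohort: session contains no units")
    m = dataset.manifest
    grid = rm.GridSpec.from_arena(m.arena)
    condition = m.condition

    occ: dict[str, rm.OccupancyMap] = {}
    for tr in m.trials:
        occ[tr.name] = rm.bin_occupancy(dataset.trajectories[tr.name], grid)

    smoothed: dict[tuple[int, str], rm.RateMap] = {}
    raw: dict[tuple[int, str], rm.RateMap] = {}
    unit_rows = []
    for uid in sorted(dataset.spike_trains):
        train = np.asarray(dataset.spike_trains[uid])
        for tr in m.trials:
            traj = dataset.trajectories[tr.name]
            sel = train[(train >= tr.t_start) & (train <= tr.t_end)]
            counts = rm.bin_spikes(sel, traj, grid)
            rmap = rm.compute_rate_map(occ[tr.name], counts, cfg.min_occupancy_s)
            smap = rm.smooth_rate_map(rmap, cfg.kernel_radius_bins, cfg.kernel_sigma_bins)
            raw[(uid, tr.name)] = rmap
            smoothed[(uid, tr.name)] = smap
            summary = met.summarize_rates(smap, occ[tr.name])
            try:
                si = met.spatial_information(smap, occ[tr.name])
                si_spike, si_sec = si.bits_per_spike, si.bits_per_second
            except ValueError:  # silent unit
                si_spike = si_sec = float("nan")
            fld = met.detect_place_field(smap)
            if summary.peak_rate > 0:
                scope = "field-restricted" if fld is not None else "full-map"
                com = met.center_of_mass(smap, scope=scope, fieldref=fld)
                com_x, com_y = com.x, com.y
            else:
                scope, com_x, com_y = "undefined", float("nan"), float("nan")
            unit_rows.append(
                {
                    "unit_id": uid,
                    "trial": tr.name,
                    "condition": condition,
                    "n_spikes": int(len(sel)),
                    "peak_hz": summary.peak_rate,
                    "mean_hz": summary.mean_rate,
                    "si_bits_per_spike": si_spike,
                    "si_bits_per_second": si_sec,
                    "field_size_cm2": fld.size_cm2 if fld is not None else float("nan"),
                    "field_n_pixels": fld.n_pixels if fld is not None else 0,
                    "com_x_cm": com_x,
                    "com_y_cm": com_y,
                    "com_scope": scope,
                }
            )
    unit_trial = pd.DataFrame(unit_rows)

    # --- transitions --------------------------------------------------------
    mv = m.layout.move_vector
    moving_t2 = m.layout.moving_object_t2.center if m.layout.objects("T3") else None
    trans_rows = []
    for uid in sorted(dataset.spike_trains):
        for before, after in (("T1", "T2"), ("T2", "T3")):
            transition = f"{before}->{after}"
            row_b = unit_trial.query("unit_id == @uid and trial == @before").iloc[0]
            row_a = unit_trial.query("unit_id == @uid and trial == @after").iloc[0]
            sum_b = met.RateSummary(row_b["peak_hz"], row_b["mean_hz"])
            sum_a = met.RateSummary(row_a["peak_hz"], row_a["mean_hz"])
            map_b, map_a = smoothed[(uid, before)], smoothed[(uid, after)]
            try:
                shift = met.com_shift(map_b, map_a)
                shift_cm = shift["distance"]
                com_vec = shift["vector"]
                com_pair = (shift["com_a"], shift["com_b"])
            except ValueError:
                shift_cm, com_vec, com_pair = float("nan"), (float("nan"),) * 2, None
            label = dyn.classify_transition(
                sum_b,
                sum_a,
                transition=transition,
                threshold_hz=cfg.active_threshold_hz,
                com_shift_cm=shift_cm if not math.isnan(shift_cm) else None,
                stability_boundary_cm=cfg.stability_boundary_cm,
            )
            if cfg.similarity_on == "raw":
                sim = met.similarity_score(raw[(uid, before)], raw[(uid, after)])
            else:
                sim = met.similarity_score(map_b, map_a)
            vec_idx = t2_dist = float("nan")
            if transition == "T2->T3" and moving_t2 is not None and com_pair is not None:
                vec_idx = dyn.vector_index(com_pair[0], com_pair[1], mv)
                t2_dist = math.hypot(
                    com_pair[0].x - moving_t2[0], com_pair[0].y - moving_t2[1]
                )
            prox = float("nan")
            objs = m.layout.objects(after)
            if objs and com_pair is not None:
                prox = met.object_proximity(com_pair[1], objs)["distance"]
            trans_rows.append(
                {
                    "unit_id": uid,
                    "transition": transition,
                    "condition": condition,
                    "class": label.label,
                    "stability": label.stability if label.stability else "n/a",
                    "com_shift_cm": shift_cm,
                    "similarity_r": sim.r,
                    "object_proximity_cm": prox,
                    "vector_index_cm": vec_idx,
                    "t2_distance_cm": t2_dist,
                }
            )
    transitions = pd.DataFrame(trans_rows)

    # --- behavior -----------------------------------------------------------
    behavior_rows = []
    for tr in m.trials:
        traj = dataset.trajectories[tr.name]
        row: dict = {
            "trial": tr.name,
            "condition": condition,
            "pct_time_moving": beh.percent_time_moving(traj, cfg.speed_threshold_cm_s),
        }
        objs = m.layout.objects(tr.name)
        if objs:
            episodes = beh.detect_object_visits(traj, objs)
            for obj in objs:
                row[f"time_{obj.label}_s"] = beh.total_visit_time(episodes, obj.label)
                row[f"visits_{obj.label}"] = beh.visit_count(episodes, obj.label)
        behavior_rows.append(row)
    behavior_df = pd.DataFrame(behavior_rows)
    t2 = behavior_df.query("trial == 'T2'")
    if not t2.empty and "time_right_s" in t2.columns:
        try:
            ratio = beh.exploration_ratio(
                float(t2["time_left_s"].iloc[0]), float(t2["time_right_s"].iloc[0])
            )
            behavior_df.loc[behavior_df["trial"] == "T2", "exploration_ratio_quotient"] = ratio.quotient
            behavior_df.loc[behavior_df["trial"] == "T2", "exploration_ratio_di"] = ratio.discrimination
        except ValueError:
            pass
    t3 = behavior_df.query("trial == 'T3'")
    if not t3.empty and "time_moved_s" in t3.columns:
        try:
            behavior_df.loc[behavior_df["trial"] == "T3", "opm_ratio"] = beh.opm_ratio(
                float(t3["time_moved_s"].iloc[0]), float(t3["time_stable_s"].iloc[0])
            )
        except ValueError:
            pass

    return {"unit_trial": unit_trial, "transitions": transitions, "behavior": behavior_df}


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------


def _comparison_row(c: GroupComparison) -> dict:
    da, db = c.descriptives
    return {
        "metric": c.metric,
        "group_a": c.groups[0],
        "group_b": c.groups[1],
        "n_a": c.n[0],
        "n_b": c.n[1],
        "test": c.test,
        "statistic": c.statistic,
        "p": c.p,
        "desc_family": da["family"],
        "center_a": da["center"],
        "spread_a": da["spread"],
        "center_b": db["center"],
        "spread_b": db["spread"],
    }


def cohort_report(
    results_by_condition: Mapping[str, dict[str, pd.DataFrame]],
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Between-condition statistics once 2+ conditions have been analysed."""
    cfg = config or AnalysisConfig()
    conditions = sorted(results_by_condition)
    classes_rows = []
    corr_rows = []
    stats_rows = []
    for cond in conditions:
        trans = results_by_condition[cond]["transitions"]
        for transition, tdf in trans.groupby("transition"):
            for cls in dyn.CLASSES:
                count = int((tdf["class"] == cls).sum())
                classes_rows.append(
                    {
                        "condition": cond,
                        "transition": transition,
                        "class": cls,
                        "count": count,
                        "percent": 100.0 * count / len(tdf),
                    }
                )
        t23 = trans.query("transition == 'T2->T3' and `class` == 'active'")
        records = [
            dyn.VectorIndexRecord(
                unit_id=int(r.unit_id),
                move_vector=(float("nan"), float("nan")),
                com_vector=(float("nan"), float("nan")),
                vector_index=float(r.vector_index_cm),
                t2_distance_to_moving_object=float(r.t2_distance_cm),
                com_shift=float(r.com_shift_cm),
                stability=None if r.stability == "n/a" else str(r.stability),
            )
            for r in t23.itertuples()
            if not math.isnan(r.vector_index_cm)
        ]
        if records:
            ova = dyn.object_vector_analysis(records)
            for subset, pairs in ova.items():
                for pair, res in pairs.items():
                    corr_rows.append(
                        {
                            "condition": cond,
                            "subset": subset,
                            "pair": pair,
                            "r": res["r"],
                            "p": res["p"],
                            "n": res["n"],
                        }
                    )
    if len(conditions) == 2:
        ca, cb = conditions
        ua = results_by_condition[ca]["unit_trial"]
        ub = results_by_condition[cb]["unit_trial"]
        for metric in ("field_size_cm2", "si_bits_per_spike", "peak_hz"):
            a = ua.query("trial == 'T1'")[metric].dropna().to_numpy()
            b = ub.query("trial == 'T1'")[metric].dropna().to_numpy()
            if len(a) >= 3 and len(b) >= 3:
                stats_rows.append(
                    _comparison_row(
                        compare_groups(a, b, metric=f"T1 {metric}", groups=(ca, cb),
                                       alpha=cfg.alpha, nonparam_test=cfg.nonparam_test)
                    )
                )
        ta = results_by_condition[ca]["transitions"]
        tb = results_by_condition[cb]["transitions"]
        for transition in dyn.TRANSITIONS:
            a = ta.query("transition == @transition and `class` == 'active'")[
                "com_shift_cm"
            ].dropna().to_numpy()
            b = tb.query("transition == @transition and `class` == 'active'")[
                "com_shift_cm"
            ].dropna().to_numpy()
            if len(a) >= 3 and len(b) >= 3:
                stats_rows.append(
                    _comparison_row(
                        compare_groups(a, b, metric=f"{transition} COM shift (active)",
                                       groups=(ca, cb), alpha=cfg.alpha,
                                       nonparam_test=cfg.nonparam_test)
                    )
                )
            cls_a = ta.loc[ta["transition"] == transition, "class"]
            cls_b = tb.loc[tb["transition"] == transition, "class"]
            counts_a = {c: int((cls_a == c).sum()) for c in dyn.CLASSES}
            counts_b = {c: int((cls_b == c).sum()) for c in dyn.CLASSES}
            try:
                chi = class_frequency_test(counts_a, counts_b, groups=(ca, cb))
                stats_rows.append(_comparison_row(
                    dataclasses.replace(chi, metric=f"{transition} class frequencies")))
            except ValueError:
                pass
    return {
        "cohort_classes": pd.DataFrame(classes_rows),
        "correlations": pd.DataFrame(corr_rows),
        "group_stats": pd.DataFrame(stats_rows),
    }


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_DEF_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=_DEF_FLOAT_FMT)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    return doc


def _analysis_config(doc: Mapping) -> AnalysisConfig:
    sub = doc.get("analysis", {})
    kernel = sub.get("kernel", {})
    return AnalysisConfig(
        min_occupancy_s=float(sub.get("min_occupancy_s", rm.DEFAULT_MIN_OCCUPANCY_S)),
        kernel_radius_bins=int(kernel.get("radius_bins", 2)),
        kernel_sigma_bins=float(kernel.get("sigma_bins", 1.0)),
        active_threshold_hz=float(sub.get("active_threshold_hz", dyn.ACTIVE_THRESHOLD_HZ)),
        stability_boundary_cm=float(sub.get("stability_boundary_cm", dyn.STABILITY_BOUNDARY_CM)),
        speed_threshold_cm_s=float(sub.get("speed_threshold_cm_s", beh.DEFAULT_SPEED_THRESHOLD_CM_S)),
        similarity_on=str(sub.get("similarity_on", "smoothed")),
        nonparam_test=str(sub.get("nonparam_test", "KS")),
        alpha=float(sub.get("alpha", DEFAULT_ALPHA)),
    )


def _cohort_spec(doc: Mapping, condition: str) -> sd.CohortSpec:
    syn = doc.get("synthetic", {})
    n_units = int(syn.get("n_units", 100))
    if n_units <= 0:
        raise ValueError("empty cohort: synthetic.n_units must be positive")
    effect = (
        sd.ConditionEffect.cpp(**syn.get("cpp_effect", {}))
        if condition == "CPP"
        else sd.ConditionEffect.saline()
    )
    kwargs = dict(
        n_units=n_units,
        fraction_inactive=float(syn.get("fraction_inactive", 0.35)),
        condition_effect=effect,
        object_dwell_gain=float(syn.get("object_dwell_gain", 0.0)),
    )
    if "class_probs_t1_t2" in syn:
        kwargs["class_probs_t1_t2"] = syn["class_probs_t1_t2"]
    if "class_probs_t2_t3" in syn:
        kwargs["class_probs_t2_t3"] = syn["class_probs_t2_t3"]
    if "trial_durations_s" in syn:
        kwargs["trial_durations_s"] = tuple(float(v) for v in syn["trial_durations_s"])
    return sd.CohortSpec(**kwargs)


def run_pipeline(config: str | Path | Mapping, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis and write a deterministic report bundle.

    The config either names session directories (``sessions:``, written by
    the generator or exported from tracking/spike files in the same layout)
    or describes a synthetic cohort (``synthetic:``) with one session per
    condition.  Identical config + seed reproduce the bundle byte for byte.
    """
    doc = load_config(config)
    if seed is None:
        seed = int(doc.get("seed", 0))
    cfg = _analysis_config(doc)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results_by_condition: dict[str, dict[str, pd.DataFrame]] = {}
    session_dirs: dict[str, Path] = {}
    if "sessions" in doc:
        for path in doc["sessions"]:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"session directory not found: {p}")
            ds = sd.read_session(p)
            results_by_condition[ds.manifest.condition] = analyze_session(ds, cfg)
            session_dirs[ds.manifest.condition] = p
    else:
        conditions = [str(c) for c in doc.get("synthetic", {}).get("conditions", ["SAL"])]
        for i, cond in enumerate(conditions):
            cohort = _cohort_spec(doc, cond)
            ds = sd.generate_opm_session(cohort, seed=seed + i)
            sess_dir = outdir / f"session_{cond}"
            sd.write_session(ds, sess_dir)
            session_dirs[cond] = sess_dir
            results_by_condition[cond] = analyze_session(ds, cfg)

    if not results_by_condition:
        raise ValueError("empty cohort: no sessions to analyze")

    hashes: dict[str, str] = {}
    unit_trial = pd.concat(
        [r["unit_trial"] for r in results_by_condition.values()], ignore_index=True
    ).sort_values(["condition", "unit_id", "trial"], kind="mergesort")
    transitions = pd.concat(
        [r["transitions"] for r in results_by_condition.values()], ignore_index=True
    ).sort_values(["condition", "unit_id", "transition"], kind="mergesort")
    behavior_df = pd.concat(
        [r["behavior"] for r in results_by_condition.values()], ignore_index=True
    ).sort_values(["condition", "trial"], kind="mergesort")
    hashes["unit_trial_metrics.csv"] = _write_csv(unit_trial, outdir / "unit_trial_metrics.csv")
    hashes["transitions.csv"] = _write_csv(transitions, outdir / "transitions.csv")
    hashes["behavior.csv"] = _write_csv(behavior_df, outdir / "behavior.csv")

    report = cohort_report(results_by_condition, cfg)
    for name, df in report.items():
        hashes[f"{name}.csv"] = _write_csv(df, outdir / f"{name}.csv")

    n_tests = len(report["group_stats"])
    log = {
        "seed": int(seed),
        "analysis": dataclasses.asdict(cfg),
        "sessions": {c: str(p) for c, p in sorted(session_dirs.items())},
        "n_group_tests_run": int(n_tests),
        "file_sha256": dict(sorted(hashes.items())),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))

    lines = ["OPM analysis summary", "===================="]
    for cond in sorted(results_by_condition):
        ut = results_by_condition[cond]["unit_trial"]
        tr = results_by_condition[cond]["transitions"]
        n_units = ut["unit_id"].nunique()
        lines.append(f"\ncondition {cond}: {n_units} units")
        for transition in dyn.TRANSITIONS:
            tdf = tr[tr["transition"] == transition]
            parts = ", ".join(
                f"{c}: {int((tdf['class'] == c).sum())}" for c in dyn.CLASSES
            )
            lines.append(f"  {transition}  {parts}")
    if not report["group_stats"].empty:
        lines.append("\ngroup comparisons (test, statistic, p):")
        for r in report["group_stats"].itertuples():
            lines.append(f"  {r.metric}: {r.test}, stat={r.statistic:.4g}, p={r.p:.4g}")
    lines.append(f"\ntests run without multiplicity correction: {n_tests}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "results_by_condition": results_by_condition,
        "report": report,
        "hashes": hashes,
        "outdir": outdir,
    }
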