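"""End-to-end orchestration: raw recordings → attractor comparisons →
cohort summaries and group statistics.

Stage order for one subject is fixed: read → low-pass filter → heel-strike
events (annotations if provided, else detection) → beginning/end windows →
stride cutting → time normalization → attractors → δM/δD/δF. Cohort runs
apply a partial-failure policy: a subject whose pipeline fails is skipped
and reported, not fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import attractor as core
from . import preprocessing as prep
from . import stats as gstats
from .exceptions import ComputationError, GaitError
from .signal_io import FEET, AccelerationTimeSeries, EventList, SessionManifest

ASSESSMENTS = ("baseline", "week10", "month12")
VARIABLES = ("delta_M", "delta_D", "delta_F", "six_mwd")


@dataclass
class PipelineConfig:
    """All analysis parameters; echoed verbatim into every output."""

    filter_cutoff_hz: float = 4.5
    filter_order: int = 4
    m: int = 200  # phase points per normalized cycle
    walkway_length: float = 30.0
    sqrt_mode: bool = True
    speed_correction: bool = False  # divide attractors by v for the reference
    outlier_low: float = 0.4
    outlier_high: float = 1.6
    detector_min_period_s: float = 0.5
    detector_max_period_s: float = 2.5
    detector_peak_separation: float = 0.7
    detector_search_back: float = 0.25
    prefer_annotations: bool = True
    mwu_mode: str = "auto"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Session:
    """One subject-assessment unit of work for a cohort run."""

    manifest: SessionManifest
    recordings: dict[str, AccelerationTimeSeries]
    events: dict[str, EventList] | None = None


@dataclass
class CohortResult:
    subject_table: pd.DataFrame
    group_table: pd.DataFrame
    stats_table: pd.DataFrame
    reference: dict = field(default_factory=dict)  # foot -> ReferenceAttractor
    reference_table: pd.DataFrame | None = None
    variability: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    config_hash: str = ""
    failures: list = field(default_factory=list)
    log: list = field(default_factory=list)


def run_subject(config: PipelineConfig,
                recordings: dict[str, AccelerationTimeSeries],
                manifest: SessionManifest,
                events: dict[str, EventList] | None = None):
    """Analyze one session; returns ``(AttractorComparison, row dict)``.

    ``row`` is one tidy record: the three metrics, the speed v, stride
    counts per window and foot, and the manifest covariates.
    """
    sid = manifest.subject_id

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GaitError as exc:
            raise ComputationError(f"subject {sid}, stage {name}: {exc}") from exc

    attractors = {}
    counts = {}
    speeds = []
    for foot in FEET:
        ts = recordings[foot]
        filtered = _stage("filter", prep.lowpass_filter, ts,
                          cutoff=config.filter_cutoff_hz,
                          order=config.filter_order)
        if events is not None and config.prefer_annotations:
            ev = events[foot]
        else:
            ev = _stage("events", prep.detect_heel_strikes, filtered,
                        min_period_s=config.detector_min_period_s,
                        max_period_s=config.detector_max_period_s,
                        peak_separation=config.detector_peak_separation,
                        search_back=config.detector_search_back)
        win_B, win_E = _stage("windows", prep.select_windows, ev, manifest,
                              filtered.n_samples, filtered.rate)
        for win in (win_B, win_E):
            strides = _stage("cut", prep.cut_strides, filtered, ev, win,
                             outlier_low=config.outlier_low,
                             outlier_high=config.outlier_high)
            cycles = [_stage("normalize", prep.normalize_cycle, s, m=config.m)
                      for s in strides]
            attractors[(foot, win.condition)] = _stage(
                "attractor", core.compute_attractor, cycles)
            counts[f"n_strides_{win.condition}_{foot}"] = len(strides)
            counts[f"n_discarded_{win.condition}_{foot}"] = win.n_strides - len(strides)
        speeds.extend([win_B.average_speed, win_E.average_speed])

    v = float(np.mean(speeds))
    comparison = _stage("metrics", core.compare_conditions, attractors, v,
                        sqrt_mode=config.sqrt_mode)
    row = {
        "subject_id": sid,
        "group": manifest.group,
        "assessment": manifest.assessment,
        "delta_M": comparison.delta_M,
        "delta_D": comparison.delta_D,
        "delta_F": comparison.delta_F,
        "v": v,
        "six_mwd": manifest.six_mwd,
        "odi_percent": manifest.odi_percent,
        **counts,
    }
    return comparison, row


def run_cohort(config: PipelineConfig, sessions) -> CohortResult:
    """Analyze a cohort of sessions and build every group-level product.

    Produces the per-subject table, group summaries, the healthy-group
    reference attractor with its between/within variability decomposition,
    and the group statistics (Mann-Whitney healthy vs patients per
    assessment; repeated-measures ANOVA with Bonferroni post-hoc tests
    across the patient assessments).
    """
    rows, failures, log = [], [], []
    healthy_attractors = {foot: [] for foot in FEET}
    healthy_within = {foot: [] for foot in FEET}

    for session in sessions:
        man = session.manifest
        try:
            comparison, row = run_subject(config, session.recordings, man,
                                          events=session.events)
        except GaitError as exc:
            failures.append({"subject_id": man.subject_id,
                             "assessment": man.assessment, "error": str(exc)})
            log.append(f"SKIP {man.subject_id}/{man.assessment}: {exc}")
            continue
        rows.append(row)
        if man.group == "healthy":
            for foot in FEET:
                att = comparison.attractors[(foot, "B")]
                if config.speed_correction:
                    att = core.Attractor(
                        mean_cycle=att.mean_cycle / comparison.v,
                        deviation=att.deviation / comparison.v,
                        n_strides=att.n_strides, foot=att.foot,
                        condition=att.condition)
                healthy_attractors[foot].append(att)
                healthy_within[foot].append(core.summarize_within_D(att))

    subject_table = pd.DataFrame(rows)
    reference, variability = {}, {}
    reference_table = None
    if all(len(v) >= 2 for v in healthy_attractors.values()):
        ref_frames = []
        for foot in FEET:
            ref = core.reference_attractor(healthy_attractors[foot])
            reference[foot] = ref
            within_mean = float(np.mean(healthy_within[foot]))
            variability[foot] = {
                "between_subject_D": ref.between_subject_D,
                "within_subject_D_mean": within_mean,
                "ratio": ref.between_subject_D / within_mean if within_mean else np.nan,
                "n_subjects": ref.n_subjects,
            }
            ref_frames.append(pd.DataFrame({
                "foot": foot,
                "tau": np.arange(ref.mean_cycle.shape[0]) / ref.mean_cycle.shape[0],
                "ax": ref.mean_cycle[:, 0], "ay": ref.mean_cycle[:, 1],
                "az": ref.mean_cycle[:, 2],
                "between_subject_sd": ref.between_subject_sd,
            }))
        reference_table = pd.concat(ref_frames, ignore_index=True)
    else:
        log.append("reference attractor skipped: fewer than 2 healthy subjects")

    group_table = _group_summaries(subject_table)
    stats_table = _group_statistics(config, subject_table, log)

    return CohortResult(
        subject_table=subject_table, group_table=group_table,
        stats_table=stats_table, reference=reference,
        reference_table=reference_table, variability=variability,
        config_echo=config.to_dict(), config_hash=config.config_hash,
        failures=failures, log=log)


def _group_summaries(subject_table: pd.DataFrame) -> pd.DataFrame:
    records = []
    if subject_table.empty:
        return pd.DataFrame(columns=["variable", "group", "assessment", "n",
                                     "mean", "sd", "median"])
    for (group, assessment), chunk in subject_table.groupby(["group", "assessment"]):
        for var in VARIABLES:
            vals = chunk[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            records.append({
                "variable": var, "group": group, "assessment": assessment,
                "n": int(vals.size), "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(np.median(vals)),
            })
    return pd.DataFrame(records)


def _group_statistics(config: PipelineConfig, subject_table: pd.DataFrame,
                      log: list) -> pd.DataFrame:
    columns = ["variable", "comparison", "test", "statistic", "p", "p_adjusted",
               "n_a", "n_b", "note"]
    if subject_table.empty:
        return pd.DataFrame(columns=columns)
    records = []
    healthy = subject_table[subject_table.group == "healthy"]
    patients = subject_table[subject_table.group == "patient"]
    if healthy.empty or patients.empty:
        log.append("group tests skipped: need both healthy and patient subjects")
    else:
        base_h = healthy[healthy.assessment == "baseline"]
        for assessment in ASSESSMENTS:
            chunk = patients[patients.assessment == assessment]
            if chunk.empty:
                continue
            for var in VARIABLES:
                a = base_h[var].dropna().to_numpy(dtype=float)
                b = chunk[var].dropna().to_numpy(dtype=float)
                if a.size == 0 or b.size == 0:
                    continue
                u, p = gstats.mann_whitney_u(a, b, mode=config.mwu_mode)
                records.append({
                    "variable": var,
                    "comparison": f"healthy-vs-patient-{assessment}",
                    "test": "mann_whitney_u", "statistic": u, "p": p,
                    "p_adjusted": np.nan, "n_a": a.size, "n_b": b.size,
                    "note": "",
                })
        # normality screen on the metric distributions actually compared
        for var in VARIABLES:
            for label, chunk in (("healthy", base_h), ("patient",
                                 patients[patients.assessment == "baseline"])):
                vals = chunk[var].dropna().to_numpy(dtype=float)
                if vals.size >= 3 and np.ptp(vals) > 0:
                    w, p = gstats.shapiro_wilk(vals)
                    records.append({
                        "variable": var, "comparison": f"{label}-baseline",
                        "test": "shapiro_wilk", "statistic": w, "p": p,
                        "p_adjusted": np.nan, "n_a": vals.size, "n_b": 0,
                        "note": "",
                    })

    # within-patient repeated measures across the three assessments
    if not patients.empty:
        for var in VARIABLES:
            wide = patients.pivot_table(index="subject_id", columns="assessment",
                                        values=var, aggfunc="first")
            present = [a for a in ASSESSMENTS if a in wide.columns]
            if len(present) < 2:
                continue
            matrix = wide[present].to_numpy(dtype=float)
            try:
                res = gstats.rm_anova(matrix)
            except ComputationError as exc:
                log.append(f"rm_anova skipped for {var}: {exc}")
                continue
            records.append({
                "variable": var, "comparison": "patients-across-assessments",
                "test": "rm_anova", "statistic": res.F, "p": res.p,
                "p_adjusted": np.nan, "n_a": res.n_complete, "n_b": 0,
                "note": (f"df=({res.df_treatment},{res.df_error}); "
                         f"dropped={res.n_dropped}; sphericity uncorrected"),
            })
            complete = matrix[~np.isnan(matrix).any(axis=1)]
            if complete.shape[0] >= 2:
                for item in gstats.paired_posthoc(complete, labels=present):
                    records.append({
                        "variable": var,
                        "comparison": f"posthoc-{item['pair'][0]}-vs-{item['pair'][1]}",
                        "test": "paired_t_bonferroni", "statistic": item["t"],
                        "p": item["p_raw"], "p_adjusted": item["p_adjusted"],
                        "n_a": complete.shape[0], "n_b": 0, "note": "",
                    })
    return pd.DataFrame(records, columns=columns)


def sessions_from_synthetic(synthetic_sessions, use_ground_truth_events=False):
    """Wrap ``(SyntheticRecording, SessionManifest)`` pairs as sessions.

    With ``use_ground_truth_events`` the analysis bypasses the detector and
    cuts strides at the generator's exact stride starts.
    """
    out = []
    for rec, manifest in synthetic_sessions:
        out.append(Session(manifest=manifest, recordings=rec.recordings,
                           events=rec.ground_truth_events
                           if use_ground_truth_events else None))
    return out
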