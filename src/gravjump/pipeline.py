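"""Per-trial orchestration and cross-trial aggregation.

``analyze_trial`` chains the stages — phase detection, gravity clustering,
EMG activity, ultrasound fascicle measurement (or a supplied fascicle
series), sarcomere estimation — into one per-phase report; ``aggregate``
groups reports into per-cluster per-phase summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.stats

from .core import (
    PHASES,
    EmptyResultError,
    GravjumpError,
    Trace,
    Trial,
    UndefinedStatisticError,
    log,
)
from .config import AnalysisConfig
from . import emg as emg_mod
from . import usseg
from .gravity import ClusterLabel, GravitySummary, assign_cluster, summarize_gravity
from .phases import PhaseMarks, mark_phases
from .sarcomere import LTModel, SarcomereEstimate


@dataclass
class PhaseReport:
    """Everything the analysis extracts from one trial."""

    trial_id: str
    cluster: ClusterLabel
    gravity: GravitySummary
    marks: PhaseMarks
    table: pd.DataFrame           # one row per phase
    delta_grf: float
    ankle_do: float
    n_sarc: float


def delta_grf(grf_total: Trace, marks: PhaseMarks, mode: str = "peak") -> float:
    """GRF change over the braking phase.

    ``"peak"``: maximum GRF within [GC, MAJ] minus the GRF at GC (default);
    ``"instant"``: GRF at MAJ minus GRF at GC.
    """
    t_gc, t_maj = marks.time("GC"), marks.time("MAJ")
    if t_maj < t_gc:
        raise ValueError("empty braking interval")
    at_gc = grf_total.value_at(t_gc)
    if mode == "peak":
        return float(np.max(grf_total.segment(t_gc, t_maj)) - at_gc)
    if mode == "instant":
        return float(grf_total.value_at(t_maj) - at_gc)
    raise ValueError(f"unknown delta_grf mode {mode!r}")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation with degenerate-input guards."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)


def _fascicle_lengths(trial: Trial, marks: PhaseMarks, cfg: AnalysisConfig,
                      lf_series: Optional[Mapping[str, float]]) -> dict:
    """Per-phase fascicle lengths: ultrasound route, supplied series, or truth."""
    if lf_series is not None:
        return dict(lf_series)
    if cfg.use_ultrasound and trial.frames is not None:
        frames = trial.frames
        frame_idx = marks.frame_indices(frames.rate, frames.t0)
        selected = dict(frame_idx)
        if cfg.include_braking_frames:
            for i in range(frame_idx["GC"], frame_idx["MAJ"] + 1):
                selected.setdefault(f"braking_{i}", i)
        labels = {v: k for k, v in frame_idx.items()}
        df = usseg.track_sequence(
            frames, selected.values(), "truth", config=cfg, phase_labels=labels
        )
        by_phase = df.set_index("phase")["lf_mm"]
        missing = [p for p in PHASES if p not in by_phase.index]
        if missing:
            raise GravjumpError(
                f"trial {trial.trial_id}: ultrasound measurement failed for "
                f"phase(s) {missing}"
            )
        return {p: float(by_phase[p]) for p in PHASES}
    if trial.truth is not None and trial.truth.lf_marks:
        log.info("trial %s: no frames; using ground-truth fascicle lengths",
                 trial.trial_id)
        return dict(trial.truth.lf_marks)
    raise GravjumpError(
        f"trial {trial.trial_id}: no fascicle length source (frames, series or truth)"
    )


def analyze_trial(
    trial: Trial,
    config: AnalysisConfig | None = None,
    lf_series: Optional[Mapping[str, float]] = None,
) -> PhaseReport:
    """Run the full per-trial analysis; deterministic given trial + config."""
    cfg = config or AnalysisConfig()
    try:
        marks = mark_phases(trial, cfg)
    except GravjumpError as exc:
        raise type(exc)(f"phase detection failed for {trial.trial_id}: {exc}") from exc

    gsum = summarize_gravity(trial.gravity_z, marks, cfg.gravity_lead_s)
    label = assign_cluster(gsum, trial.is_reference, cfg.gravity_dev_limit_g)
    if label.excluded:
        log.info("trial %s excluded: %s", trial.trial_id, label.reason)

    activities = {}
    for muscle, trace, ref in (
        ("GM", trial.emg_gm, trial.subject.mvc_gm),
        ("TA", trial.emg_ta, trial.subject.mvc_ta),
    ):
        for mark in PHASES:
            center = trace.index_at(marks.time(mark), clip=True)
            activities[(muscle, mark)] = emg_mod.window_activity(
                trace, center, ref, cfg.emg_halfwidth_s, muscle, mark
            )
    ratios = {
        m: emg_mod.gm_ta_ratio(activities[("GM", m)], activities[("TA", m)])
        for m in PHASES
    }

    lf = _fascicle_lengths(trial, marks, cfg, lf_series)
    est = SarcomereEstimate.from_fascicle_lengths(
        lf, trial.subject.lf_stand_mm, cfg.sl_ref_um,
        LTModel(cfg.lt_breakpoints),
    )

    rows = []
    for m in PHASES:
        rows.append({
            "phase": m,
            "time_s": marks.time(m),
            "lf_mm": est.lf_mm[m],
            "lf_norm_do": est.lf_norm_do[m],
            "sl_um": est.sl_um[m],
            "force_fraction": est.force_fraction[m],
            "gm_iemg": activities[("GM", m)].iemg_norm,
            "ta_iemg": activities[("TA", m)].iemg_norm,
            "gm_ta": ratios[m].gm_ta,
            "log_gm_ta": ratios[m].log_gm_ta,
            "frame_idx": marks.frame_index(m),
        })
    table = pd.DataFrame(rows)

    grf = trial.grf_total()
    return PhaseReport(
        trial_id=trial.trial_id,
        cluster=label,
        gravity=gsum,
        marks=marks,
        table=table,
        delta_grf=delta_grf(grf, marks, cfg.delta_grf_mode),
        ankle_do=trial.ankle.value_at(marks.time("DO")),
        n_sarc=est.n_sarc,
    )


@dataclass
class AggregateResult:
    phases: pd.DataFrame          # per-cluster per-phase mean/sd/n
    clusters: pd.DataFrame        # per-cluster delta_grf and ankle summaries
    n_excluded: int = 0


_PHASE_METRICS = ("lf_mm", "lf_norm_do", "sl_um", "force_fraction",
                  "gm_iemg", "ta_iemg", "gm_ta", "log_gm_ta")


def aggregate(reports: Iterable[PhaseReport]) -> AggregateResult:
    """Per-cluster per-phase mean +/- SD tables over non-excluded trials."""
    reports = list(reports)
    if not reports:
        raise EmptyResultError("no reports to aggregate")
    kept = [r for r in reports if not r.cluster.excluded]
    n_excl = len(reports) - len(kept)
    if n_excl:
        log.info("aggregate: %d of %d trials excluded", n_excl, len(reports))
    if not kept:
        raise EmptyResultError("all trials excluded; nothing to aggregate")

    long = pd.concat(
        [r.table.assign(cluster=r.cluster.name, trial_id=r.trial_id) for r in kept],
        ignore_index=True,
    )
    grouped = long.groupby(["cluster", "phase"], sort=False)
    parts = {"n": grouped.size()}
    for col in _PHASE_METRICS:
        parts[f"{col}_mean"] = grouped[col].mean()
        parts[f"{col}_sd"] = grouped[col].std().fillna(0.0)
    phases = pd.DataFrame(parts).reset_index()
    phases["phase"] = pd.Categorical(phases["phase"], categories=PHASES, ordered=True)
    phases = phases.sort_values(["cluster", "phase"]).reset_index(drop=True)

    per_trial = pd.DataFrame(
        {
            "cluster": [r.cluster.name for r in kept],
            "delta_grf": [r.delta_grf for r in kept],
            "ankle_do": [r.ankle_do for r in kept],
            "g_mean": [r.gravity.g_pre150_po_mean for r in kept],
        }
    )
    g = per_trial.groupby("cluster")
    clusters = pd.DataFrame({
        "n": g.size(),
        "delta_grf_mean": g["delta_grf"].mean(),
        "delta_grf_sd": g["delta_grf"].std().fillna(0.0),
        "ankle_do_mean": g["ankle_do"].mean(),
        "g_mean": g["g_mean"].mean(),
        "g_sd": g["g_mean"].std().fillna(0.0),
    }).reset_index()
    return AggregateResult(phases=phases, clusters=clusters, n_excluded=n_excl)


def report_to_csv(report: PhaseReport, path) -> None:
    """Write one trial's per-phase table (with trial metadata columns)."""
    df = report.table.assign(
        trial_id=report.trial_id,
        cluster=report.cluster.name,
        excluded=report.cluster.excluded,
        reason=report.cluster.reason,
        delta_grf=report.delta_grf,
        ankle_do=report.ankle_do,
    )
    df.to_csv(path, index=False, float_format="%.6g")
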