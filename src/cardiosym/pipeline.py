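"""End-to-end orchestration: simulate → preprocess → symbolise → analyse.

``run_pipeline`` generates (or loads) a cohort, turns every RR
recording into an analysis-ready segment, computes the V0/V1/V2
symbolic profiles, and runs the statistical layer: repeated-measures
ANOVA with sphericity handling, pairwise default-Bayes comparisons
with multiplicity-corrected prior odds (the report-table analogues),
and condition deltas for the time-trial outcomes.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import RepeatedMeasuresAnova, deltas, kruskal_fallback, shapiro_gate
from .bayes import BayesConfig, PairwiseBayes
from .preprocess import (
    DetrendConfig,
    best_stationary_window,
    detrend_smoothness_priors,
    filter_artifacts,
    select_supine_segment,
)
from .series import RRSeries
from .symbolic import SymbolicConfig, symbolic_profile
from .synth import (
    CONDITIONS,
    SUPINE_CONTEXTS,
    TT_CONTEXTS,
    AutonomicProfile,
    CohortSpec,
    default_cohort_spec,
    generate_study,
)

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "emit_tables",
            "process_recording", "save_config", "load_config"]

logger = logging.getLogger(__name__)

SYMBOLIC_VARS = ("v0_pct", "v1_pct", "v2_pct")


@dataclass(frozen=True)
class RunConfig:
    """Serialisable configuration of one full analysis run."""

    seed: int = 0
    out_dir: str | None = None
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    symbolic: SymbolicConfig = field(default_factory=SymbolicConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    artifact_threshold: float = 0.2
    detrend_enabled: bool = True
    tt_segment_length: int = 1000
    tt_segment_stride: int = 50
    supine_duration_s: float = 300.0
    cohort_overrides: dict = field(default_factory=dict)

    def cohort_spec(self) -> CohortSpec:
        return default_cohort_spec(seed=self.seed, **self.cohort_overrides)


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # dataclasses.asdict already flattens the nested configs to dicts
    return d


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["detrend"] = DetrendConfig(**d.get("detrend", {}))
    d["symbolic"] = SymbolicConfig(**d.get("symbolic", {}))
    d["bayes"] = BayesConfig(**d.get("bayes", {}))
    return RunConfig(**d)


def process_recording(series: RRSeries, config: RunConfig) -> dict:
    """One recording → one symbolic-profile row.

    Supine recordings contribute their first 5 minutes; time-trial
    recordings contribute their most stationary ``tt_segment_length``-beat
    window.  The segment is artifact-filtered, (optionally) detrended by
    smoothness priors, and symbolised.
    """
    filtered, report = filter_artifacts(series, config.artifact_threshold)
    if series.context in SUPINE_CONTEXTS or (
        series.context is None and filtered.duration_s >= config.supine_duration_s
    ):
        segment = select_supine_segment(filtered, config.supine_duration_s)
        start, score = 0, float("nan")
    else:
        start, score = best_stationary_window(
            filtered.intervals,
            length=config.tt_segment_length,
            stride=config.tt_segment_stride,
        )
        segment = filtered.slice(start, start + config.tt_segment_length)
    values = segment.intervals
    if config.detrend_enabled:
        _, values = detrend_smoothness_priors(values, config.detrend)
    prof = symbolic_profile(
        values,
        config.symbolic,
        subject=series.subject,
        condition=series.condition,
        context=series.context,
    )
    row = prof.as_dict()
    row.update(
        start_index=start,
        length=len(segment),
        stationarity_score=score,
        n_artifacts=report.n_flagged,
    )
    return row


def _route_and_test(table: pd.DataFrame, dv: str) -> dict:
    """Normality-gated omnibus test across conditions for one variable."""
    cells = [g[dv].to_numpy() for _, g in table.groupby("condition")]
    try:
        route = shapiro_gate(cells)
    except ValueError:
        route = "degenerate"
    out = {"variable": dv, "route": route}
    if route == "non_normal":
        h, p = kruskal_fallback(cells)
        out.update(statistic=h, p=p, test="kruskal-wallis")
    return out


@dataclass
class PipelineReport:
    """Everything one run produces, ready for emission."""

    config: RunConfig
    cohort: pd.DataFrame
    profiles: pd.DataFrame
    anova_tables: dict  # name -> DataFrame
    anova_summaries: dict  # name -> str
    bayes_tables: dict  # name -> DataFrame
    posthoc_tables: dict  # name -> DataFrame
    deltas: dict  # variable -> {condition: delta}
    routing: list  # normality-gate decisions


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Simulate a cohort and run the complete analysis."""
    spec = config.cohort_spec()
    out = Path(config.out_dir) if config.out_dir else None
    rr_dir = out / "rr" if out else None
    cohort, recordings = generate_study(spec, out_dir=rr_dir)
    logger.info("pipeline[simulate]: %d recordings", len(recordings))

    rows = [process_recording(series, config) for series in recordings.values()]
    profiles = pd.DataFrame(rows)
    logger.info("pipeline[symbolize]: %d profiles", len(profiles))

    supine = profiles[profiles["context"].isin(SUPINE_CONTEXTS)]
    tt = profiles[profiles["context"].isin(TT_CONTEXTS)]

    anova_tables, anova_summaries, bayes_tables, posthoc_tables = {}, {}, {}, {}
    routing = []

    def analyse_block(block: pd.DataFrame, tag: str) -> None:
        if block.empty or block["context"].nunique() == 0:
            return
        for dv in SYMBOLIC_VARS:
            name = f"{tag}_{dv}"
            routing.append(_route_and_test(block, dv))
            if block["context"].nunique() >= 2:
                res = RepeatedMeasuresAnova(
                    block, dv, within=("condition", "context"), subject="subject"
                ).fit()
            else:
                res = RepeatedMeasuresAnova(
                    block, dv, within="condition", subject="subject"
                ).fit()
            anova_tables[name] = res.anova_table()
            anova_summaries[name] = res.summary()
            posthoc_tables[name] = res.posthoc_tukey()
            # report-table analogue: per-subject condition means
            per_subj = (
                block.groupby(["subject", "condition"], sort=False)[dv]
                .mean()
                .reset_index()
            )
            bres = PairwiseBayes(
                per_subj, dv, within="condition", subject="subject",
                config=config.bayes, order=spec.conditions,
            ).fit()
            bayes_tables[name] = bres.summary()

    analyse_block(supine, "supine")
    analyse_block(tt, "tt")

    # time-trial outcome variables
    cohort = cohort.copy()
    cohort["power_avg_w"] = cohort[
        ["power_beginning_w", "power_midway_w", "power_final_w"]
    ].mean(axis=1)
    delta_map = {}
    for dv in ("tt_time_s", "power_avg_w"):
        routing.append(_route_and_test(cohort, dv))
        res = RepeatedMeasuresAnova(
            cohort, dv, within="condition", subject="subject_id"
        ).fit()
        anova_tables[dv] = res.anova_table()
        anova_summaries[dv] = res.summary()
        posthoc_tables[dv] = res.posthoc_tukey()
        bres = PairwiseBayes(
            cohort, dv, within="condition", subject="subject_id",
            config=config.bayes, order=spec.conditions,
        ).fit()
        bayes_tables[dv] = bres.summary()
        delta_map[dv] = deltas(cohort, dv)

    report = PipelineReport(
        config=config,
        cohort=cohort,
        profiles=profiles,
        anova_tables=anova_tables,
        anova_summaries=anova_summaries,
        bayes_tables=bayes_tables,
        posthoc_tables=posthoc_tables,
        deltas=delta_map,
        routing=routing,
    )
    if out is not None:
        emit_tables(report, out)
    return report


def emit_tables(report: PipelineReport, out_dir: str | Path) -> list[Path]:
    """Write the report bundle as CSV/JSON files; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    _write_csv(report.cohort, "cohort_outcomes.csv")
    _write_csv(report.profiles, "symbolic_profiles.csv")
    for name, df in sorted(report.anova_tables.items()):
        _write_csv(df, f"anova_{name}.csv")
    for name, df in sorted(report.bayes_tables.items()):
        _write_csv(df, f"bayes_{name}.csv")
    for name, df in sorted(report.posthoc_tables.items()):
        if len(df):
            _write_csv(df, f"posthoc_{name}.csv")
    p = out / "deltas.json"
    p.write_text(json.dumps(report.deltas, indent=2, sort_keys=True))
    written.append(p)
    p = out / "routing.json"
    p.write_text(json.dumps(report.routing, indent=2))
    written.append(p)
    save_config(report.config, out / "run_config.yaml")
    written.append(out / "run_config.yaml")
    return written
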