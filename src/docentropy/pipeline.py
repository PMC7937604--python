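"""End-to-end orchestration: simulate (or load) -> preprocess -> entropy ->
group statistics -> prognosis, with a manifest and a single text report.

All randomness flows from the one cohort seed; execution is sequential and
single-CPU, which is the determinism contract: the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .channels import DEFAULT_PAIRS
from .entropy import ApEnParams, apen_matrix, capen_pairs
from .io import EEGRecording, determine_affected_side, notch_filter, \
    remap_montage, select_epoch, write_recording
from .prognosis import fit_all_models, outcome_summary
from .simulate import CohortConfig, SyntheticCohort, generate_cohort
from .stats import condition_difference, describe_cohort, hotelling_blocks, \
    render_comparison_table, ttest_by_measure

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str = ""
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


@dataclass
class AnalysisResult:
    """All tables produced by one full run."""

    manifest: RunManifest
    meta: pd.DataFrame
    cohort_table: pd.DataFrame
    apen_table: pd.DataFrame
    capen_table: pd.DataFrame
    baseline_apen: pd.DataFrame
    baseline_capen: pd.DataFrame
    diff_apen: pd.DataFrame
    diff_capen: pd.DataFrame
    ttest_baseline_apen: pd.DataFrame
    ttest_baseline_capen: pd.DataFrame
    ttest_diff_apen: pd.DataFrame
    ttest_diff_capen: pd.DataFrame
    hotelling: pd.DataFrame
    outcome: pd.DataFrame | None
    regressions: dict | None
    report: str


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_recordings(cohort: SyntheticCohort,
                          notch: float | None = 50.0,
                          amplitude_limit: float = 100.0,
                          n_points: int | None = None,
                          apen_params: ApEnParams | None = None,
                          ) -> list[EEGRecording]:
    """Notch, epoch-select, determine affected side, and remap per subject.

    The affected side comes from the subject's imaging field; when that is
    'unknown' the ApEn tie-break on the eyes-closed epoch decides.
    """
    meta = cohort.meta.set_index("subject_id")
    by_subject: dict[str, dict[str, EEGRecording]] = {}
    for rec in cohort.recordings:
        by_subject.setdefault(rec.subject_id, {})[rec.condition] = rec
    out = []
    for sid, conds in sorted(by_subject.items()):
        npts = n_points or min(r.n_samples for r in conds.values())
        processed = {}
        for cond in ("eyes_closed", "pain"):
            rec = conds[cond]
            if notch:
                rec = notch_filter(rec, notch)
            processed[cond] = select_epoch(rec, npts, amplitude_limit)
        montage = determine_affected_side(
            meta.loc[sid, "affected_side"], processed["eyes_closed"],
            apen_params)
        for cond in ("eyes_closed", "pain"):
            out.append(remap_montage(processed[cond], montage))
    return out


def run_full_analysis(config: CohortConfig, out_dir: str | Path | None = None,
                      signals: bool = True,
                      apen_params: ApEnParams | None = None,
                      notch: float | None = 50.0,
                      amplitude_limit: float = 100.0,
                      predictor_kind: str = "difference") -> AnalysisResult:
    """Run every stage on a simulated cohort and assemble the report.

    ``signals=False`` skips signal synthesis and measures nothing: the
    generator's proxy entropy tables feed the statistics directly (fast
    path for large-n statistical validation).
    """
    manifest = RunManifest(
        config=dataclasses.asdict(config), config_hash=_config_hash(config),
        seed=config.seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage = "simulate"
    try:
        cohort = generate_cohort(config, signals=signals)
        meta = cohort.meta
        manifest.stages["simulate"] = {"n_subjects": len(meta),
                                       "signals": signals}

        if signals:
            stage = "preprocess"
            recs = preprocess_recordings(cohort, notch, amplitude_limit,
                                         apen_params=apen_params)
            stage = "entropy"
            p = apen_params or ApEnParams(n_points=recs[0].n_samples)
            apen_table = apen_matrix(recs, p)
            capen_table = capen_pairs(recs, DEFAULT_PAIRS, p)
        else:
            apen_table = cohort.apen_proxy
            capen_table = cohort.capen_proxy
        manifest.stages["entropy"] = {
            "apen_values": len(apen_table), "capen_values": len(capen_table)}

        stage = "stats"
        groups = meta.set_index("subject_id")["group"]
        cohort_table = describe_cohort(meta)
        base_a = apen_table[apen_table.condition == "eyes_closed"][
            ["subject_id", "channel", "apen"]]
        base_c = capen_table[capen_table.condition == "eyes_closed"][
            ["subject_id", "pair", "capen"]]
        diff_a = condition_difference(apen_table)
        diff_c = condition_difference(capen_table)
        tt_base_a = ttest_by_measure(base_a, groups)
        tt_base_c = ttest_by_measure(base_c, groups)
        tt_diff_a = ttest_by_measure(diff_a, groups)
        tt_diff_c = ttest_by_measure(diff_c, groups)
        hot_a = hotelling_blocks(diff_a, groups)
        hot_c = hotelling_blocks(diff_c, groups)
        nonempty = [h for h in (hot_a, hot_c) if not h.empty]
        hotelling = (pd.concat(nonempty, ignore_index=True)
                     if nonempty else hot_a)
        manifest.stages["stats"] = {"hotelling_blocks": len(hotelling)}

        stage = "prognosis"
        outcome = None
        regressions = None
        max_params = 15  # widest design: intercept + 6 covariates + 8 channels
        if not ("mgos_12m" in meta.columns
                and meta["mgos_12m"].astype(bool).all()):
            logger.warning("outcome data missing; prognosis stage skipped")
        elif len(meta) <= max_params:
            logger.warning("cohort of %d subjects cannot support the "
                           "%d-parameter designs; prognosis stage skipped",
                           len(meta), max_params)
            outcome = outcome_summary(meta)
        else:
            outcome = outcome_summary(meta)
            regressions = fit_all_models(meta, apen_table, capen_table,
                                         predictor_kind=predictor_kind)
            manifest.stages["prognosis"] = {
                m: {"residual_df": r.residual_df, "r2": round(r.r_squared, 4)}
                for m, r in regressions.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report = _render_report(cohort_table, tt_base_a, tt_base_c, tt_diff_a,
                            tt_diff_c, hotelling, outcome, regressions)
    result = AnalysisResult(
        manifest=manifest, meta=meta, cohort_table=cohort_table,
        apen_table=apen_table, capen_table=capen_table,
        baseline_apen=base_a, baseline_capen=base_c,
        diff_apen=diff_a, diff_capen=diff_c,
        ttest_baseline_apen=tt_base_a, ttest_baseline_capen=tt_base_c,
        ttest_diff_apen=tt_diff_a, ttest_diff_capen=tt_diff_c,
        hotelling=hotelling, outcome=outcome, regressions=regressions,
        report=report)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _render_report(cohort_table, tt_base_a, tt_base_c, tt_diff_a, tt_diff_c,
                   hotelling, outcome, regressions) -> str:
    parts = ["# Non-linear dynamic EEG analysis report", ""]
    parts += ["## Cohort", cohort_table.to_string(index=False), ""]
    parts += ["## Eyes-closed ApEn by group",
              render_comparison_table(tt_base_a), ""]
    parts += ["## Eyes-closed C-ApEn by group",
              render_comparison_table(tt_base_c), ""]
    parts += ["## Pain-minus-rest ApEn differences",
              render_comparison_table(tt_diff_a), ""]
    parts += ["## Pain-minus-rest C-ApEn differences",
              render_comparison_table(tt_diff_c), ""]
    parts += ["## Multivariate (Hotelling) block tests on differences",
              hotelling.to_string(index=False), ""]
    if outcome is not None:
        parts += ["## 12-month outcome", outcome.to_string(), ""]
    if regressions is not None:
        for name, reg in regressions.items():
            parts += [
                f"## Regression: {name}",
                reg.coefficients.to_string(),
                f"Residual SE {reg.residual_se:.4f} on {reg.residual_df} df; "
                f"R^2 {reg.r_squared:.4f} (adj {reg.adj_r_squared:.4f}); "
                f"F {reg.f_statistic:.3f} on {reg.f_df[0]} and {reg.f_df[1]} "
                f"df (p {reg.f_pvalue:.3g})", ""]
    return "\n".join(parts)


def _write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.meta.to_csv(out_dir / "metadata.csv", index=False)
    result.apen_table.to_csv(out_dir / "apen.csv", index=False)
    result.capen_table.to_csv(out_dir / "capen.csv", index=False)
    result.ttest_baseline_apen.to_csv(out_dir / "ttest_baseline_apen.csv", index=False)
    result.ttest_baseline_capen.to_csv(out_dir / "ttest_baseline_capen.csv", index=False)
    result.ttest_diff_apen.to_csv(out_dir / "ttest_diff_apen.csv", index=False)
    result.ttest_diff_capen.to_csv(out_dir / "ttest_diff_capen.csv", index=False)
    result.hotelling.to_csv(out_dir / "hotelling.csv", index=False)
    if result.outcome is not None:
        result.outcome.to_csv(out_dir / "outcome_summary.csv")
    if result.regressions is not None:
        for name, reg in result.regressions.items():
            reg.coefficients.to_csv(out_dir / f"regression_{name}.csv")
    (out_dir / "report.md").write_text(result.report)
    (out_dir / "manifest.json").write_text(result.manifest.to_json())


def export_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write cohort metadata as CSV and recordings as CSV+sidecar files,
    with a manifest mapping subject x condition to file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.meta.to_csv(out_dir / "metadata.csv", index=False)
    manifest = {}
    for rec in cohort.recordings:
        name = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording(rec, out_dir / name)
        manifest[f"{rec.subject_id}/{rec.condition}"] = name
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
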