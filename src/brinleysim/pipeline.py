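"""End-to-end orchestration: simulate -> aggregate -> fit -> plot -> report.

``run_case`` executes one simulated realization of one case and writes all
artifacts (trial CSV, study-means CSV, model-comparison and fixed-effect
TSVs, both plots).  ``run_all`` repeats this for Cases A-H with per-case
seeds derived deterministically from a base seed (seed*1000 + case index)
and writes a combined summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .aggregate import study_condition_means, write_study_means
from .brinley import BrinleyFit, ModelComparison, fit_brinley_models
from .cases import CASE_IDS, CaseSpec, apply_overrides, build_case_library
from .errors import BrinleySimError
from .plots import PlotSpec, modified_brinley_plot, standard_brinley_plot
from .simulate import simulate_case, write_trial_table
from .trial_mlm import TrialMLMFit, fit_trial_mlm

__all__ = ["CaseReport", "run_case", "run_all", "case_seed"]

logger = logging.getLogger(__name__)

_TRIAL_PREDICTORS = ("intercept", "age", "trial_type", "interaction")


def case_seed(seed_base: int, case_id: str) -> int:
    """Deterministic per-case seed for run_all (documented convention)."""
    return seed_base * 1000 + CASE_IDS.index(case_id)


@dataclass
class CaseReport:
    """All outputs of one pipeline run on one case realization."""

    case_id: str
    seed: int
    spec: CaseSpec
    paths: dict[str, Path]
    brinley_restricted: BrinleyFit
    brinley_full: BrinleyFit
    comparison: ModelComparison
    trial_fit: TrialMLMFit

    @property
    def decision_summary(self) -> dict[str, object]:
        one_line = self.comparison.preferred_model == "restricted"
        return {
            "case_id": self.case_id,
            "brinley_verdict": (
                "one line sufficient" if one_line else "two lines necessary"
            ),
            "delta_chi2": self.comparison.delta_chi2,
            "delta_chi2_p": self.comparison.p_value,
            "trial_mlm_interaction_significant": self.trial_fit["interaction"].p < 0.05,
            "trial_mlm_interaction_p": self.trial_fit["interaction"].p,
        }


def _comparison_frame(report: CaseReport) -> pd.DataFrame:
    rows = []
    for label, fit in (
        ("Restricted", report.brinley_restricted),
        ("Full", report.brinley_full),
    ):
        rows.append(
            {
                "case": report.case_id,
                "model": label,
                "df": fit.n_parameters,
                "r2_marginal": round(fit.r2_marginal, 4),
                "aic": round(fit.aic, 2),
                "bic": round(fit.bic, 2),
                "deviance": round(fit.deviance, 2),
                "delta_chi2": (
                    round(report.comparison.delta_chi2, 3) if label == "Full" else ""
                ),
                "p": round(report.comparison.p_value, 4) if label == "Full" else "",
            }
        )
    return pd.DataFrame(rows)


def _trial_frame(report: CaseReport) -> pd.DataFrame:
    rows = []
    for name in _TRIAL_PREDICTORS:
        eff = report.trial_fit[name]
        rows.append(
            {
                "case": report.case_id,
                "predictor": name,
                "estimate": round(eff.estimate, 3),
                "se": round(eff.se, 3),
                "t": round(eff.t, 3),
                "p": round(eff.p, 5),
            }
        )
    return pd.DataFrame(rows)


def _beta_frame(report: CaseReport) -> pd.DataFrame:
    rows = []
    for label, fit in (
        ("Restricted", report.brinley_restricted),
        ("Full", report.brinley_full),
    ):
        row = {"case": report.case_id, "model": label}
        for b in ("beta0", "beta1", "beta2", "beta3"):
            row[b] = round(fit.beta[b], 4) if b in fit.beta else ""
            row[f"{b}_se"] = round(fit.se[b], 4) if b in fit.se else ""
        rows.append(row)
    return pd.DataFrame(rows)


def run_case(
    case_id: str,
    seed: int,
    out_dir: str | Path,
    overrides: Mapping | None = None,
) -> CaseReport:
    """Run the full pipeline on one simulated realization of one case."""
    library = build_case_library()
    if case_id not in library:
        raise BrinleySimError(f"unknown case_id {case_id!r}; expected one of {CASE_IDS}")
    spec = library[case_id]
    if overrides:
        spec = apply_overrides(spec, overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("case %s seed %d: spec=%s", case_id, seed, spec)

    stage = "simulate"
    try:
        table = simulate_case(spec, seed)
        paths = {"trial_csv": out / f"case_{case_id}_trials.csv"}
        write_trial_table(table, paths["trial_csv"])

        stage = "aggregate"
        means = study_condition_means(table)
        paths["means_csv"] = out / f"case_{case_id}_study_means.csv"
        write_study_means(means, paths["means_csv"])

        stage = "brinley_fit"
        restricted, full, comparison = fit_brinley_models(means)

        stage = "trial_mlm_fit"
        trial_fit = fit_trial_mlm(table)

        stage = "plot"
        paths["standard_plot"] = standard_brinley_plot(
            means,
            PlotSpec(out / f"case_{case_id}_standard.svg",
                     title=f"Case {case_id}: standard Brinley plot"),
        )
        paths["modified_plot"] = modified_brinley_plot(
            means,
            PlotSpec(out / f"case_{case_id}_modified.svg",
                     title=f"Case {case_id}: modified Brinley plot"),
        )

        stage = "report"
        report = CaseReport(
            case_id=case_id,
            seed=seed,
            spec=spec,
            paths=paths,
            brinley_restricted=restricted,
            brinley_full=full,
            comparison=comparison,
            trial_fit=trial_fit,
        )
        paths["model_comparison_tsv"] = out / f"case_{case_id}_model_comparison.tsv"
        _comparison_frame(report).to_csv(paths["model_comparison_tsv"], sep="\t", index=False)
        paths["trial_mlm_tsv"] = out / f"case_{case_id}_trial_mlm.tsv"
        _trial_frame(report).to_csv(paths["trial_mlm_tsv"], sep="\t", index=False)
        paths["fixed_effects_tsv"] = out / f"case_{case_id}_brinley_betas.tsv"
        _beta_frame(report).to_csv(paths["fixed_effects_tsv"], sep="\t", index=False)
    except Exception as exc:
        raise BrinleySimError(f"case {case_id} failed at stage {stage!r}: {exc}") from exc
    logger.info("case %s done: %s", case_id, report.decision_summary)
    return report


def run_all(
    seed_base: int,
    out_dir: str | Path,
    overrides: Mapping | None = None,
    case_ids: tuple[str, ...] = CASE_IDS,
) -> tuple[list[CaseReport], pd.DataFrame]:
    """Run every case; per-case failures are recorded, remaining cases run.

    Returns the successful reports plus a combined summary frame (also
    written to ``summary.tsv`` in ``out_dir``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: list[CaseReport] = []
    summary_rows = []
    for case_id in case_ids:
        seed = case_seed(seed_base, case_id)
        try:
            report = run_case(case_id, seed, out / f"case_{case_id}", overrides)
        except BrinleySimError as exc:
            logger.error("case %s failed: %s", case_id, exc)
            summary_rows.append({"case_id": case_id, "seed": seed, "error": str(exc)})
            continue
        reports.append(report)
        row = dict(report.decision_summary)
        row.update(
            seed=seed,
            beta2_restricted=round(report.brinley_restricted.beta["beta2"], 4),
            r2_restricted=round(report.brinley_restricted.r2_marginal, 4),
            interaction_estimate=round(report.trial_fit["interaction"].estimate, 3),
            error="",
        )
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return reports, summary
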