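"""Pipeline orchestration and report tables.

``run_pipeline`` executes the three analysis stages in order — posterior
inference for the six tree probabilities, the first-year cost comparison
with break-even search, and the ten-year discounted projection — and returns
:class:`ReportTable` objects whose rounding policy is applied only at
serialization (CSV, TSV or markdown).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .economics import (
    ArmProbabilities,
    NoBreakEvenError,
    break_even_cohort,
    calibrate_variable_saving,
    cohort_cost_table,
    genotyping_unit_cost,
    per_patient_difference,
    variable_saving_from_tree,
)
from .inference import (
    derive_subseed,
    mcmc_diagnostics,
    mh_sample,
    summarize_samples,
)
from .projection import (
    AnnualRisks,
    aggregate_savings,
    project_cohort,
    run_markov,
    ten_year_savings,
)

__all__ = ["ReportTable", "run_pipeline", "write_table", "PIPELINE_STAGES"]

logger = logging.getLogger("otocost")

PIPELINE_STAGES = ("posteriors", "first_year", "ten_year")

#: Reporting precision by column name: probabilities at 2-3 d.p., currency in cents.
_DEFAULT_ROUNDING = {
    "median": 2,
    "ci_low": 2,
    "ci_high": 2,
    "acceptance_rate": 3,
    "ess": 0,
    "lag1_autocorrelation": 3,
    "genotyped_cost": 2,
    "conventional_cost": 2,
    "difference": 2,
    "alive_continuous": 2,
    "discount_factor": 4,
    "annual_saving": 2,
    "cumulative_saving": 2,
    "saving_per_patient": 2,
    "without_hl": 2,
    "with_hl": 2,
    "dead": 2,
    "alive": 2,
    "value": 4,
}


@dataclass(frozen=True)
class ReportTable:
    """A named rectangular result with a per-column rounding policy."""

    name: str
    data: pd.DataFrame
    rounding: Mapping[str, int] = field(default_factory=dict)

    def rounded(self) -> pd.DataFrame:
        out = self.data.copy()
        policy = {**_DEFAULT_ROUNDING, **self.rounding}
        for col, nd in policy.items():
            if col in out.columns and pd.api.types.is_numeric_dtype(out[col]):
                out[col] = out[col].round(nd)
                if nd == 0:
                    out[col] = out[col].astype("Int64")
        return out


def _markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def write_table(table: ReportTable, path: str | Path, format: str = "csv") -> None:
    """Serialize a table with its rounding policy; header always present."""
    df = table.rounded()
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif format == "markdown":
        path.write_text(_markdown(df), encoding="utf-8")
    else:
        raise ValueError(f"unknown table format: {format!r}")


def _posterior_stage(config: ScenarioConfig) -> tuple[ReportTable, ReportTable, dict[str, float]]:
    rows = []
    diag_rows = []
    medians: dict[str, float] = {}
    for record in config.evidence:
        cfg = replace(config.mcmc, seed=derive_subseed(config.seed, record.label))
        samples = mh_sample(record, cfg, noninformative=config.noninformative)
        summary = summarize_samples(samples)
        diag = mcmc_diagnostics(samples)
        medians[record.label] = summary.median
        rows.append(
            (record.label, summary.median, summary.ci_low, summary.ci_high)
        )
        lag1 = float(diag.autocorrelation[1]) if diag.autocorrelation.size > 1 else np.nan
        diag_rows.append(
            (record.label, diag.acceptance_rate, lag1, diag.ess, diag.degenerate)
        )
    posteriors = ReportTable(
        "posteriors",
        pd.DataFrame(rows, columns=["label", "median", "ci_low", "ci_high"]),
    )
    diagnostics = ReportTable(
        "diagnostics",
        pd.DataFrame(
            diag_rows,
            columns=["label", "acceptance_rate", "lag1_autocorrelation", "ess", "degenerate"],
        ),
    )
    return posteriors, diagnostics, medians


def _probabilities_from_medians(
    config: ScenarioConfig, medians: Mapping[str, float]
) -> ArmProbabilities:
    # The low-risk ototoxicity estimate defaults to the non-informative-prior
    # variant when both P5 rows are present.
    p5 = medians.get("P5_noninformative", medians.get("P5"))
    if p5 is None:
        raise KeyError("no P5 evidence record in scenario")
    return ArmProbabilities(
        p1_high_risk=medians["P1"],
        p2_dropout_cddp=medians["P2"],
        p3_dropout_docetaxel=medians["P3"],
        p4_oto_conventional=medians["P4"],
        p5_oto_lowrisk_cddp=p5,
        p6_oto_docetaxel=medians["P6"],
        t1_death_cumulative=config.markov.death_cumulative,
        t1_horizon_years=config.markov.death_horizon_years,
        t2_hearingloss_cumulative=config.markov.hearingloss_cumulative,
        t2_horizon_years=config.markov.hearingloss_horizon_years,
    )


def _first_year_stage(
    config: ScenarioConfig, probs: ArmProbabilities
) -> tuple[ReportTable, ReportTable]:
    table = cohort_cost_table(
        probs, config.costs, config.batch_size, config.cohort_grid, config.batch_model
    )
    amort = config.costs.annual_amortization_usd
    if config.reported_difference_at_ref is not None:
        ref_n, ref_diff = config.reported_difference_at_ref
        k = calibrate_variable_saving(ref_diff, amort, ref_n)
        k_source = "calibrated"
    else:
        k = float(
            variable_saving_from_tree(
                probs, config.costs, config.batch_size, config.batch_model
            )
        )
        k_source = "decision_tree"
    step = min(np.diff(config.cohort_grid).min(), config.cohort_grid[0]) if len(config.cohort_grid) > 1 else 25
    try:
        n_star: float | None = break_even_cohort(k, amort, step=int(step))
    except NoBreakEvenError:
        n_star = None
    unit = genotyping_unit_cost(
        config.batch_size,
        config.batch_model if config.batch_model is not None else config.costs.genotyping_unit_usd_by_batch,
    )
    summary = pd.DataFrame(
        {
            "quantity": [
                "variable_saving_k",
                "k_source",
                "genotyping_unit_cost",
                "annual_amortization",
                "break_even_cohort",
                "difference_at_cohort_n",
            ],
            "value": [
                round(k, 4),
                k_source,
                round(unit, 4),
                amort,
                n_star if n_star is not None else "none",
                round(float(per_patient_difference(k, amort, config.cohort_n)), 4),
            ],
        }
    )
    return (
        ReportTable("first_year", table),
        ReportTable("break_even", summary, rounding={"value": 4}),
    )


def _ten_year_stage(
    config: ScenarioConfig, probs: ArmProbabilities
) -> ReportTable:
    mk = config.markov
    trajectory = project_cohort(mk.n0, mk.death_annual, mk.horizon_years)
    states = run_markov(
        mk.n0,
        AnnualRisks(mk.death_annual, mk.hearingloss_annual),
        mk.horizon_years,
    )
    if config.reported_annual_savings is not None:
        savings = aggregate_savings(trajectory, config.reported_annual_savings)
    else:
        p1 = probs.p1_high_risk
        delta = (1 - probs.p2_dropout_cddp) * probs.p4_oto_conventional - (
            (1 - p1) * (1 - probs.p2_dropout_cddp) * probs.p5_oto_lowrisk_cddp
            + p1 * (1 - probs.p3_dropout_docetaxel) * probs.p6_oto_docetaxel
        )
        savings = ten_year_savings(
            trajectory, config.schedule, float(delta), config.costs.discount_rate
        )
    merged = savings.merge(
        states[["year", "without_hl", "with_hl", "dead"]], on="year"
    )
    return ReportTable("ten_year", merged)


def run_pipeline(
    config: ScenarioConfig, stages: Iterable[str] = PIPELINE_STAGES
) -> dict[str, ReportTable]:
    """Run the requested stages in analysis order and collect their tables.

    Stage order is fixed (posteriors -> first_year -> ten_year) because the
    economics stages consume the posterior medians.  A stage failure is
    re-raised with the stage name attached.
    """
    wanted = set(stages)
    unknown = wanted - set(PIPELINE_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]

    tables: dict[str, ReportTable] = {}
    probs: ArmProbabilities | None = None
    medians: dict[str, float] = {}
    for stage in PIPELINE_STAGES:
        needed = stage in wanted or (
            stage == "posteriors" and wanted & {"first_year", "ten_year"}
        )
        if not needed:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "posteriors":
                posteriors, diagnostics, medians = _posterior_stage(config)
                probs = _probabilities_from_medians(config, medians)
                if stage in wanted:
                    tables["posteriors"] = posteriors
                    tables["diagnostics"] = diagnostics
            elif stage == "first_year":
                assert probs is not None
                first_year, break_even = _first_year_stage(config, probs)
                tables["first_year"] = first_year
                tables["break_even"] = break_even
            elif stage == "ten_year":
                assert probs is not None
                tables["ten_year"] = _ten_year_stage(config, probs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info(
            "stage=%s config=%s elapsed=%.3fs", stage, cfg_hash, time.perf_counter() - t0
        )
    return tables
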