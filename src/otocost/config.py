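"""Scenario configuration: one validated object drives the whole pipeline.

A :class:`ScenarioConfig` bundles the evidence records for the six
decision-tree probabilities, the monetary inputs, the first-year scenario
settings (annual cohort size, PCR batch size, cohort grid), the Markov block
(initial cohort, horizon, cumulative risks and their annualization methods,
discount rate) and the per-year audiological cost schedule, plus a single
seed from which every chain's sub-seed is derived.

Configs round-trip through YAML; validation failures raise
:class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .economics import BatchCostModel, CostInputs
from .inference import (
    BetaPseudoCounts,
    BinomialObservation,
    EvidenceRecord,
    MCMCConfig,
)
from .projection import CostSchedule, annualize_cumulative_risk

__all__ = ["ScenarioConfig", "MarkovSettings", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """A scenario configuration failed validation."""


@dataclass(frozen=True)
class MarkovSettings:
    """Long-term projection settings.

    Cumulative risks over their stated horizons are converted to annual
    probabilities with per-risk annualization methods ("uniform" or
    "geometric").
    """

    n0: int = 250
    horizon_years: int = 10
    death_cumulative: float = 0.77
    death_horizon_years: float = 10.0
    death_annualization: str = "uniform"
    hearingloss_cumulative: float = 0.042
    hearingloss_horizon_years: float = 10.0
    hearingloss_annualization: str = "geometric"

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ConfigError("markov.n0 must be non-negative")
        if self.horizon_years < 1:
            raise ConfigError("markov.horizon_years must be >= 1")
        for name in ("death_cumulative", "hearingloss_cumulative"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"markov.{name} must lie in [0, 1)")
        for name in ("death_annualization", "hearingloss_annualization"):
            if getattr(self, name) not in ("uniform", "geometric"):
                raise ConfigError(f"markov.{name} must be 'uniform' or 'geometric'")

    @property
    def death_annual(self) -> float:
        return annualize_cumulative_risk(
            self.death_cumulative, self.death_horizon_years, self.death_annualization
        )

    @property
    def hearingloss_annual(self) -> float:
        return annualize_cumulative_risk(
            self.hearingloss_cumulative,
            self.hearingloss_horizon_years,
            self.hearingloss_annualization,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    evidence: tuple[EvidenceRecord, ...]
    costs: CostInputs = field(default_factory=CostInputs)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    markov: MarkovSettings = field(default_factory=MarkovSettings)
    schedule: CostSchedule = field(
        default_factory=lambda: CostSchedule.constant(0.0, 73.81, 10)
    )
    batch_model: BatchCostModel | None = None
    noninformative: str = "jeffreys"
    cohort_n: int = 500
    batch_size: int = 3
    cohort_grid: tuple[int, ...] = tuple(range(25, 501, 25))
    seed: int = 0
    # Literature-reported quantities usable as calibration inputs / aggregate-mode
    # savings data; None when a scenario carries no external reporting.
    reported_difference_at_ref: tuple[int, float] | None = None
    reported_annual_savings: tuple[float, ...] | None = None
    reported_component_savings: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        labels = [r.label for r in self.evidence]
        if len(set(labels)) != len(labels):
            raise ConfigError("evidence labels must be unique within a scenario")
        if self.noninformative not in ("jeffreys", "uniform"):
            raise ConfigError("noninformative must be 'jeffreys' or 'uniform'")
        if self.cohort_n < 1:
            raise ConfigError("scenario.cohort_n must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("scenario.batch_size must be >= 1")
        if not self.cohort_grid:
            raise ConfigError("scenario.cohort_grid must be non-empty")
        if self.schedule.years != self.markov.horizon_years:
            raise ConfigError(
                "schedule length must equal markov.horizon_years "
                f"({self.schedule.years} != {self.markov.horizon_years})"
            )
        if self.reported_annual_savings is not None and len(
            self.reported_annual_savings
        ) != self.markov.horizon_years:
            raise ConfigError(
                "reported_annual_savings must have one entry per projection year"
            )

    def record(self, label: str) -> EvidenceRecord:
        for r in self.evidence:
            if r.label == label:
                return r
        raise KeyError(f"no evidence record labelled {label!r}")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed, mcmc=replace(self.mcmc, seed=seed))

    # ------------------------------------------------------------------ YAML

    def to_dict(self) -> dict[str, Any]:
        def rec(r: EvidenceRecord) -> dict[str, Any]:
            d: dict[str, Any] = {
                "label": r.label,
                "events": r.obs.events,
                "non_events": r.obs.non_events,
            }
            if r.prior is None:
                d["prior"] = "noninformative"
            else:
                d["prior"] = {"events": r.prior.alpha, "non_events": r.prior.beta}
            return d

        d: dict[str, Any] = {
            "evidence": [rec(r) for r in self.evidence],
            "noninformative": self.noninformative,
            "costs": {
                "cddp_course_usd": self.costs.cddp_course_usd,
                "docetaxel_course_usd": self.costs.docetaxel_course_usd,
                "genotyping_unit_usd_by_batch": {
                    int(k): float(v)
                    for k, v in self.costs.genotyping_unit_usd_by_batch.items()
                },
                "equipment_usd": self.costs.equipment_usd,
                "amortization_rate": self.costs.amortization_rate,
                "annual_amortization_usd": self.costs.annual_amortization_usd,
                "hearing_annual_usd": self.costs.hearing_annual_usd,
                "first_year_oto_usd": self.costs.first_year_oto_usd,
                "discount_rate": self.costs.discount_rate,
            },
            "mcmc": {
                "iterations": self.mcmc.iterations,
                "burn_in": self.mcmc.burn_in,
                "proposal_sd": self.mcmc.proposal_sd,
                "tune": self.mcmc.tune,
            },
            "markov": {
                "n0": self.markov.n0,
                "horizon_years": self.markov.horizon_years,
                "death_cumulative": self.markov.death_cumulative,
                "death_horizon_years": self.markov.death_horizon_years,
                "death_annualization": self.markov.death_annualization,
                "hearingloss_cumulative": self.markov.hearingloss_cumulative,
                "hearingloss_horizon_years": self.markov.hearingloss_horizon_years,
                "hearingloss_annualization": self.markov.hearingloss_annualization,
            },
            "schedule": {
                "device": list(self.schedule.device),
                "support": list(self.schedule.support),
            },
            "scenario": {
                "cohort_n": self.cohort_n,
                "batch_size": self.batch_size,
                "cohort_grid": list(self.cohort_grid),
                "seed": self.seed,
            },
        }
        if self.batch_model is not None:
            d["batch_model"] = {
                "reagent_usd_per_test": self.batch_model.reagent_usd_per_test,
                "control_tests_per_batch": self.batch_model.control_tests_per_batch,
                "loss_fraction": self.batch_model.loss_fraction,
                "labor_usd_per_batch": self.batch_model.labor_usd_per_batch,
            }
        if self.reported_difference_at_ref is not None:
            n, diff = self.reported_difference_at_ref
            d["reported"] = d.get("reported", {})
            d["reported"]["difference_at_ref"] = {"cohort_n": n, "difference_usd": diff}
        if self.reported_annual_savings is not None:
            d.setdefault("reported", {})["annual_savings"] = list(
                self.reported_annual_savings
            )
        if self.reported_component_savings is not None:
            dev, sup = self.reported_component_savings
            d.setdefault("reported", {})["component_savings"] = {
                "device": dev,
                "support": sup,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        def need(block: Mapping[str, Any], key: str, where: str) -> Any:
            if key not in block or block[key] is None:
                raise ConfigError(f"missing required field {where}.{key}" if where else
                                  f"missing required field {key}")
            return block[key]

        try:
            records = []
            for r in need(d, "evidence", ""):
                prior_raw = need(r, "prior", "evidence[]")
                if prior_raw == "noninformative":
                    prior = None
                else:
                    prior = BetaPseudoCounts(
                        float(need(prior_raw, "events", "evidence[].prior")),
                        float(need(prior_raw, "non_events", "evidence[].prior")),
                    )
                records.append(
                    EvidenceRecord(
                        label=str(need(r, "label", "evidence[]")),
                        obs=BinomialObservation(
                            int(need(r, "events", "evidence[]")),
                            int(need(r, "non_events", "evidence[]")),
                        ),
                        prior=prior,
                    )
                )

            c = need(d, "costs", "")
            costs = CostInputs(
                cddp_course_usd=float(need(c, "cddp_course_usd", "costs")),
                docetaxel_course_usd=float(need(c, "docetaxel_course_usd", "costs")),
                genotyping_unit_usd_by_batch={
                    int(k): float(v)
                    for k, v in need(c, "genotyping_unit_usd_by_batch", "costs").items()
                },
                equipment_usd=float(need(c, "equipment_usd", "costs")),
                amortization_rate=float(need(c, "amortization_rate", "costs")),
                annual_amortization_usd=float(
                    need(c, "annual_amortization_usd", "costs")
                ),
                hearing_annual_usd=float(need(c, "hearing_annual_usd", "costs")),
                first_year_oto_usd=(
                    None
                    if c.get("first_year_oto_usd") is None
                    else float(c["first_year_oto_usd"])
                ),
                discount_rate=float(need(c, "discount_rate", "costs")),
            )

            m = d.get("mcmc", {})
            sc = d.get("scenario", {})
            seed = int(sc.get("seed", 0))
            mcmc = MCMCConfig(
                iterations=int(m.get("iterations", 12_500)),
                burn_in=int(m.get("burn_in", 2_500)),
                proposal_sd=float(m.get("proposal_sd", 0.05)),
                seed=seed,
                tune=bool(m.get("tune", True)),
            )

            mk = d.get("markov", {})
            markov = MarkovSettings(
                n0=int(mk.get("n0", 250)),
                horizon_years=int(mk.get("horizon_years", 10)),
                death_cumulative=float(mk.get("death_cumulative", 0.77)),
                death_horizon_years=float(mk.get("death_horizon_years", 10.0)),
                death_annualization=str(mk.get("death_annualization", "uniform")),
                hearingloss_cumulative=float(mk.get("hearingloss_cumulative", 0.042)),
                hearingloss_horizon_years=float(
                    mk.get("hearingloss_horizon_years", 10.0)
                ),
                hearingloss_annualization=str(
                    mk.get("hearingloss_annualization", "geometric")
                ),
            )

            sch = d.get("schedule")
            if sch is None:
                schedule = CostSchedule.constant(0.0, 73.81, markov.horizon_years)
            else:
                schedule = CostSchedule(
                    device=tuple(need(sch, "device", "schedule")),
                    support=tuple(need(sch, "support", "schedule")),
                )

            bm = d.get("batch_model")
            batch_model = (
                None
                if bm is None
                else BatchCostModel(
                    reagent_usd_per_test=float(bm["reagent_usd_per_test"]),
                    control_tests_per_batch=int(bm["control_tests_per_batch"]),
                    loss_fraction=float(bm["loss_fraction"]),
                    labor_usd_per_batch=float(bm["labor_usd_per_batch"]),
                )
            )

            rep = d.get("reported", {})
            diff_ref = rep.get("difference_at_ref")
            reported_diff = (
                None
                if diff_ref is None
                else (int(diff_ref["cohort_n"]), float(diff_ref["difference_usd"]))
            )
            annual = rep.get("annual_savings")
            comp = rep.get("component_savings")

            return cls(
                evidence=tuple(records),
                costs=costs,
                mcmc=mcmc,
                markov=markov,
                schedule=schedule,
                batch_model=batch_model,
                noninformative=str(d.get("noninformative", "jeffreys")),
                cohort_n=int(sc.get("cohort_n", 500)),
                batch_size=int(sc.get("batch_size", 3)),
                cohort_grid=tuple(
                    int(x) for x in sc.get("cohort_grid", range(25, 501, 25))
                ),
                seed=seed,
                reported_difference_at_ref=reported_diff,
                reported_annual_savings=(
                    None if annual is None else tuple(float(x) for x in annual)
                ),
                reported_component_savings=(
                    None
                    if comp is None
                    else (float(comp["device"]), float(comp["support"]))
                ),
            )
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario configuration: {exc}") from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a YAML scenario configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return ScenarioConfig.from_dict(raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
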