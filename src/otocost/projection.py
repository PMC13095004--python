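"""Ten-year Markov cohort projection with discounting.

The cohort moves through three states in annual cycles: alive without
hearing loss, alive with hearing loss, and dead (absorbing).  Mortality and
background hearing-loss risks are supplied as cumulative figures over a
stated horizon and annualized either uniformly (cumulative / horizon) or
geometrically (1 - (1 - cumulative)^(1/horizon)).  Counts are carried as
continuous (expected-value) quantities and rounded only for reporting, so
per-patient division checks stay exact.

Future savings are discounted at an annual rate r with year 1 at face value:
cost in year t is multiplied by (1 + r)^-(t - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualRisks",
    "StateCounts",
    "CostSchedule",
    "annualize_cumulative_risk",
    "project_cohort",
    "markov_step",
    "run_markov",
    "discount_factor",
    "ten_year_savings",
    "aggregate_savings",
    "savings_components",
]


@dataclass(frozen=True)
class AnnualRisks:
    """Per-cycle transition risks: death (from either alive state) and
    hearing-loss onset (from the asymptomatic state only)."""

    death_annual: float
    hearingloss_annual: float

    def __post_init__(self) -> None:
        for name in ("death_annual", "hearingloss_annual"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")


@dataclass(frozen=True)
class StateCounts:
    """Continuous occupancy of the three Markov states."""

    without_hl: float
    with_hl: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        if min(self.without_hl, self.with_hl, self.dead) < 0:
            raise RuntimeError("state counts must be non-negative")

    @property
    def alive(self) -> float:
        return self.without_hl + self.with_hl

    @property
    def total(self) -> float:
        return self.alive + self.dead


@dataclass(frozen=True)
class CostSchedule:
    """Per-year, per-affected-patient audiological cost components (USD).

    ``device`` covers hearing-aid acquisition/replacement in each year of
    follow-up; ``support`` covers audiometry and clinical appointments.  Both
    sequences must have one entry per projection year.
    """

    device: tuple[float, ...]
    support: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "device", tuple(float(x) for x in self.device))
        object.__setattr__(self, "support", tuple(float(x) for x in self.support))
        if len(self.device) != len(self.support):
            raise ValueError("device and support schedules must have equal length")
        if any(x < 0 for x in self.device + self.support):
            raise ValueError("schedule entries must be non-negative")

    @property
    def years(self) -> int:
        return len(self.device)

    def total(self, year: int) -> float:
        """Combined per-affected-patient cost in a 1-based year."""
        return self.device[year - 1] + self.support[year - 1]

    @classmethod
    def constant(cls, device: float, support: float, years: int = 10) -> "CostSchedule":
        return cls(device=(device,) * years, support=(support,) * years)


def annualize_cumulative_risk(
    cumulative_p: float,
    horizon_years: float,
    method: Literal["uniform", "geometric"] = "geometric",
) -> float:
    """Convert a cumulative risk over a horizon to an annual probability.

    ``uniform`` divides the cumulative figure by the horizon; ``geometric``
    solves 1 - (1 - p)^horizon = cumulative for the constant per-year hazard
    probability p.
    """
    if not (0.0 <= cumulative_p < 1.0):
        raise ValueError(f"cumulative_p must lie in [0, 1), got {cumulative_p}")
    if horizon_years <= 0:
        raise ValueError(f"horizon_years must be positive, got {horizon_years}")
    if method == "uniform":
        return cumulative_p / horizon_years
    if method == "geometric":
        return 1.0 - (1.0 - cumulative_p) ** (1.0 / horizon_years)
    raise ValueError(f"unknown annualization method: {method!r}")


def project_cohort(n0: int, annual_death: float, years: int) -> pd.DataFrame:
    """Survival-only cohort trajectory: n_t = n0 * (1 - annual_death)^t.

    The continuous count is carried unrounded; ``alive_rounded`` is the
    nearest-integer reporting value.  Years are 1-based.
    """
    if n0 < 0:
        raise ValueError(f"n0 must be non-negative, got {n0}")
    if not (0.0 <= annual_death < 1.0):
        raise ValueError(f"annual_death must lie in [0, 1), got {annual_death}")
    t = np.arange(1, years + 1)
    alive = n0 * (1.0 - annual_death) ** t
    return pd.DataFrame(
        {
            "year": t,
            "alive_continuous": alive,
            "alive_rounded": np.rint(alive).astype(int),
        }
    )


def markov_step(state: StateCounts, risks: AnnualRisks) -> StateCounts:
    """One annual cycle of the three-state model.

    Death removes the same fraction from both alive states; among surviving
    asymptomatic patients, a fraction acquires hearing loss.  The dead state
    is absorbing and the total is conserved exactly.
    """
    d = risks.death_annual
    h = risks.hearingloss_annual
    deaths = (state.without_hl + state.with_hl) * d
    surv_without = state.without_hl * (1.0 - d)
    new_hl = surv_without * h
    return StateCounts(
        without_hl=surv_without - new_hl,
        with_hl=state.with_hl * (1.0 - d) + new_hl,
        dead=state.dead + deaths,
    )


def run_markov(
    n0: float,
    risks: AnnualRisks,
    years: int,
    initial_with_hl: float = 0.0,
) -> pd.DataFrame:
    """Full three-state trajectory with per-year occupancy, 1-based years."""
    state = StateCounts(without_hl=n0 - initial_with_hl, with_hl=initial_with_hl)
    rows = []
    for year in range(1, years + 1):
        state = markov_step(state, risks)
        rows.append(
            (year, state.without_hl, state.with_hl, state.dead, state.alive)
        )
    return pd.DataFrame(
        rows, columns=["year", "without_hl", "with_hl", "dead", "alive"]
    )


def discount_factor(rate: float, year: int) -> float:
    """Present-value factor (1 + rate)^-(year - 1); year 1 is undiscounted."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    return (1.0 + rate) ** (-(year - 1))


def ten_year_savings(
    trajectory: pd.DataFrame,
    schedule: CostSchedule,
    incidence_delta: float,
    rate: float,
) -> pd.DataFrame:
    """Discounted annual savings from averted ototoxicity management.

    ``incidence_delta`` is the absolute reduction in moderate-to-severe
    ototoxicity incidence achieved by genotype-guided therapy; each year's
    saving is delta x alive_t (continuous) x per-affected schedule cost x
    discount factor.  The returned frame carries annual and cumulative
    columns; the grand total is their last cumulative entry.
    """
    alive = trajectory["alive_continuous"].to_numpy(dtype=float)
    years = trajectory["year"].to_numpy(dtype=int)
    if len(alive) != schedule.years:
        raise ValueError(
            f"trajectory has {len(alive)} years but schedule has {schedule.years}"
        )
    if not (0.0 <= incidence_delta <= 1.0):
        raise ValueError("incidence_delta must lie in [0, 1]")
    factors = np.array([discount_factor(rate, int(y)) for y in years])
    per_affected = np.array([schedule.total(int(y)) for y in years])
    annual = incidence_delta * alive * per_affected * factors
    out = trajectory.copy()
    out["discount_factor"] = factors
    out["annual_saving"] = annual
    out["cumulative_saving"] = np.cumsum(annual)
    out["saving_per_patient"] = np.divide(
        annual, alive, out=np.zeros_like(annual), where=alive > 0
    )
    return out


def aggregate_savings(
    trajectory: pd.DataFrame, annual_savings: Sequence[float]
) -> pd.DataFrame:
    """Aggregate mode: attach an externally supplied annual-saving column.

    Used when per-year savings come from a separate costing exercise; the
    total is their exact sum and per-patient values divide by the unrounded
    cohort.
    """
    annual = np.asarray(list(annual_savings), dtype=float)
    if len(annual) != len(trajectory):
        raise ValueError(
            f"{len(annual)} annual savings supplied for a "
            f"{len(trajectory)}-year trajectory"
        )
    alive = trajectory["alive_continuous"].to_numpy(dtype=float)
    out = trajectory.copy()
    out["annual_saving"] = annual
    out["cumulative_saving"] = np.cumsum(annual)
    out["saving_per_patient"] = np.divide(
        annual, alive, out=np.zeros_like(annual), where=alive > 0
    )
    return out


def savings_components(device_total: float, support_total: float) -> dict[str, float]:
    """Breakdown of total savings into hearing-aid and support components."""
    if device_total < 0 or support_total < 0:
        raise ValueError("savings components must be non-negative")
    total = device_total + support_total
    return {
        "device": device_total,
        "support": support_total,
        "total": total,
        "device_share": device_total / total if total else 0.0,
        "support_share": support_total / total if total else 0.0,
    }
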