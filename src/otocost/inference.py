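"""Bayesian beta-binomial estimation of decision-tree probabilities.

Each arm probability (carrier prevalence, dropout, ototoxicity risk) is
modelled as a Bernoulli success probability ``p`` with a Beta prior expressed
as pseudo-counts of prior events / non-events and a binomial likelihood for
the observed events / non-events.  The posterior is therefore conjugate,

    p | data ~ Beta(alpha + events, beta + non_events),

which this module uses as an exact oracle, while the production estimate is
drawn by a random-walk Metropolis-Hastings sampler (the estimation procedure
the analysis is built on): 12,500 iterations with a 2,500-iteration burn-in
by default, Gaussian proposals on the unit interval, and an optional
burn-in-phase step-size adaptation targeting a 20-50% acceptance rate.

Summaries are the posterior median and the equal-tailed 95% credible
interval; chain quality is reported as acceptance rate, lag-k
autocorrelation and effective sample size.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BetaPseudoCounts",
    "BinomialObservation",
    "EvidenceRecord",
    "MCMCConfig",
    "ProbabilitySamples",
    "PosteriorSummary",
    "MCMCDiagnostics",
    "UNIFORM",
    "JEFFREYS",
    "conjugate_posterior",
    "beta_quantile",
    "mh_sample",
    "summarize_samples",
    "mcmc_diagnostics",
    "derive_subseed",
]

NoninformativeKind = Literal["jeffreys", "uniform"]


@dataclass(frozen=True)
class BetaPseudoCounts:
    """Beta prior written as pseudo-counts: ``alpha`` events, ``beta`` non-events."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta pseudo-counts must be positive, got ({self.alpha}, {self.beta})"
            )

    def swapped(self) -> "BetaPseudoCounts":
        """The same prior with events/non-events exchanged.

        Published evidence tables occasionally orient a prior toward the
        complementary outcome; exposing both orientations lets the caller
        check which one is consistent with a reported credible interval.
        """
        return BetaPseudoCounts(self.beta, self.alpha)


#: Flat Beta(1, 1) prior.
UNIFORM = BetaPseudoCounts(1.0, 1.0)
#: Jeffreys Beta(1/2, 1/2) prior — the default non-informative choice.
JEFFREYS = BetaPseudoCounts(0.5, 0.5)


@dataclass(frozen=True)
class BinomialObservation:
    """Observed binomial counts: ``events`` successes, ``non_events`` failures."""

    events: int
    non_events: int

    def __post_init__(self) -> None:
        if self.events < 0 or self.non_events < 0:
            raise ValueError(
                f"counts must be non-negative, got ({self.events}, {self.non_events})"
            )

    @property
    def n(self) -> int:
        return self.events + self.non_events


@dataclass(frozen=True)
class EvidenceRecord:
    """One probability's evidence: a label, observed counts, and a prior.

    ``prior=None`` marks a non-informative prior whose concrete form
    (Jeffreys or uniform) is resolved at sampling time.
    """

    label: str
    obs: BinomialObservation
    prior: BetaPseudoCounts | None

    def resolve_prior(self, noninformative: NoninformativeKind = "jeffreys") -> BetaPseudoCounts:
        if self.prior is not None:
            return self.prior
        if noninformative == "jeffreys":
            return JEFFREYS
        if noninformative == "uniform":
            return UNIFORM
        raise ValueError(f"unknown non-informative prior kind: {noninformative!r}")


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis-Hastings run settings.

    ``iterations`` is the total chain length including ``burn_in``; the
    retained sample has ``iterations - burn_in`` draws.  ``proposal_sd`` is
    the Gaussian random-walk step; with ``tune`` on, it is adapted in batches
    during burn-in toward a 20-50% acceptance rate and then frozen.
    """

    iterations: int = 12_500
    burn_in: int = 2_500
    proposal_sd: float = 0.05
    seed: int = 0
    tune: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")


@dataclass(frozen=True)
class ProbabilitySamples:
    """Post-burn-in posterior draws of a probability, all strictly in (0, 1)."""

    values: np.ndarray
    acceptance_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ValueError("acceptance_rate must lie in [0, 1]")
        if self.values.size and not (
            np.all(self.values > 0.0) and np.all(self.values < 1.0)
        ):
            raise ValueError("all samples must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior median with equal-tailed 95% credible interval."""

    median: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("require ci_low <= median <= ci_high")


@dataclass(frozen=True)
class MCMCDiagnostics:
    acceptance_rate: float
    autocorrelation: np.ndarray  # lags 0..k
    ess: float
    n_samples: int
    degenerate: bool = False


def conjugate_posterior(
    prior: BetaPseudoCounts, obs: BinomialObservation
) -> BetaPseudoCounts:
    """Exact conjugate update: add observed counts to the prior pseudo-counts.

    Serves as the closed-form oracle the sampler is validated against.
    """
    return BetaPseudoCounts(prior.alpha + obs.events, prior.beta + obs.non_events)


def beta_quantile(params: BetaPseudoCounts, q: float) -> float:
    """q-quantile of Beta(alpha, beta) by inversion of the regularized incomplete beta."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile level must lie in (0, 1), got {q}")
    return float(stats.beta.ppf(q, params.alpha, params.beta))


def derive_subseed(seed: int, label: str) -> int:
    """Deterministic per-label sub-seed from one scenario seed.

    CRC32 of the label folded into the scenario seed; reduced mod 2^31 so the
    result is a portable small non-negative integer.
    """
    return (int(seed) * 2_654_435_761 + zlib.crc32(label.encode("utf-8"))) % (2**31)


def _log_target(p: float, a: float, b: float) -> float:
    # Unnormalized Beta(a, b) log-density; -inf outside the open unit interval.
    if p <= 0.0 or p >= 1.0:
        return -np.inf
    return (a - 1.0) * np.log(p) + (b - 1.0) * np.log1p(-p)


def mh_sample(
    record: EvidenceRecord,
    config: MCMCConfig | None = None,
    *,
    noninformative: NoninformativeKind = "jeffreys",
) -> ProbabilitySamples:
    """Random-walk Metropolis-Hastings draw from the beta-binomial posterior.

    The target is proportional to ``p^(events+alpha-1) (1-p)^(non_events+beta-1)``.
    Proposals outside (0, 1) are rejected outright (equivalently, the prior is
    zero there).  The chain starts at the posterior mean.  Deterministic for a
    fixed ``config.seed``.
    """
    if config is None:
        config = MCMCConfig()
    post = conjugate_posterior(record.resolve_prior(noninformative), record.obs)
    a, b = post.alpha, post.beta

    rng = np.random.default_rng(config.seed)
    n_keep = config.iterations - config.burn_in
    kept = np.empty(n_keep, dtype=float)

    p = a / (a + b)
    lp = _log_target(p, a, b)
    sd = config.proposal_sd
    batch = 100  # adaptation batch length during burn-in
    batch_accepts = 0
    accepts_post = 0

    steps = rng.standard_normal(config.iterations)
    log_us = np.log(rng.random(config.iterations))

    for i in range(config.iterations):
        prop = p + sd * steps[i]
        lp_prop = _log_target(prop, a, b)
        accepted = lp_prop - lp > log_us[i]
        if accepted:
            p, lp = prop, lp_prop
        in_burn = i < config.burn_in
        if in_burn:
            if config.tune:
                batch_accepts += accepted
                if (i + 1) % batch == 0:
                    rate = batch_accepts / batch
                    if rate < 0.20:
                        sd *= 0.7
                    elif rate > 0.50:
                        sd *= 1.4
                    batch_accepts = 0
        else:
            accepts_post += accepted
            kept[i - config.burn_in] = p

    acc = accepts_post / n_keep if n_keep else 0.0
    return ProbabilitySamples(values=kept, acceptance_rate=acc)


def summarize_samples(samples: ProbabilitySamples | Sequence[float]) -> PosteriorSummary:
    """Median and equal-tailed 95% interval (2.5th / 97.5th percentiles)."""
    values = samples.values if isinstance(samples, ProbabilitySamples) else np.asarray(samples, float)
    if values.size == 0:
        raise RuntimeError("cannot summarize an empty sample set")
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return PosteriorSummary(median=float(med), ci_low=float(lo), ci_high=float(hi))


def mcmc_diagnostics(samples: ProbabilitySamples, max_lag: int = 20) -> MCMCDiagnostics:
    """Chain-quality report: acceptance rate, lag-k autocorrelation, ESS.

    A chain with (numerically) zero variance — e.g. every proposal rejected —
    is flagged ``degenerate`` with an ESS of 0 rather than raising.
    """
    import arviz as az
    from statsmodels.tsa.stattools import acf

    values = samples.values
    if values.size == 0:
        raise RuntimeError("cannot diagnose an empty sample set")
    n = int(values.size)
    if np.ptp(values) == 0.0 or np.var(values) < 1e-300:
        return MCMCDiagnostics(
            acceptance_rate=samples.acceptance_rate,
            autocorrelation=np.ones(1),
            ess=0.0,
            n_samples=n,
            degenerate=True,
        )
    nlags = min(max_lag, n - 1)
    rho = acf(values, nlags=nlags, fft=True)
    ess = float(az.ess(values))
    ess = min(ess, float(n))  # ESS is capped at the retained sample count
    return MCMCDiagnostics(
        acceptance_rate=samples.acceptance_rate,
        autocorrelation=np.asarray(rho),
        ess=ess,
        n_samples=n,
        degenerate=False,
    )


def estimate_probability(
    record: EvidenceRecord,
    config: MCMCConfig | None = None,
    *,
    noninformative: NoninformativeKind = "jeffreys",
) -> tuple[PosteriorSummary, MCMCDiagnostics]:
    """Convenience wrapper: sample, summarize, and diagnose one record."""
    samples = mh_sample(record, config, noninformative=noninformative)
    return summarize_samples(samples), mcmc_diagnostics(samples)
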