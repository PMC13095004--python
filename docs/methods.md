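# Methods

## Model overview

The package is a cost-minimization analysis: the two treatment strategies
(unstratified cisplatin versus *GSTP1* c.313A>G genotype-guided selection of
cisplatin or docetaxel) are assumed clinically equivalent, so the analysis
compares expected costs only. Three layers feed each other:

1. Bayesian beta–binomial estimation of the decision-tree probabilities;
2. a first-year decision-tree expected-cost comparison with batch-genotyping
   economics and a break-even search over annual cohort size;
3. a ten-year, three-state Markov cohort projection with discounting.

## Posterior inference

Each probability is a Bernoulli parameter with a Beta prior expressed as
pseudo-counts (prior events α, prior non-events β) and a binomial
observation (k events, m non-events). The prior pseudo-counts are used
directly, with no +1 offsets: the posterior is Beta(α + k, β + m). This
parameterization is what reproduces the reported medians for the dropout
and ototoxicity probabilities, verified against the conjugate closed form.

The production estimator is a random-walk Metropolis–Hastings chain — the
estimation procedure the analysis is defined with — rather than a direct
beta draw, with the conjugate quantile function kept as an independent
oracle in the tests (median agreement to < 0.005, two-sample
Kolmogorov–Smirnov distance to i.i.d. conjugate draws < 0.05).

Sampler details (the underlying study does not specify a proposal, so these
are this package's choices):

- **Chain length**: 12,500 iterations with a 2,500-iteration burn-in
  (defaults; configurable via `MCMCConfig`).
- **Proposal**: Gaussian random walk with initial step 0.05; proposals
  outside (0, 1) are rejected outright, equivalent to a prior that is zero
  there. The chain starts at the posterior mean.
- **Step tuning**: during burn-in only, the step is rescaled in batches of
  100 iterations (×0.7 below 20% batch acceptance, ×1.4 above 50%), then
  frozen, so the sampling phase is a valid fixed-kernel chain. On the
  reference evidence this lands acceptance rates between 0.28 and 0.40 with
  effective sample sizes above 1,600 of 10,000 retained draws.
- **Seeding**: one scenario seed deterministically derives a per-probability
  sub-seed as `(seed · 2654435761 + crc32(label)) mod 2³¹`, so a full
  pipeline run is reproducible from a single integer.
- **Summaries**: posterior median and equal-tailed 95% interval
  (2.5th/97.5th percentiles). Report tables round probabilities to 2
  decimals (3 where finer precision is conventional) and currency to cents;
  full precision is carried internally.
- **Non-informative prior**: configurable between Jeffreys Beta(½, ½)
  (default) and uniform Beta(1, 1). For the low-risk ototoxicity record
  (7/33 observed) Jeffreys gives a median of 0.178 and uniform 0.186; the
  Jeffreys default matches the reported two-decimal value 0.18.
- **Diagnostics**: acceptance rate, lag-k autocorrelation
  (statsmodels `acf`), and effective sample size (arviz `ess`), with a
  degenerate-chain flag (zero-variance chains report ESS 0 instead of
  raising).

### The high-risk-prevalence prior orientation

For the carrier-prevalence probability P1, conjugacy on the evidence counts
as tabulated (obs 49/40, prior 178/114) yields a posterior median of ≈0.60,
inconsistent with the reported interval 0.37–0.47; with the prior's
events/non-events exchanged it yields ≈0.43, which is consistent. The
orientation used upstream is ambiguous, so `BetaPseudoCounts.swapped()`
exposes both, the reported tables carry the as-tabulated orientation, and
P1's median is not treated as a reproduction target. Similarly the dropout
probability P2's conjugate median (0.040) sits inside its reported interval
but rounds to 0.04, not the reported 0.03; it is checked by interval
containment only.

## First-year economics

Expected per-patient costs (H denotes the first-year audiological
management cost per affected patient):

- conventional: `c_CDDP + (1−P2)·P4·H`
- genotype-guided:
  `u(b) + A/N + P1·c_DOC + (1−P1)·c_CDDP + [(1−P1)(1−P2)·P5 + P1(1−P3)·P6]·H`

where `u(b)` is the genotyping unit cost at PCR batch size b, A the annual
equipment amortization (20% straight-line of US$38,340 = US$7,668, fully
charged to the genotyping arm and spread over the annual cohort N), and
c_CDDP/c_DOC the chemotherapy course costs (US$307.02 / US$270.29). The
difference (conventional − genotyped; positive = genotyping saves) is
`diff(N) = K − A/N` with K independent of N, strictly increasing in N and
approaching K. `K` can be computed from the tree or calibrated from a single
known difference (`calibrate_variable_saving`); calibration from the
500-patient reference value US$14.01 regenerates the entire published
difference column to within one cent and places the break-even at 275
patients (batch of 3) or 200 (batch of 5) on the 25-patient grid.

Numerical conventions: `break_even_cohort` requires a *strictly* positive
difference, so a cohort where the saving is exactly zero does not count; a
non-positive K raises `NoBreakEvenError` rather than returning a sentinel.

**The H parameter.** No headline figure exists for the first-year
audiological cost per affected patient (it aggregates device acquisition,
fitting and assessments). It is therefore a required configuration
parameter; every difference-based quantity is independent of it. The
reference scenario sets H = 180.18, calibrated so the conventional arm's
expected first-year cost reproduces its reported per-patient median
(368.19 = 307.02 + 0.97·0.35·H). Posterior draws can be pushed through both
arm formulas array-wise to get credible intervals on costs.

**Batch cost model.** Besides the unit-cost lookup {3: 26.27, 5: 17.12},
a parametric model covers other batch sizes: each run of b patient samples
adds 2 control reactions, inflates reagent use by a 10% loss allowance, and
carries a fixed per-run labor cost; the run cost is divided by b. Reagent
(US$3.0864/test) and labor (US$61.834/run) defaults are solved so batches
of 3 and 5 reproduce the lookup values exactly. These two parameters absorb
the underlying reagent/manpower line items, which are not modelled
individually.

## Ten-year projection

Three states: alive without hearing loss, alive with hearing loss
(absorbing into dead only), dead (absorbing). Death removes the same
fraction from both alive states each cycle; hearing-loss onset applies to
surviving asymptomatic patients. Occupancy is carried as continuous
expected counts — conservation to the initial cohort is then exact — and
rounded to integers only in reports, which keeps per-patient divisions
(annual saving ÷ unrounded survivors) well defined.

Annualization of cumulative literature risks:

- **Mortality** (77% cumulative): divided uniformly over the 10-year
  horizon, giving 0.077/yr, by default. This choice — not the geometric
  conversion over the source's 9.2-year follow-up — reproduces all ten
  reported yearly survivor counts (231 … 112 from 250) after rounding;
  the geometric method remains available per risk.
- **Background hearing loss** (4.2% cumulative over 10 years): geometric by
  default (0.00428/yr); the uniform value 0.0042 differs negligibly.

Discounting: cost in year t is multiplied by (1 + r)^−(t−1) with
r = 0.0679/yr, i.e. year 1 at face value — the usual cost-effectiveness
convention; the source does not state one.

Savings come in two modes. The *first-principles* mode multiplies the
incidence reduction by the continuous survivor count, a per-year
per-affected cost schedule (device + support components), and the discount
factor. The *aggregate* mode totals an externally supplied per-year saving
column exactly and derives per-patient values from the unrounded cohort.
The year-by-year schedule is configuration-driven because the reported
annual reductions jump sharply between years 2 and 3 — a device
acquisition/replacement pattern whose line items are not part of this
package's inputs — so no attempt is made to regenerate those dollar values
from first principles; the reference scenario instead carries the reported
annual reductions as aggregate-mode data, whose sum (US$13,077.73 within one
cent; the ten rounded values themselves sum to 13,077.74) and per-patient
divisions the tests verify. The reported component split (US$10,540.71
hearing aids + US$2,537.02 support) is checked to sum to the same total.

## Synthetic data

`simulate_trial_counts` draws binomial event counts at a known true
probability — the exact generating process the inference layer assumes — so
parameter recovery is testable end to end (posterior median within ±0.02 of
truth at n = 10,000; mean absolute error < 0.01 across 20 seeds at
n = 5,000). `random_scenario` draws probabilities in [0.01, 0.8], unit costs
in [0, 1,000] USD, and cohort sizes in [25, 2,000] — ranges bracketing the
reference values — to fuzz structural invariants (difference monotonicity,
config validity, break-even definition). What the generator does *not*
emulate: individual-level audiometry, genotype linkage disequilibrium,
correlated priors between probabilities, or real-world cost uncertainty;
passing tests therefore demonstrate correctness of the computational
pipeline under its stated model, not clinical validity of the inputs.

## Problem sizes

Default runs are small by construction: seven chains of 12,500 iterations,
a 20-point cohort grid, and a 10-cycle Markov projection complete in a few
seconds; the property-test suites use shortened chains (2,000–4,000
iterations) and 25–100 random scenarios.

## Known limitations

- The decision tree charges chemotherapy and first-year ototoxicity costs
  only; salvage therapy, nephro-/neurotoxicity management, and indirect
  costs are out of scope, as are currency conversion and inflation
  adjustment of the USD inputs.
- Treatment-year dropout (P2/P3) is not linked to the Markov death state;
  year-1 onward attrition is governed by the annualized follow-up mortality
  alone, consistent with the reported survivor counts.
- Cost-utility (QALY) analysis is deliberately absent: the method is a pure
  cost minimization under an equivalence assumption.
- Reported-table inputs (the per-year savings column, component totals, the
  500-patient difference) are treated as data; the package verifies their
  internal identities rather than re-deriving their supplementary line-item
  composition.
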