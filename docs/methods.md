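# Methods

## Decision problem and model structure

The package simulates individual women (default starting age 50, the
midpoint of the 45–55 target population) who undergo one of nine surgical
procedures for stress urinary incontinence, then move monthly through a
state space of *cured*, *incontinent awaiting re-treatment*, and
*containment*, with death from all causes possible at any cycle and urge
urinary incontinence (UUI) tracked in parallel. A woman can have at most
three surgeries (the initial procedure plus two re-treatments); after a
first failure 75% seek re-treatment and after a second failure 30% do,
re-treatment is always a retropubic (55%) or transobturator (45%)
mid-urethral sling, and repeat surgery is 90% as effective as primary
surgery. Non-seekers, and every woman whose third surgery fails, use
containment products permanently. UUI — residual or arising as a surgical
complication — is treated through three lines (bladder training,
medication, botulinum toxin A); if all three fail it persists untreated.

Costs (GBP 2018/19) and QALYs are accumulated per cycle and discounted at
3.5% per year over 1-year, 10-year or lifetime (to age 100) horizons.

## Effectiveness

Comparator effects enter as cure odds ratios (ORs) versus the retropubic
sling. A comparator's absolute cure probability applies the OR to the
reference's 12-month cure probability on the odds scale. The 12-month
point is used as the single cure-assessment point because it carries the
largest evidence base of the reported follow-up times; the 6/24/36-month
rows ship in the configuration but do not enter the base case.

Long-term recurrence extrapolates the reference cure curve with a
two-parameter Weibull, S(t) = exp(−(t/λ)ᵏ), fitted in closed form through
the 1-year (0.841) and 5-year (0.329) cure proportions:

    k = ln(ln s₂ / ln s₁) / ln(t₂/t₁),   λ = t₁ / (−ln s₁)^(1/k)

giving k ≈ 1.155, λ ≈ 4.56 years. The fit reproduces both anchor points to
machine precision, and the rising hazard (k > 1) means the monthly
conditional recurrence probability 1 − S(t+Δ)/S(t) grows with time since
cure.

Two readings were open and are resolved as follows. First, the Weibull is
interpreted as governing **recurrence after an initial cure**, not
time-to-failure from surgery: cure is determined at the 12-month
assessment point (probability S(1) for the reference, so the two views
coincide there) and the recurrence clock starts at t = 1 year. Second, the
0.90 re-treatment multiplier is applied on the **probability scale**
(cure probability × 0.9, clamped to [0, 1], a clamp that cannot bind for
valid inputs); applying it on the odds scale would be an equally
defensible alternative and would give slightly higher repeat-cure
probabilities. All comparators reuse the reference's Weibull shape after
cure, since the evidence provides relative effects only at the cure
assessment point.

## Simulation engine

* **Cycle length: 1 month.** Monthly resolution is needed to resolve the
  1-year horizon, short-lived complications and the UUI treatment lines.
  Annual life-table probabilities convert to monthly ones under a
  constant within-year hazard, q_month = 1 − (1 − q_year)^(1/12).
* **Fixed event order** within a cycle: mortality; surgery (cure
  determination + complication onset draws); recurrence; re-treatment
  decision; UUI-line progression; complication-duration bookkeeping;
  accrual. Death is checked first and is absorbing: a woman who dies
  accrues nothing in her death cycle.
* **Re-treatment timing.** A failure in cycle t is acted on in cycle
  t + 1: the seeking draw, and (if positive) the repeat surgery itself,
  happen in that next cycle. Seeking probabilities are per failure event,
  not per-cycle hazards; a negative draw sends the woman to containment
  permanently.
* **Discounting.** Recurring quantities (utility, containment costs) are
  discounted at mid-cycle (half-cycle correction); one-off event costs
  (procedure plus perioperative tests, complication management, UUI line
  starts) at the start of their cycle.
* **Utility composition.** The cycle utility is the continence-state
  utility (cured / pre-treatment SUI / containment), reduced to the UUI
  utility when UUI is present, minus the sum of active complication
  decrements, floored at zero. The *awaiting* and *containment* states
  are given separate utilities in the configuration but are not
  distinguished by the published evidence; the shipped values differ only
  slightly.
* **Random numbers.** Patient i of a cohort always draws from the
  substream seeded by (seed, i), independent of execution order. The same
  substreams are reused across strategies — and across PSA draws — so
  incremental comparisons use common random numbers and between-draw
  variation in the PSA reflects parameter uncertainty rather than
  resampled patient noise.

## Economic analysis

Strategies are ordered by mean discounted cost. Strict dominance (no more
costly *and* no less effective, strictly better on one axis) is marked
first; extended dominance is then removed by a repeated sweep that drops
any strategy whose incremental ICER from its cheaper frontier neighbour
is at least the ICER to its more effective neighbour. ICERs are computed
between successive frontier members from full-precision means; rounding
happens only at presentation. A zero QALY gain on the frontier reports an
infinite ICER with an explicit label.

## Probabilistic sensitivity analysis

Each draw realises: ORs from lognormals fitted to (median, 95% CrI) —
μ = ln median, σ = (ln high − ln low)/(2·1.96) — so the sampled median
reproduces the published median exactly; complication incidences from
per-strategy beta distributions; utilities and utility decrements from
moment-matched betas; costs from gammas with a configurable coefficient
of variation (default 0.2). The pre-treatment utility is sampled as a
beta-distributed fraction of the cured utility, and the 60-month cure as
a beta-distributed fraction (effective sample size 50) of the 12-month
draw, so the orderings u_cured ≥ u_pre and s₆₀ < s₁₂ hold in every draw —
necessary because the very wide published credible intervals on the cure
proportions would otherwise invert the Weibull fit's inputs. Zero-width
intervals and zero CVs make every distribution degenerate, reproducing
the base case draw for draw.

CEACs report, per willingness-to-pay value, the fraction of draws in
which each strategy attains the maximal net monetary benefit; exact ties
(possible only in degenerate configurations, since draws are continuous)
are split equally so columns always sum to one. The default WTP grid is
£1,000–£50,000 in £1,000 steps, covering the £20,000 and £30,000
thresholds; zero is excluded because WTP values are required positive.

EVPI per person is mean-max minus max-mean NMB over draws. Population
EVPI multiplies by the affected population (15,000/year) and the number
of years, undiscounted by default so the published table's exact
multiples are reproduced; a discounted variant is available. EVPPI uses a
single-loop regression estimator: each strategy's NMB is regressed on the
group's sampled values (cubic polynomial for ≤ 2 parameters, ridge
regression for larger groups), and the estimate is clipped into
[0, EVPI], its theoretical range. The linear smoother for large groups is
conservative for strongly non-linear relationships; the estimator is
validated against a closed-form one-parameter toy in the tests.

## Synthetic defaults and what the tests show

The evidence tables print the ORs, the reference cure curve, the policy
constants, the discount rate and the population size — these ship as-is.
Everything else is a **documented synthetic placeholder**: complication
incidences (≤ 0.09, mesh and persistent-pain complications rarer than
transient ones), one-off complication costs (£100–£2,600), utility
decrements (≤ 0.10), procedure tariffs (day-case £1,400–£1,800 <
inpatient £2,600–£3,900), utilities (0.67–0.85), the UUI pathway, and a
Gompertz female life table (q(x) = 2·10⁻⁵·e^{0.094x}, ages 40–100,
implied life expectancy at 50 ≈ 35 years). One relative effect — the
injectable-agents OR, absent from the published table — is likewise a
placeholder (0.45, CrI 0.25–0.80, placed below the sling comparators).
The persistent-pain duration defaults to 1 year; sensitivity scenarios
set it to 3 or 5 years. Utilities are not age-adjusted by default (an
optional multiplier schedule exists).

Consequently the test suite validates the *mechanics* — conversion
algebra, extrapolation, pathway rules, accounting identities, estimator
behaviour, dominance logic — on these placeholder magnitudes. Passing
tests do **not** certify the published cost/QALY/CEAC magnitudes, which
depend on supplementary inputs not printed in the evidence base; anyone
using this package for decision-making must supply their own complication,
cost and utility estimates via the configuration file.

## Problem sizes and numerical tolerances

Default analysis sizes are desk-scale: 2,000 patients per cohort and 200
PSA draws, with flags to reach larger scales. The validation suite uses
20,000 patients for the simulation-versus-closed-form oracle (agreement
within 3 Monte-Carlo standard errors), 10,000 fuzzed lifetime
trajectories for the pathway rules, 200 draws × 9 strategies for the
CEAC/EVPI structural properties, 10,000 draws for the EVPPI toy (5%
relative tolerance), and 100,000 draws for recovering the published OR
medians (2 standard errors of the sample median). The Weibull fit is
asserted to 1e-9 relative tolerance and the odds-scale composition
identity to 1e-12.

## Known limitations

* Baseline UUI prevalence among women with mixed incontinence is not
  modelled; UUI enters only as a post-surgical complication, so the UUI
  pathway's cost and QALY impact is understated relative to a population
  where roughly half have urge symptoms at baseline.
* No surgery-attributable mortality; mortality is all-cause only.
* The third UUI line failing leaves UUI untreated permanently (no repeat
  botulinum toxin cycles).
* Relative effects are assumed constant over the lifetime — the same
  limitation the underlying short-term evidence imposes on any
  extrapolating model.
* Costs are entered at 2018/19 prices; no inflation machinery.
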