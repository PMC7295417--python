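# suisim

Markov microsimulation for the cost-utility analysis of nine surgical
treatments for women with stress urinary incontinence (SUI) or
stress-predominant mixed urinary incontinence, from a UK NHS and personal
social services perspective.

The package is aimed at health economists and HTA analysts who want a
transparent, scriptable re-implementation of this decision problem:
patient-level simulation of treatment and re-treatment pathways, cost and
QALY accumulation with discounting, probabilistic sensitivity analysis
(PSA) with cost-effectiveness acceptability curves (CEACs), and expected
value of (partial) perfect information (EVPI/EVPPI).

## The model in brief

Nine strategies are compared, with the retropubic mid-urethral sling
(retro-MUS) as reference: transobturator MUS, open and laparoscopic
colposuspension, traditional sling, single-incision sling, bladder-neck
needle suspension, anterior repair, and injectable bulking agents.

* **Effectiveness.** Each comparator's cure odds ratio OR (with 95%
  credible interval) is applied to the reference's absolute 12-month cure
  probability p₀ on the odds scale: p = p₀/(1−p₀)·OR / (1 + p₀/(1−p₀)·OR).
  Long-term recurrence after cure follows a Weibull survival curve
  S(t) = exp(−(t/λ)ᵏ) fitted in closed form through the reference cure
  proportions at 1 year (0.841) and 5 years (0.329), discretised into
  monthly conditional recurrence probabilities 1 − S(t+Δ)/S(t).
* **Pathway.** Women receive at most three surgeries. After a first
  failure 75% seek re-treatment (30% after a second), always a retro-MUS
  (55%) or transobturator MUS (45%) that is 90% as effective as primary
  surgery; everyone else — and everyone after a third failure — manages
  with containment products. Urge urinary incontinence, whether residual
  or surgery-induced, is treated through three lines (bladder training,
  medication, botulinum toxin A). All-cause mortality follows a female
  life table.
* **Economics.** Costs (GBP 2018/19) and QALYs accrue per monthly cycle,
  discounted at 3.5% per year with a half-cycle correction, over 1-year,
  10-year and lifetime horizons. Strategies are compared by ICERs with
  strict and extended dominance; decision uncertainty is summarised by
  CEACs (probability of maximal net monetary benefit NMB = λ·QALY − cost),
  per-person EVPI = E[maxₛ NMB] − maxₛ E[NMB], its population scaling, and
  regression-based EVPPI per parameter group.

Published inputs (odds ratios, reference cure curve, policy constants,
discount rate, 15,000 affected women/year) are tagged `provenance="paper"`
in the shipped configuration; everything the evidence tables do not print
(complication incidences and costs, tariffs, utilities, the UUI pathway,
the life table) ships as documented synthetic placeholders tagged
`provenance="synthetic-default"` — replace them with your own estimates
for substantive use. See `docs/methods.md`.

## Worked example

```python
from suisim import *

p = default_parameter_set()
c12, c60 = p.cure_at(12), p.cure_at(60)
w = fit_weibull_two_points(1, c12.cure_prop, 5, c60.cure_prop)
print(f"Weibull fit: shape={w.shape:.4f}, scale={w.scale:.3f} years")
print(f"transob-MUS 12-month cure prob: {effective_cure_prob(p, 'transob-MUS', 1):.3f}")
print(f"retro-MUS repeat-surgery cure prob: {effective_cure_prob(p, 'retro-MUS', 2):.4f}")

results = [simulate_cohort(p, s, 1000, "10y", seed=1)
           for s in ("retro-MUS", "trad-sling", "single-incision")]
print(compute_icers(results).round(3).to_string(index=False))
```

prints

```
Weibull fit: shape=1.1553, scale=4.562 years
transob-MUS 12-month cure prob: 0.796
retro-MUS repeat-surgery cure prob: 0.7569
       strategy     cost  qaly  inc_cost  inc_qaly       icer     label
single-incision 5501.958 6.440       NaN       NaN        NaN reference
      retro-MUS 5629.629 6.491   127.671     0.052   2464.260          
     trad-sling 6899.225 6.499  1269.596     0.007 176098.338
```

The Weibull shape > 1 means the recurrence hazard rises with time since
cure. The transobturator sling's OR of 0.738 converts the reference's
0.841 cure probability to 0.796; a repeat retro-MUS is 90% as effective as
a primary one (0.841 × 0.9 = 0.7569). The ICER table ranks strategies by
mean discounted cost and prices each extra QALY along the efficient
frontier — here (synthetic cost/utility placeholders, 1,000 women per
arm, 10-year horizon) the traditional sling's extra 0.007 QALYs cost
about £176,000 each, far above conventional willingness-to-pay.

The same analyses run from the shell:

```sh
suisim basecase --horizon lifetime --n-patients 2000 --seed 1 --out out/
suisim psa --horizon 10y --n-draws 200 --n-patients 2000 --seed 1 --out out/
suisim scenario --scenario mesh-incidence=0.2 --horizon lifetime --out out/
```

each writing delimited tables (cohort results, ICER table, CEAC, VOI) plus
a JSON manifest from which the run can be reproduced exactly.

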