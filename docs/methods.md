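# Methods

## Model structure

The decision problem compares two breastfeeding-promotion strategies —
standard health-facility promotion (HFP, parameterised by the control arm
of a two-arm cluster trial) and community peer counselling on top of HFP
(parameterised by the intervention arm) — for their effect on infant
diarrhoea over the first six months of life.

The engine is a discrete-time cohort model with monthly cycles over the
joint state space {EBF/PBF, MF/RF} × {well, sick} plus an absorbing dead
state.  Diarrhoea severity (mild / moderate-outpatient / severe-
hospitalised) is a within-cycle decomposition of new sick occupancy rather
than extra Markov states: severity determines treatment cost and
disability weight of an episode but not subsequent dynamics.

Within a cycle the update order is **death → feeding transition → health
transition conditional on destination feeding state**.  The order matters
at the third decimal of occupancy; it is fixed, documented, and shared
between the cohort engine, the individual-level microsimulation used as
its oracle, and the synthetic-trial generator, so the three components are
mutually consistent by construction.

The cohort starts fully alive, well, and in EBF/PBF.  This is the simplest
reading of a model whose month-1 feeding row acts on a pure EBF/PBF start;
the initial state is exposed in the settings (`initial_feeding`).

New diarrhoea episodes are counted as transitions into the sick state
(well→sick inflow).  A sick→sick month continues the same episode and
incurs no additional treatment cost or disability; with mean episode
duration of 7 days against a 30-day cycle this undercounts recurrent
episodes within a persistent-sick spell, which is the conservative choice.

## Parameters

All parameters live in a validated `ParameterSet`; `default_parameters()`
is the built-in base case.  Key quantities, units and defaults:

| group | parameter | default | unit / note |
|---|---|---|---|
| feeding | α₁…α₄ per arm × month 1–6 | monthly tables | stay/switch probabilities |
| health | β₁…β₄ per arm × feeding state | 8-cell table | monthly sick/well probabilities |
| costs | HFP promotion | 3.60 (2.20–6.43) | US$/child, 2007 prices |
| costs | peer counselling | 139 (74–233) | US$/child |
| costs | hospitalised / outpatient case | 95 (65–134) / 9 (3.80–26) | US$/episode |
| severity | RR hospitalisation, partial BF | 4.43 (1.75–13.84) | vs exclusive BF |
| severity | RR, not breastfed | 14.40 (6.13–33.86) | used only via `rf_weight` |
| severity | p_hosp_ebf | 0.02 | **calibrated, not an external estimate** |
| severity | p_moderate_given_not_severe | 0.50 | **calibrated, not an external estimate** |
| DALY | disability weights mild/moderate/severe | 0.061 / 0.202 / 0.281 | dimensionless |
| DALY | episode duration | 7 | days |
| DALY | life expectancy / age at onset | 53 (38–77) / 0.1 | years |
| DALY | discount rate | 0.03 (0–0.06) | per annum |
| mortality | 6-month cumulative, control / intervention | 0.003 / 0.008 (0.001–0.01) | all-cause, per child |
| settings | WTP per DALY | 1653 = 3 × 551 | US$ |
| settings | mean MEBF control / intervention | 1.5 / 3.5 | months, survival-analysis means |

The health-transition table is stored under the semantics in which the
complementary pairs (β₁, β₄) and (β₂, β₃) each sum to one — the unique
reading under which all eight table cells are coherent.  Two-decimal
probability rows whose sum is within 0.02 of one are renormalised row-wise
on load; larger discrepancies are validation errors.  Where a source prints
conflicting values for the not-breastfed relative risk, the tabulated 14.40
is the default and the alternative is reachable by config override.

Mortality is arm-specific but feeding-independent: only arm-level
all-cause six-month risks are available, so there is nothing
feeding-specific to implement.  The MF/RF hospitalisation risk uses the
partial-breastfeeding RR alone by default because replacement feeding was
essentially absent (~0.3%) in the source trial; `severity.rf_weight` mixes
in the not-breastfed RR for scenario analyses.  RRs multiply the baseline
severe probability and are clamped at 1; no risk/odds conversion is
attempted since baseline risks are small.

## Costs and discounting

Promotion costs are charged once per child at entry (the per-child-per-year
programme figures are the per-child cost of the six-month episode of
care); treatment costs accrue per episode at the cycle midpoint,
discounted at the annual rate with monthly compounding,
(1 + r)^(−(t − 0.5)/12).  No half-cycle correction is applied anywhere
else.  YLD uses continuous discounting e^(−r·t_mid) from the episode's
cycle midpoint; YLL uses the standard continuous form
(1 − e^(−r(L − a)))/r.  At r = 0 all formulas reduce exactly to their
undiscounted sums (tested).

### Absolute per-child costs and the severity calibration

The model's expected per-child costs from the printed inputs alone
(≈ US$17 HFP, ≈ US$148 peer counselling at the default severity settings)
are far below the reported per-child totals (113 / 250): the reported
totals embed a severity mix that was never printed.
`calibrate_severity(p, arm, target)` bisects on `p_hosp_ebf` (expected cost
is monotone in it) to find the severe share reproducing a target per-child
cost to US$0.01.  For the control arm the target 113 is reachable
(p* ≈ 0.60).  For the intervention arm the target 250 is **not** reachable:
even with every episode hospitalised, the intervention arm's low diarrhoea
transition probabilities cap expected costs near US$206, and the function
raises an error reporting the achievable range.  Consequently the
base-case report defaults to the reported per-child totals as cost
*fixtures* (`settings.cost_source = "fixtures"`, values 113/250) for the
incremental table, while the model-computed costs are always written
alongside for audit.  Setting `cost_source = "model"` bases the CEA on the
cohort model's own costs.

## Effect measures

MEBF has two sources.  `survival_means` (the default) returns the per-arm
mean durations 1.5 / 3.5 months estimated by the original survival
analysis of recall data — these are the figures the base-case incremental
effect of 2.0 months rests on.  `occupancy` sums EBF/PBF occupancy over
cycles; with the default tables it gives ≈ 4.56 (intervention) and ≈ 3.46
(control) months, a materially different level and a smaller increment
(≈ 1.10).  The two modes answer different questions (duration until
cessation vs time spent in the state under two-way switching) and the
discrepancy is deliberately surfaced rather than hidden: reports record
which mode produced each number.

Per-child DALY totals of ~5.8 reported alongside the original analysis
cannot be reconstructed from any combination of the printed disability
weights, episode durations, and mortality rates (they exceed the maximum
YLL of a 0.8% death risk by an order of magnitude).  The package therefore
reports its own transparently computed YLD/YLL components and does not
attempt to force agreement.  By this arithmetic peer counselling *adds*
≈ 0.13 DALYs/child (the intervention arm's higher observed all-cause
mortality dominates its diarrhoea reduction), so the DALY comparison is
unfavourable — in qualitative agreement with the original conclusion that
the strategy is not cost-effective per DALY.

## Sensitivity analyses

**One-way / tornado.**  Each parameter is set to its low and high bound
with everything else fixed and the full pipeline re-run with
model-computed costs (so that cost parameters can influence the result).
The output metric is incremental net health benefit ΔE − ΔC/λ at the
configured willingness-to-pay (per-DALY by default).  The tornado ranks
parameters by swing = |NHB_high − NHB_low| and normalises shares to 100%
(the standard normalisation; swing shares are permutation-invariant).  The
default range set covers the eight published sensitivity ranges (two
mortality rates, life expectancy, discount rate, two treatment costs, two
promotion costs).

**Probabilistic.**  Probability parameters get beta distributions by
method of moments; their standard errors are not published, so defaults
use binomial SEs from the per-arm sample sizes (368 control, 329
intervention), overridable via `arm_n`.  Relative risks get lognormals
with μ = ln(point), σ = (ln hi − ln lo)/3.92.  Costs get gammas under the
stated se-equals-mean convention — shape 1, i.e. exponential — which is
implemented literally but prominently flagged; `cost_se` accepts
user-supplied standard errors.  Row constraints hold by construction: the
free member of each complementary pair is drawn and its partner set to one
minus it, so no resampling is ever needed.  Each draw uses an independent
substream `default_rng([seed, draw_index])`, making any single draw
reproducible in isolation.

PSA incremental MEBF is computed in occupancy mode: the survival-means
figure is a configured constant and would contribute no sampling
uncertainty to the scatter.  CEACs report, per λ, the fraction of draws
with strictly positive net monetary benefit (ties count for the
comparator), so the two-strategy curves sum to one.  With default inputs
≈ 8% of 10,000 draws are cost-effective at US$1653/DALY and the top
tornado parameter is the intervention-arm mortality rate — the published
analysis reports 9% and the same top parameter, a qualitative (not
numeric) correspondence since the underlying standard errors were never
published.

## Synthetic trial generator

`simulate_trial` emulates the panel structure behind the transition
tables: two arms (368/329 children by default) in 12 clusters per arm,
visits at weeks 3, 6, 12, 24 mapping to months 1, 2, 3, 6
(ceil(week/4.345)), with current feeding state, diarrhoea recall and vital
status read off a latent monthly path generated by exactly the process the
cohort model assumes.  Dropout is an independent per-visit probability
(default 0.02, chosen to give attrition of the order seen in such trials);
once dropped or reported dead a child contributes no further records.  An
optional cluster-level random intercept on logit(α₁) exists to exercise
the cluster-bootstrap CI; it defaults to 0 because the economic model
ignores clustering.

The generator deliberately does **not** emulate recall measurement error
(24-hour vs 7-day discordance), seasonality, or intention-to-treat
recoding of missing data; passing recovery tests therefore demonstrates
estimator correctness for the assumed process, not robustness to the
messiness of real recall data.

**Re-estimation.**  Feeding transitions use the discrete-time multinomial
estimator on consecutive observation pairs: month 1 from the known EBF/PBF
start (the MF/RF origin row is unobservable and flagged missing), months 2
and 3 from adjacent visit pairs, and months 4–6 from the week-12→24 pair
under a constant-within-interval assumption — the matrix cube root
(`scipy.linalg.fractional_matrix_power`) of the empirical three-month
transition matrix, with delta-method standard errors propagated
numerically through the root map.  The estimand of the bridged cells is
the cube root of the true three-month product, not any single month's
value; recovery tests compare against that estimand.  Health transitions
pool adjacent-month pairs stratified by arm × feeding state at the later
visit (the state whose matrix acted in that month).  Cells with no
observed origin mass are flagged missing, never imputed as zero.  The
original analysis estimated these quantities with parametric survival and
longitudinal models on real recall data; the multinomial estimator used
here is consistent for the generating process the economic model assumes,
and the recovery target is the transition table itself.

`prevalence_ratio` reports the intervention/control prevalence ratio at a
visit with a seed-controlled cluster-bootstrap lognormal CI (resampling
clusters with replacement within arm).

## Numerical choices

- Reported dollar ratios are truncated toward zero at the reporting layer
  only — the unique rule consistent with all published base-case ratios
  (113/1.5 = 75.33→75, 250/3.5 = 71.43→71, 137/2 = 68.5→68); internal
  values keep full precision.
- A published net-health-benefit caption of the form (E − C)/λ is
  dimensionally incoherent; the standard NHB = ΔE − ΔC/λ (and
  NMB = λΔE − ΔC) is implemented instead.
- Severity calibration bisects to |cost − target| ≤ US$0.01.
- Probability-row renormalisation tolerance 0.02 before load-time
  normalisation; post-normalisation validation tolerance 1e-9.
- CEAC ties (NMB exactly 0) count for the comparator.
- Matrix roots are clipped at 0 and re-normalised row-wise (the raw
  fractional power of a noisy 2×2 stochastic matrix can stray slightly
  outside the simplex).

## Problem sizes

The validation experiments use 100,000 children for the
cohort-vs-microsimulation comparison, 10,000 children per arm for
parameter recovery, 10,000 draws for the PSA, and 100 replicates × 100
bootstrap resamples for the CI coverage experiment; these sizes put
Monte-Carlo error well below the tolerances being tested while keeping the
full suite fast on a single CPU.

## Known limitations

- Only diarrhoea morbidity is modelled; no other breastfeeding-sensitive
  outcomes, no age structure beyond six months, no seasonality.
- Mortality is feeding-independent (data constraint, see above), so the
  DALY effect of the intervention is driven by the arm-level mortality
  difference.
- The absolute per-child cost totals and per-child DALY totals of the
  original report are not derivable from printed inputs; the package
  treats the former via fixtures + calibration and the latter as
  non-reproducible (see above).
- The PSA's probability standard errors are assumptions (binomial at trial
  sample sizes), so PSA percentages are qualitative correspondences, not
  reproductions.
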