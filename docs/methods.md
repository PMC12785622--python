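# Methods

## Scope and data model

shelfkin analyses accelerated storage trials in which one product is held
under several packaging × temperature conditions and a set of quality
attributes is measured on a fixed schedule. The in-memory model is a
`StudyDataset` of `QualitySeries` objects keyed by (attribute, condition).
Two kinds of incompleteness are first-class:

* **Censoring by rejection.** Sensory evaluation stops once the panel
  rejects the product, so a series may end early (`terminated_early`).
  Such a series still contributes to kinetic fitting (its measured points
  are valid), but its experimental shelf life may only be a bound.
* **Detection limits.** Microbial counts below the plating detection limit
  are stored as qualified records ("<2.5e-1 cfu/g"), never as numbers.
  They are excluded from kinetic fits and from maxima — a "<0.25" plate is
  evidence of absence, not a small count — unless *every* record is
  censored, in which case the summary itself is the largest limit, still
  qualified.

Temperatures live in °C throughout the data layer; the single Kelvin
conversion (+273.15 exactly) happens inside the Arrhenius module.

## Kinetic fitting

Both reaction orders are fitted by unweighted two-parameter ordinary least
squares: value on time (zero order) and log-value on time (first order),
with k = −slope. Design choices:

* **Free intercept.** Q0 is estimated, not forced through the measured
  baseline. Forcing the regression through the origin on the log scale
  distorts k whenever the first sessions sit slightly off the long-run
  trend, which hedonic means routinely do.
* **Baseline inclusion.** When a week-0 baseline is known it is prepended
  before fitting (`include_baseline`, default on). The choice moves k in
  its last significant digit on panel-scale data, so it is configurable.
* **R² on the fitting scale.** The first-order R² is computed on ln Q —
  the scale the line was fitted on — so the order comparison is a
  comparison of the two linearisations.
* **Unweighted.** Panel sd and n are descriptive; with a constant panel
  size per session there is no weighting to gain.
* **Order selection** keeps the larger R²; an exact tie goes to first
  order, the conventional model for browning-driven quality loss. On the
  packaged panel data the refitted orders do not always agree with the
  published choice of first order (at some conditions the linear fit edges
  out the exponential one); the selection rule is applied as stated rather
  than hard-coding the published preference.

Degenerate inputs are explicit errors: fewer than three usable points
(`InsufficientDataError`), a single distinct time
(`DegenerateDesignError`), non-positive values on the log scale
(`DomainError` naming the offending week). A flat series returns k = 0
with R² = 0 by convention.

## Arrhenius extrapolation

`fit_arrhenius` regresses ln k on 1/T (kelvin) over at least three distinct
temperatures; Ea = −slope·R with R = 8.314 J/(mol·K). Fitting is linear on
the Arrhenius plot, not nonlinear on (T, k): with four temperatures and no
replicate rate estimates, the linearised fit is the defensible choice, and
it is what multi-temperature storage studies report. Points are not
weighted by the precision of the underlying kinetic fits (none is
published for the packaged study, and propagating it would suggest a
precision the design cannot support).

Extrapolation quality depends strongly on the scatter of the input rates:
for the packaged colour-acceptance rates, the per-packaging Arrhenius fits
have R² between 0.48 and 0.96, and the rate the fitted law implies at
25 °C can differ from the 25 °C input rate by a third. `k_at` is exact with
respect to the fitted law; it cannot be more consistent than the rates fed
in.

## Shelf life

Predicted: t_s = (Q0 − Qe)/k or ln(Q0/Qe)/k. Defaults are the packaged
study's values — Q0 = 6.3 (initial colour-acceptance score), Qe = 5.0 (a
mean below "neither like nor dislike" ends shelf life). `reported_weeks`
floors t_s to completed weeks; floor is the conservative shelf-life
convention and agrees with rounding-to-nearest on every reproducible cell
of the packaged comparison, so the policy is configurable but floor is the
default. Qe ≥ Q0 yields t_s = 0 flagged `already_rejected` rather than an
error, so batch comparisons keep going.

Experimental: rejection is the *first* session with mean strictly below
the threshold; shelf life is the last passing session before it. Strictness
matters — a week-24 mean of exactly 5.0 passes, producing the open
">24 weeks" bound that interpolation or a ≤ rule would destroy. No
interpolation between sessions is attempted: with 3-week spacing the data
cannot distinguish failure at week 16 from week 18, and the last-passing
convention reproduces every observed cell of the packaged study.

The default decision attribute is colour acceptance: in the packaged study
colour is the failure mode that drives rejection, and the overall-
acceptance series contradict the published shelf-life table at one hot
condition while the colour series reproduce it everywhere.

`compare_actual_predicted` takes its rate constants from one of three
sources: `fitted` (fresh per-condition fits with order selection),
`printed` (the packaged rate table — the study's own constants), or
`arrhenius` (per-packaging extrapolation from the printed rates). A
condition with no obtainable rate keeps its experimental column and
reports the prediction as absent.

## Synthetic data generator

The generator emulates the study design, not just the model:

* **Decay series** — model curve plus additive Gaussian noise
  (`noise_sd`, default 0.05 attribute units), one independent seeded
  stream per (seed, temperature).
* **Panel studies** — per session, `n_consumers` (default 50) individual
  ballots ~ Normal(model mean, `consumer_sd`, default 1.5 points), clipped
  to the 1–9 hedonic range and rounded to whole points before averaging,
  so synthetic session means show the same ≈0.02 granularity as real panel
  tables; sessions default to every 3 weeks through week 24. Censoring
  applies the same strict below-threshold rule as the analysis, keeping
  generator and analyser consistent by construction.
* **Arrhenius families** — exact k(T) = k_ref·exp(−Ea/R·(1/T − 1/T_ref)),
  for round-trip tests.

What it does **not** emulate: correlated multi-attribute noise, panel
drift or consumer learning across sessions, non-Gaussian ballot
distributions, and microbial growth. Passing recovery tests therefore show
that the estimators are consistent under the stated noise model, not that
real panels satisfy it.

Monte-Carlo recovery at the study's own scale (first-order k = 0.028/week,
Q0 = 6.3, Qe = 5.0, 50 consumers, sd 1.5, 3-week sessions, censoring on)
keeps the pipeline's predicted shelf life within ±3 weeks of the analytic
value in ≈97% of 500 replicates; the suite asserts ≥90%. Slower decay
regimes are intrinsically harder under the same absolute tolerance: the
relative error in k maps to an absolute shelf-life error proportional to
t_s, so a condition with a months-long shelf life recovers less often than
this one.

## Packaged fixtures and their warts

The fixture CSVs transcribe the study's printed tables cell-for-cell, and
a checksum test freezes the transcription. Known internal inconsistencies
are carried verbatim and flagged in a `note` column rather than repaired:
two zero-order rate entries whose printed scale is out of line with their
neighbours (`scale_anomaly`), and one first-order entry (nitrogen-flushed
bag at 25 °C, k = 0.002/week) that conflicts with the value the study's
conclusions quote for the same condition (`conflicts_conclusions`) and
produces an implausible 115-week prediction. The published rate constants
themselves cannot be reproduced exactly from the panel means under any
standard OLS variant (the original fitting protocol is underdetermined);
refits agree to about one significant figure, and the activation energies
implied by the printed rate tables agree with the published ones to within
about 2.5 kJ/mol. The comparison table's low-temperature predicted cells
(58/23 weeks at 4 °C) stem from an unstated extrapolation and are likewise
stored as printed, not recomputed.

## Numerical notes

Regressions go through `scipy.stats.linregress`; the test suite checks
them against hand-coded closed-form least-squares formulas at 1e-10.
Problem sizes throughout the suite (≤ 1000 replicate fits of ≤ 9-point
series) keep the full test run in seconds.
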