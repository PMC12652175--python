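# Methods

## Absolute qPCR quantification

Each run carries four fluorophore channels (AURKA, HDAC4, CARHSP1, one
housekeeping gene) and a 10-fold plasmid dilution series per channel
(1e5–1e2 copies/µL by default). The standard curve is the OLS fit of Cq
on log10(copies); amplification efficiency E = 10^(−1/slope) − 1 is the
run-level QC statistic, accepted in the inclusive window [90%, 110%].
Curves are fitted strictly per run and per channel — pooling across runs
would average away exactly the failure mode the gate exists to catch.
r² is computed and logged with a warn-only threshold (default 0.98) but
never gated, since efficiency is the only hard criterion.

Unknown wells are back-calculated as copies/µL = 10^((Cq − intercept)/slope).
Replicate wells are averaged on the Cq scale before quantification
(conventional qPCR practice). An absent/undetermined Cq is treated as
**zero copies** — true biological non-expression, not missing data. This
keeps Δ[RNA] and the SFI defined for silent targets; the alternative
(missingness) would make composite scoring undecidable for exactly the
samples the index is most interesting for. A sample whose housekeeping
channel yields zero copies cannot be normalized and is flagged invalid,
never silently scored.

## The SFI

SFI = (3.14·Δ_CARHSP1 + 4.51·Δ_AURKA + 18.91·Δ_HDAC4) · s·v·1000/300.
The weights and the tier thresholds (290/320) are published constants
and are never re-estimated here. Two conventions are fixed explicitly:

* **Units of s.** The formula's source does not state whether s is an
  absolute count or in millions. This package carries s in millions of
  motile sperm in the 0.3 mL assay aliquot and applies the formula as
  printed; the whole aliquot conversion (1000/300 per mL) is exposed as
  one configurable multiplier (`aliquot_scale`) so an alternative unit
  reading is a configuration change, not a code change.
* **Tier boundaries.** 290 and 320 belong to the intermediate tier
  (the inequalities are "< 290", "> 320", "290–320").

`derive_thresholds` re-derives a cutoff from labelled SFI values: the
candidate grid is the midpoints between consecutive sorted unique values
plus the two extremes; the center maximizes Youden's J (sensitivity +
specificity − 1) with a sample called positive when SFI ≥ cutoff; ties go
to the lowest candidate (deterministic, favors sensitivity). The
intermediate band is center ± margin (default 15 SFI units, reproducing
the published 30-unit band width); margin 0 collapses it. This is one
documented reading of an underspecified ROC procedure — the statistic and
band-width rule behind the published 290/320 are not stated, so the
shipped defaults remain the published constants and `derive_thresholds`
never overrides them silently.

## WHO categorization

The abnormality tally uses exactly three parameters — concentration,
progressive motility, normal morphology — against lower reference limits
that are **inclusive** (a value at the limit is normal). Categories:
normospermic (0), one/two altered parameters, OAT (all 3). Total
motility is carried and used by the high-quality gate but excluded from
the tally; this three-parameter reading matches the definition of
normospermia by concentration/progressive motility/morphology and the
OAT definition of three concurrent abnormalities, and is configurable.
The numeric defaults (16 × 10⁶/mL, 30%, 4%, 42% total motility) are the
6th-edition WHO manual limits, shipped as overridable configuration.
The "very high-quality" subgroup is normospermic samples with
concentration ≥ 50 × 10⁶/mL, total motility ≥ 50%, progressive motility
≥ 40% and ≥ 14% normal forms (Kruger), all inclusive.

## Training pipeline

Binarized target (1 = score 6, 0 = score 0), three Δ[RNA] predictors.

* **Split**: stratified; per class the training set gets
  round-half-up(n_class · fraction) samples, so the class ratio is
  preserved up to rounding and totals are conserved. Deterministic per
  seed; seeds are mandatory (no global random state).
* **Standardization**: z-scores with the population (divide-by-n)
  standard deviation — an arbitrary but fixed convention so tests can be
  exact; a `ddof` flag switches to the sample convention. Test data are
  always transformed with stored training statistics (no leakage; the
  suite asserts a shifted test set does not re-center).
* **Logistic fit**: IRLS (Newton) on the class-weighted log-likelihood
  with optional L2 ridge on the coefficients (intercept unpenalized).
  Convergence at gradient norm < 1e−8 or 100 iterations. With ridge = 0
  on separable data the MLE does not exist; divergence is detected
  (complete separation along the fitted direction with |coefficient| > 8
  on the z scale) and reported as an error advising ridge > 0. Class
  weights: none, an explicit mapping, or "balanced"
  (n / (2·n_class)). Odds ratios are exp(coefficients).
* **PR curve**: one point per candidate threshold (all distinct scores
  plus 0 and 1); positive means score ≥ threshold; precision at an empty
  positive set is 1 (the standard endpoint convention that keeps the
  curve total).
* **Threshold selection**: maximizes F1 (the printed criterion is only
  "balancing false positive and true positive detection"; F1 is the
  documented default and the criterion argument is pluggable), optionally
  restricted to a probability band; ties — including F1 values equal in
  exact arithmetic that differ by one ulp in floats — resolve to the
  lowest threshold.
* **Cross-validation**: stratified k-fold (per-class fold sizes differ by
  at most 1); each fold's report comes from its own fitted model; a class
  smaller than k is an error.

The reported training metrics of the original 106-sample study are not
reproducible without that private dataset; the suite instead checks the
machinery by oracle equivalence (brute-force PR enumeration, statsmodels
as an independent fit reference) and parameter recovery on simulated data
(n = 5000, ±10% relative error).

## Synthetic data

`simulate_training` models Δ[RNA] as multivariate lognormal: ratios are
strictly positive and right-skewed, and a class shift on the log scale is
the simplest mechanism consistent with box-plot-style group differences.
Defaults: log-sd 0.5 per gene, pairwise log-scale correlation 0.6, class
shifts of 1.0 / 1.5 / 1.0 log units (AURKA / HDAC4 / CARHSP1). These make
HDAC4 the dominant discriminator, give every gene essentially full power
in a two-sample test at 53 samples per class (p < 0.01), and make two
classes of 53 nearly separable for the three-gene logistic model —
mirroring the qualitative structure the pipeline was designed around
without asserting anyone's exact headline metrics. What the generator
does **not** emulate: measurement noise of the qPCR step feeding into
Δ[RNA], any dependence between expression and semen parameters, age or
batch structure. Passing tests therefore validate the pipeline's
arithmetic and statistical machinery, not clinical performance on real
ejaculates.

`build_count_matched_fixture` constructs cohorts whose classification
tallies are exact by design: each record's semen parameters are drawn on
the prescribed side of every WHO limit with a relative safety margin
(default 5% of the limit), and its Δ[RNA]/motile inputs are solved so the
SFI lands inside the prescribed tier with an **absolute** margin (default
5 SFI units — a relative margin cannot work inside the 30-unit
intermediate band, where 5% of 290 already exceeds the half-band).
Jitter is seeded and confined to the safe regions, so different seeds
give different raw tables with identical classification counts; this is
property-tested over randomized specifications. Non-high-quality
normospermic records keep their concentration strictly below the
high-quality gate so the high-quality count is also exact.
`simulate_run_sheet` renders Δ[RNA] targets back into raw Cq run sheets
through true per-channel curves (doubling slope), closing the loop for
end-to-end quantification tests.

## Reporting

Counts are the source of truth; percentages are derived by round-half-up
at a configurable precision (default 1 decimal) — so a report can match
tables printed at mixed precisions, and internally inconsistent printed
percentages are resolved in favor of the counts. Report generation is a
pure function of the cohort and configuration (byte-identical JSON on
rerun). Per-record failures are collected per sample_id; a run aborts
only when more than a configurable fraction (default 10%) of records
fail, reflecting clinical batch practice where one bad tube should not
void a plate.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses
are defined at: the 627-record cohort structure, 106-sample training
sets, n = 5000 for parameter recovery and simulator calibration checks,
200 replicates for the power check. The full suite completes in a few
seconds on one core.

## Known limitations

* The relation between the published SFI weights and the logistic odds
  ratios is not specified anywhere; the weights are treated as opaque
  published constants.
* The housekeeping gene is unnamed in the source material and is handled
  as an opaque channel.
* The ROC convention behind the published 290/320 thresholds is a
  documented choice (Youden J, midpoint grid, lowest-tie), not a
  reconstruction.
* Generator parameters are explicit configuration, not estimates of any
  real population; clinical validation requires real cohorts.
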