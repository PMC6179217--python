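# Methods

## The problem

Patient-level hospital costs vary enormously, and part of that variability is
suspected to be waste.  The decomposition implemented here splits total
patient-level cost variability into contributions from declared *drivers*
(casemix group, age, socio-economic indices, wards, units, doctors, calendar
fields, clinical flags), and then into two subtotals: variability explained
by drivers *predictable before the admission starts* (warranted — the
hospital cannot influence a patient's age or diagnosis mix) and variability
attached to drivers *not predictable a-priori* (the discharging ward, the
attending doctor, the hour of arrival).  The non-predictable subtotal is an
upper bound on potentially unwarranted, waste-related variability: anything
the model attributes to those drivers could in principle be standardised
away, though part of it may still be irreducible randomness.

## Model and estimator

The outcome is the raw, untransformed admission cost (costs are right-skewed
but the published decomposition operates on the dollar scale; the l1 penalty
supplies some robustness to the resulting outliers).  With the design split
into m named groups, the fit minimizes

    (1 / 2n) * ||y − Xβ||²  +  λ [ (1 − α) Σ_j w_j ||β^(j)||₂  +  α Σ_i |β_i| ]

a sparse group lasso: α mixes a per-coefficient lasso term (α = 1 is the
plain lasso) against a per-group Euclidean-norm term (α = 0 is the group
lasso), so whole drivers can be selected out as units while coefficients
within a retained driver can still be zeroed individually.  The 1/(2n) loss
scaling makes λ stable across sample sizes; consequently λ values are not
transferable to implementations with other scalings, and every report
records the convention.

The solver is blockwise coordinate descent.  On orthonormalized groups
(X_j'X_j/n = I, the case after pre-processing) each block update is a single
closed-form proximal step — soft-threshold then group-shrink; on general
groups a short monotone FISTA inner loop is used with the per-block
Lipschitz constant.  Convergence is declared when the largest coefficient
change and the KKT subgradient violation both fall below tolerance
(defaults 1e-7 and 1e-4 on a unit-variance outcome; the solver internally
rescales y to unit standard deviation and maps the solution back through the
exact identity β(cy; cλ) = c·β(y; λ), so tolerances are scale-free).
λ_max — the smallest penalty yielding the certified all-zero model — is
found per group by monotone bisection on
‖S(X_j'y/n, αλ)‖₂ = (1−α)λw_j, with closed forms at α ∈ {0, 1}.

## Pre-processing

Missing numeric indices are filled with the training mean, missing flags
with the training mode (ties break to the first declared level); this
mirrors the single mean/mode fill of the source analysis — no multiple
imputation.  Categorical drivers are one-hot encoded with **all** L
indicators (no reference level dropped: centering plus PCA removes the
redundancy and keeps levels symmetric).  Each multi-column group is then
replaced by its principal-component scores, keeping the smallest leading set
of components whose cumulative explained variance reaches `retain`
(default 0.995; `retain=1.0` keeps every positive-variance component;
`retain=None` skips the rotation for the un-pre-processed comparison
condition).  Finally every surviving column is scaled to unit population
standard deviation, which makes |β| comparable between singleton continuous
drivers and multi-component groups — the default comparability convention;
a range-scaling alternative (|β|·column range) is available behind a flag.
The PCA sign ambiguity is fixed by making the largest-magnitude loading
entry positive, so the whole pipeline is bit-reproducible.

Within-group scores are exactly uncorrelated (certified to 1e-8 in tests).
That orthogonality is what justifies the headline statistic: the
**aggregate coefficient** of a driver is Σ|β_i| over its columns, its
**share** is 100·aggregate/Σ(all aggregates), and the predictable /
non-predictable subtotals of shares sum to exactly 100.  On a
non-orthogonalized design the report carries a warning, since summing
absolute coefficients of correlated columns double-counts.

The fitted transform (imputation values, level sets, loadings, scales) is a
frozen object; cross-validation folds each fit their own transform on
training rows only and apply it unchanged to held-out rows, so no held-out
information leaks into the design.  Unseen categorical levels in new data
map to an all-zero indicator block with a warning.

## Penalty selection

k-fold cross-validation (default k = 10; the canonical study below uses
k = 5) over a log-spaced λ grid from λ_max down three decades, per α in a
configurable grid containing 0.15, the grouping strength the source analysis
selected.  `best` is the error-minimizing pair with ties broken toward
larger λ then larger α (the sparser model); `best_1se` is the largest λ
whose mean error is within one standard error of the minimum — the standard
rule when support recovery matters more than the last sliver of predictive
error.

Group weights: `PenaltyConfig` defaults to w_j = 1, the penalty exactly as
written above.  For support recovery the package provides
w_j = √p_j ("sqrt") and w_j = √p_j + √(2 log m) ("concentration").  The
rationale: under pure noise the score norm ‖X_j'ε/n‖ of a p_j-column group
concentrates around σ√p_j — unit weights therefore let *large* null groups
(the 100-level doctor analogs) enter first — while the norm's fluctuations
are O(σ) regardless of p_j, so √p_j weights alone leave *small* calendar
groups leaking at the selection boundary.  The √(2 log m) union-bound term
gives every one of the m groups simultaneous exclusion margin.  Measured on
the synthetic study at n = 5,000, unit weights leave doctor analogs active
with 2–4% shares at the CV optimum; concentration weights plus the 1-SE rule
zero all five null drivers in most runs while keeping every true signal
driver active.

## The synthetic cohort

The confidential single-hospital extract behind the published analysis has
no public accession, so the generator emulates its structure: 24 drivers —
a 617-level casemix (DRG analog) with zipf-like level frequencies, two
100-level doctor analogs, ward/unit groups of 15–25 levels, calendar fields
(7/12/24 levels) carrying **no** true effect, continuous age (mean 53,
sd 24) and two correlated socio-economic indices (ρ = 0.85, missing jointly
in ~0.6% of rows, mirroring missing postcodes), an 11-point ordinal
comorbidity score entered linearly, and binary clinical flags, two of which
(alcohol overuse, obesity analogs) are exact deterministic functions of
subsets of casemix levels — reproducing the exact collinearity that makes
those drivers unestimable by OLS.

Costs are multiplicative: cost = exp(b0 + η + ε) with b0 = 8.3
(≈ $4,000 typical admission), η the sum of per-driver effects (per-level
Normal(0, s) draws for categoricals, fixed indicator coefficients for flags,
z-scored linear terms for continuous/ordinal drivers) and ε log-normal with
dispersion 0.4 by default (a gamma alternative with mean exp(b0 + η) is
provided).  Effect scales were set once to shape the truth like the
published decomposition — casemix strongest (0.35), then age and the
discharging ward/unit, small clinical-flag effects, zero for calendar and
doctor groups.  The generator separates its randomness into a truth stream
(per-level effects, collinear subsets — a function of `config.seed` only)
and a data stream (`data_seed`), so replication studies can redraw cohorts
under one fixed truth.

The ground-truth decomposition (`oracle_report`) projects the noiseless
cost exp(b0 + η) onto the same orthogonalized design by least squares and
aggregates with the shared statistic.  Because the noise is a positive
multiplicative factor with constant mean, E[cost|X] ∝ exp(b0 + η), so these
oracle shares are exactly the population target of the fitted decomposition.

What the generator does **not** emulate: real DRG cost-weight structure,
within-patient correlation across repeat admissions (rows are i.i.d.),
longitudinal drift, or coding error.  Passing recovery tests therefore shows
the pipeline recovers a paper-shaped truth under clean sampling assumptions,
not that a real extract would behave identically.

## The canonical study

`study.run_recovery(seed)` freezes the protocol used by the analysis
scripts and the acceptance script: n = 5,000 admissions, retain = 0.995,
α ∈ {0.15}, 15-point λ grid, k = 5 folds, concentration weights, 1-SE
selection, and a **two-stage (relaxed) share estimate**: the 1-SE fit fixes
which drivers are active, and the coefficients entering the aggregate
report are refit at the error-minimizing λ on the selected groups only.
The two stages answer different questions and need different penalties —
reliable exclusion of null groups requires the heavier 1-SE shrinkage,
which however biases the large signal groups' aggregates down, while an
entirely unpenalized refit over-counts, because summing |β| over a
450-component group accumulates the magnitude of every noise coordinate.
The relaxed refit at the prediction-optimal λ sits between the two and, in
the synthetic study, tracks the oracle subtotals to within a few points.
Problem sizes are scaled for a single-CPU desk run; at this n the 617-level
casemix group has ~8 rows per level, which is the hard regime for support
recovery — the published cohort was ten times larger.

## Inference

Nonparametric pairs bootstrap: rows resampled with replacement, the entire
pipeline (imputation → encoding → PCA → standardization → fit) re-run per
replicate at the fixed selected penalty, percentile intervals per driver
aggregate (B = 200, level 0.95 by default; a `refit_lambda` switch re-runs
CV inside each replicate as a sensitivity analysis).  Post-selection
caveats apply: selection events are resampled as part of the variability,
and percentile intervals around a penalized estimate can under-cover a
truth the penalty biases away from — the coverage experiment in the test
suite therefore evaluates coverage at a lightly-penalized CV choice on a
strong-signal configuration, where the bias is small relative to interval
width.

## Comparison arm

Plain least squares on the identical pre-processed design.  Rank handling:
columns in the span of higher-precedence columns are flagged "not
estimable" (singular-value tolerance 1e-10 relative); precedence scans
groups in descending column count, so a derived flag duplicating casemix
information is the column reported lost, matching how the published table
attributes the failure.  VIFs are 1/(1−R²_k); every column participating in
an exact dependence is flagged infinite (detected from the null space of
the correlation matrix), the rest come from the inverse correlation matrix
restricted to a maximal independent column set, which provably leaves their
regressor span unchanged.  The nonlinearity re-run adds squared terms for
age and the comorbidity score on repeated 10% subsamples and declares
"linearity adequate" when the combined |linear| + |squared| aggregate stays
inside the baseline bootstrap interval in a majority of repeats — a
criterion-based verdict, no p-value.

## Numerical choices and edge cases

- Zero-variance columns (empty levels in a fold) are dropped and recorded;
  a group can vanish entirely and then reports a zero aggregate.
- An all-zero fit is a flagged "null model": shares are undefined rather
  than 0/0.
- Blockwise objective decrease is guaranteed (closed-form prox or monotone
  FISTA), and the recorded objective path is asserted non-increasing.
- The λ_max bisection runs 200 halvings (beyond double precision), so fits
  at exactly λ_max certify KKT to ~1e-12.
- Exact collinearity *across* groups is tolerated by the penalized fit for
  λ > 0; the λ grid floors at 1e-3·λ_max to stay in the well-posed regime.

## Known limitations

- λ values are implementation-specific (loss scaling, standardization);
  only shares and subtotals are comparable across implementations.
- The share statistic attributes variability, not causation; a driver can
  carry share because it proxies an unmeasured cause.
- Bootstrap intervals are percentile-after-selection approximations.
- The default retain = 0.995 is a reproducible stand-in for an unpublished
  retention rule; sensitivity to it is exposed via configuration, and the
  component count per group is recorded in the fitted transform.
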