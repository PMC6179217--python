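# costdrivers

Decomposition of patient-level hospital cost variability into per-driver
contributions, splitting the total into a **predictable (warranted)** part —
attributable to drivers knowable before an admission starts, such as age,
casemix (DRG) group or area socio-economic indices — and a **non-predictable
(potentially unwarranted)** part attached to drivers like the discharging
ward, the attending doctor or the hour of arrival.  The non-predictable
subtotal is an upper bound on waste-related cost variability, the quantity
hospital funders care about.

For analysts of hospital admission extracts: one row per admission, a
declared roster of drivers (continuous, ordinal, binary or categorical, each
flagged predictable or not), and a positive cost outcome.

## Method

Admission records are dummy-encoded into a grouped design (one group per
driver, all L indicators kept per categorical), each multi-column group is
replaced by its principal-component scores (within-group columns become
exactly uncorrelated), and all columns are standardized.  The fit minimizes
the sparse group lasso objective

    (1/2n) ||y − Xβ||² + λ[(1−α) Σ_j w_j ||β^(j)||₂ + α Σ_i |β_i|]

with (λ, α) selected by k-fold cross-validation.  Because within-group
columns are orthogonal, a driver's **aggregate coefficient** Σ|β_i| over its
columns is a faithful summary of its pull on cost variability; its **share**
is the aggregate as a percentage of the sum over all drivers.  Shares and
the predictable/non-predictable subtotals sum to exactly 100.  An
unpenalized OLS arm on the identical design (with VIF diagnostics and
exact-collinearity detection) shows what goes wrong without the penalty, and
a pairs bootstrap supplies percentile intervals per aggregate.

The confidential hospital extract behind the original analysis has no public
accession, so the package ships a synthetic-admissions generator with the
same statistical anatomy (617-level casemix analog, 100-level doctor
analogs, null calendar fields, skewed costs, sparse missingness, exact
casemix-derived collinear flags) plus the ground truth needed for recovery
testing.

## Worked example

```sh
python analysis/01_generate_cohort.py --n 5000 --seed 0
python analysis/02_select_penalty.py
python analysis/03_decompose_variability.py
python analysis/04_compare_ols.py
```

Script 01 prints, for seed 0:

```
wrote 5000 admissions to results/cohort
cost: median 3868, mean 5483, skew 3.67 (right-skewed as hospital costs are)
missing index rows: 31 (both indices missing together)
oracle non-predictable share of the noiseless signal: 31.8%
```

and script 03, after cross-validating the penalty and bootstrap intervals:

```
fit: converged=True, KKT violation 6.5e-07, active drivers 10/24
predictable (warranted) share:      71.4%
non-predictable share (upper bound on unwarranted): 28.6%
```

Read: the fitted decomposition keeps the true cost drivers (casemix, age,
indices, wards, units), zeroes the calendar and doctor analogs, and puts the
non-predictable subtotal within a few points of the generator's oracle value
(31.8% here).  Script 04 prints the comparison arm:

```
mean VIF on the fitted design: 1.07 (587 columns exactly collinear)
not estimated under OLS (exact collinearity): ['alcohol_overuse', 'obesity']
casemix share: OLS 58.1% vs penalized 61.4%
```

— the two casemix-derived flags cannot be estimated by OLS (the penalized
fit stays finite and KKT-certified), and the accompanying lambda-path table
shows the casemix share falling as the penalty grows, the signature of a
group of many thin coefficients.

The same pipeline runs on any CSV + roster via the `costdrivers` CLI
(`generate`, `preprocess`, `cv`, `fit`, `bootstrap`, `compare`, `run-all`).

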