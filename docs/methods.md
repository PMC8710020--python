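# Methods

## The quantification model

The analysis treats segmented mIHC data as a marked point pattern: each
cell has a position (µm, per-core frame with origin at the bounding-box
corner), one intensity per channel, and — after gating — a phenotype,
receptor statuses and a compartment. A TMA core is a disc containing a
CK-positive tumor region; the compartment rule is purely geometric
(centroid inside or on the boundary of any tumor polygon → tumoral),
because segmented-cell tables carry no better notion of membership than
the centroid. Densities are counts divided by the matching compartment
area in mm² (1 mm² = 10⁶ µm²). "Total" ("tumoral and stromal") densities
divide by the whole core area; this is the only convention under which
counts and areas are simultaneously additive across the three levels, and
it is used consistently.

## Thresholding

Positivity cut-offs per channel come from a two-component Gaussian mixture
on log-intensity (EM, 10 seeded random restarts, tolerance 1e-8, ≥ 50
positive finite values required). The returned threshold is the intensity
where posterior membership in the two components is 0.5, found by bisection
between the component means; a manual entry point bypasses the fit. The
fit fails loudly (a `ThresholdUnderivableError`) on zero-variance input or
collapsed components rather than returning an arbitrary split — the caller
must then supply a manual value. Positivity is *strict* (> threshold): the
tie direction is arbitrary but must be fixed, and strict inequality makes
"all-zero channel, positive threshold" uniformly negative.

## Phenotyping cascade

The lineage table (T: CD45+CD3+CD20−; B: CD45+CD3−CD20+; CD57+ NK:
CD45+CD3−CD20−CD57+; macrophage: CD45+CD3−CD20−CD57−CD68+) is evaluated as
an ordered cascade (CD3 → CD20 → CD57 → CD68) on CD45+ cells. The profiles
are mutually exclusive only when evaluated in this order; double-positive
profiles outside the table (e.g. CD3+CD20+, or CD57+CD68+ without CD3/CD20)
are resolved by cascade order and flagged `ambiguous_lineage`, never
dropped. CD57 on a T cell is a legitimate subset, not a conflict. SMA and
Ki-67 are read and stored but play no role in gating — the panel stains
them without defining a lineage rule on them. HLA-E positivity on tumor
cells uses the same thresholding machinery as the immune channels.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline assumes:

- **Scale**: 55 patients, one core per patient (1.2 mm discs), ~4,000
  cells per core (Poisson). The default per-core cell count is chosen so
  that immune densities land near the reported cohort medians
  (≈ 1,800 CD45+ cells/mm²) at a 50% immune fraction; tests and the
  bundled experiments override it downward where a smaller core suffices.
- **Composition**: CD45+ cells split T 65.5%, macrophage 25.4%, B 5.3%,
  CD57+ NK 3.8%; 23.2% of T cells are CD57+, which makes NK cells 20.0% of
  CD45+CD57+ lymphocytes. Receptor rates: CD16 on 55.1% of T and 59.3% of
  NK cells; NKG2A on 27.9% of T and 14.8% of NK cells. B-cell and
  macrophage receptor rates are not reported per-phenotype and are set to
  plausible defaults (B: 5%/2%; macrophage: 40%/5% — FcγRIII is common on
  macrophages, NKG2A essentially lymphoid).
- **Intensities**: two-component log-normal per channel (negative location
  e⁰ = 1, positive e³ ≈ 20, scale 0.35 on the log scale) — strictly
  positive, right-skewed and clearly bimodal, as IHC intensity
  distributions are when a marker separates well.
- **Geometry**: the tumor region is a union of 1–5 random convex blobs,
  each grown about its own centroid until the covered area hits the target
  tumor fraction within 2% (growth about the blob centroid keeps covered
  area monotone in the scale factor, so bisection converges). Cells are
  uniform over the disc; CK+ tumor cells arise only inside the region.
- **HLA-E**: the per-core HLA-E+ tumor-cell rate follows a logistic link
  to the core's intratumoral T/B/macrophage densities (coefficient 0 for
  NK), anchored at the reported median densities — reproducing the
  observed pattern that HLA-E tracks T cells, B cells and macrophages but
  not CD57+ NK cells.
- **Survival**: exponential (optionally Weibull) proportional hazards with
  baseline ln 2 / 85.4 per month (median OS ≈ 85.4 months), follow-up
  horizon 108 months, exponential censoring hazard 0.006/month (≈ 40–45%
  observed events, near the cohort's 38% deaths / 42% progressions).
  Default log-hazard coefficients: +0.5 per SD of tumoral NK density,
  −0.3 per SD of total T and macrophage density — the direction of the
  reported prognostic findings. PFS is OS minus an exponential gap
  (mean 20 months ≈ the gap between the reported median OS and PFS)
  truncated at zero, guaranteeing PFS ≤ OS without modeling disease states.
- **Clinical covariates**: molecular subtype drawn at the reported
  frequencies (4/7/21/4/19 of 55), with MSI marker flags, EBV, E-cadherin
  and p53 fields generated so the classification cascade recovers the
  drawn subtype exactly; stage III at 41/55.

Not emulated: spatial clustering (placement is uniform), cell shapes,
stain spillover, between-case composition heterogeneity (per the default;
the per-core Poisson/binomial noise is the only source of variation), and
multi-core patients. Passing recovery tests therefore show the *pipeline*
is correct under the assumed data model — not that real tissue satisfies
that model.

Truth labels live in separate columns/files (`truth_cells.csv`,
`truth_patients.csv`) that no pipeline stage reads, so recovery tests
cannot leak. Randomness is split per (core, channel) by counter-based
`SeedSequence` spawn keys: output is deterministic under the master seed
and independent of generation order.

## Statistics

Spearman correlation uses mid-rank Pearson with the t-approximation for p
(n−2 df), the standard choice at n ≈ 55; an exact-permutation option
exists for n ≤ 10 and is used for oracle checks. Group comparisons use
Welch's unequal-variance t-test. Densities enter tests untransformed by
default (a log1p option exists); no multiplicity adjustment is applied
anywhere, matching the screening character of the analysis — the
selection-induced inflation of the cutpoint screen is measured by the null
simulations in the test suite instead of corrected.

## Survival machinery

Kaplan–Meier, log-rank, the maximally selected rank statistic and
univariate Cox regression are implemented from first principles:

- **Cox**: Newton–Raphson on the scalar partial likelihood (tolerance
  1e-9 on the step, max 50 iterations, step-halving safeguard), Efron tie
  handling by default with Breslow for cross-checks; SE from observed
  information; Wald CI/p. Constant covariates raise a singular error;
  monotone likelihoods (perfect separation) raise a convergence error that
  reports the direction of divergence. The score test at β = 0 is exposed
  because it reproduces the log-rank chi-square for a binary covariate on
  tie-free data — a classical identity the tests verify to 1e-6.
- **Cutpoint search**: every distinct observed covariate value leaving at
  least ⌈minprop·n⌉ subjects on each side (minprop defaults to 0.1, the
  conventional default of maximally-selected-rank-statistics software) is
  scored by the standardized log-rank statistic of {> c} vs {≤ c}; the
  maximizing |z| wins, ties broken toward the smallest cutpoint. The
  vectorized search is verified to agree *exactly* with a brute-force scan
  that calls the log-rank test per split.
- **Screen**: high = value > cutpoint (the same strict-inequality
  convention as gating); per-combination failures (constant covariate, no
  admissible cutpoint, separation) are recorded per row and never abort
  the screen; patients missing a covariate are dropped pairwise for that
  combination only. A secondary continuous mode fits per-unit Cox models
  without dichotomization, since forest-style reports do not always state
  which of the two was used.

## Numerical choices and degenerate inputs

Zero-area compartments with nonzero counts raise a geometry error; with
zero counts the density is reported missing (NaN), as are composition
fractions with empty denominators — never silently 0. Survival times are
floored at 0.01 months (the generator's resolution) except under a zero
follow-up horizon, where everything is censored at 0 by construction.
Log-rank variance terms with a single subject at risk contribute 0. The
mixture threshold is searched only between the two component means; a fit
whose posterior never crosses 0.5 there is treated as underivable.

## Problem sizes used by the bundled experiments

The composition-recovery experiment pools 210,000 cells (≥ 100,000 CD45+)
— large enough that three binomial standard errors on the rarest class
(NK, 3.8%) are ±0.18 percentage points. Oracle-equivalence checks use 50
datasets of n = 60; Cox recovery uses n = 2,000; the survival-screen
direction experiment uses 50 replicate 55-patient cohorts at 300 cells
per core (the covariate under test is the realized tumoral NK density, so
the smaller core count adds covariate spread without changing the model);
calibration checks use 1,000 null replicates each.
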