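# Methods

## Model and procedure

The response is the drug-loading capacity LC (% w/w) of polymeric micelles,
modeled on the natural-log scale: ln(LC) is closer to Gaussian and keeps
predictions positive after back-transformation. The model class is multiple
linear regression on a small subset of molecular descriptors,

ln(LC) = b₀ + Σₖ bₖ xₖ + ε,

fitted by QR-based ordinary least squares. Rank-deficient designs raise an
error rather than falling back to a pseudo-inverse: in a 22-sample study a
silently degenerate fit is worse than no fit.

### Descriptor pre-reduction

Before any model selection, columns are removed that cannot carry
information: exactly constant columns; near-constant columns (sample
sd < 1e-8·(1+|mean|), or more than 95% identical values — the literature
rarely quantifies "near-constant", so the rule is declared and logged); and
one member of every pair with |Pearson r| > 0.99. Correlated pairs are
visited by descending |r| and the member with the larger mean absolute
correlation to all remaining columns is dropped (tie → later column), which
makes the filter deterministic and idempotent. Descriptors are standardized
column-wise by mean and sample standard deviation (ddof = 1, the convention
of mainstream statistics software).

### Duplex splitting

Training and test sets must both span descriptor space. The Duplex rule:
the globally furthest pair (Euclidean, on standardized descriptors) seeds
the training set; the furthest pair of the remainder seeds the test set;
remaining samples are assigned alternately (training first), each time
taking the sample with the largest summed distance to the receiving set's
current members. "Furthest from the selected points" is ambiguous between
max-sum and max-min; max-sum is used because it matches the description of
the seeding steps and remains stable as the sets grow. Once either set
reaches its target size (test: n_test; training: n − n_test), the rest go
to the other set. All ties break toward the lowest sample index, so splits
are reproducible.

### GFA subset selection

The genetic function approximation evolves a population of fixed-size
descriptor subsets. Fitness is Friedman's revised lack-of-fit of the
subset's OLS fit,

LOF = (SSE/n) / [1 − λ(c + d·p)/n]²,

with c = p = subset size for purely linear terms, smoothness d = 0.5,
λ = 0.99 (guards the denominator). At fixed size, LOF is monotone in SSE;
across sizes it penalizes larger models. d is applied literally as written
above; some commercial implementations internally rescale their smoothness
parameter, which is why published model lists are not expected to be
bit-reproducible (see Limitations).

Genetic operators, chosen where the method description is silent:

- **Selection**: tournament of size 2 (standard, mild selection pressure).
- **Crossover**: uniform set-crossover — genes carried by *both* parents are
  always inherited; the child's remaining slots are sampled uniformly
  without replacement from the parents' symmetric difference. Sampling all
  k genes from the plain union instead would drop a shared gene with
  probability ≈ 1 − k/|union|; measured on the default simulation this
  prevents the population from ever converging (planted-subset recovery
  40–85% instead of 20/20), so the heritability-preserving form is used.
- **Mutation**: each gene independently with probability 0.1 is replaced by
  a uniformly random descriptor not currently in the chromosome.
- **Survival**: generational replacement with one elite copy, so the best
  LOF is non-increasing.
- Chromosomes are fixed-length descriptor sets; spline/quadratic terms are
  out of scope (the models of interest are linear with a fixed term count).

Fitness values are cached by descriptor set (results are identical with or
without the cache), and the returned top-N distinct models are re-fitted
through the public OLS path. A single seeded generator owns all randomness.

The published settings are population 1000 × 5000 generations; they remain
the defaults of `GfaConfig`. The analysis scripts, tests and the acceptance
script run population 60 × 40 generations: on the default simulated study
(36 descriptors, subset size 5) that scale already recovers the planted
subset in 20/20 seeded runs in ~0.1 s per run, so the larger budget buys
nothing on these problem sizes.

### Validation battery

- R² with an explicit reference mean (the training mean) in the
  denominator; R²cv by leave-one-out, computed with the exact hat-matrix
  identity ŷ₋ᵢ = yᵢ − eᵢ/(1−hᵢᵢ) — algebraically identical to n refits,
  verified against a brute-force refit oracle in the tests.
- RMSE (population form, divide by n); F = (R²/p)/((1−R²)/(n−p−1)).
- External R²pred keeps the *training* mean in its denominator: a test set
  predicted no better than the training mean scores 0.
- Roy's metrics: r² is the squared Pearson correlation of observed and
  predicted test values; r0² comes from regressing observed on predicted
  through the origin (r′0² with axes swapped); rm² = r²(1 − √(r² − r0²)).
  Literature conventions differ on which axis is constrained, so the
  convention is recorded in every report. A numerically negative radicand
  is clamped to zero with a warning.
- Y-randomization permutes the response (Fisher–Yates from the run's seeded
  stream), refits the *same* descriptor subset — descriptor selection is not
  rerun, as the descriptor matrix is held fixed — and averages R² and R²cv
  over 500 rounds by default. The reliability verdict requires both means
  below 0.5. Under exchangeable noise the refit null mean R² is p/(n−1)
  (≈ 0.238 at p = 5, n = 22), which the tests confirm at 5000 iterations;
  published Y-randomization means far below that value would indicate a
  different (unspecified) scrambling variant, so the 0.5 threshold — not any
  particular printed mean — is the binding check.

### Applicability domain

Leverage of a query sample against the training design (intercept column
included): h_i = x_i(XᵀX)⁻¹x_iᵀ, computed via a factorized solve and checked
against the explicit-inverse formula in tests. Warning leverage
h* = 3(p+1)/n. The residual axis of the Williams table standardizes
training LOO residuals by their own sample sd and test residuals by the
training RMSE (the literature does not fix this choice; it is stated in
every report), with the domain bounded at ±3 units. Leverage is computed on
whichever descriptor scale the model was fitted on.

### Interpretation

Segment–descriptor Pearson correlations (including composite segments such
as PCL+PDEA) connect descriptors to monomer chemistry. Monomer
contributions are ratio-of-ratios: C = (value/basis)/(value_ref/basis_ref)
with a chosen reference monomer, so the reference row is identically 1 and
the table is invariant to global rescaling of values or bases — any
consistent per-monomer accounting yields the same contributions.

## Synthetic study generator

`SyntheticSpec` defaults emulate the study design: 30 formulations (15
polymers × drug/polymer feed ratios 10/40 and 20/40), 36 descriptors drawn
from a correlated Gaussian — signal columns independent (identifiability of
the planted subset), filler columns in equicorrelated blocks of (4, r=0.7)
and (3, r=0.5) mimicking co-varying surface/energy descriptors — with
marginals standardized by construction. The ln-scale response is a planted
five-descriptor model (coefficients −1.953, 1.101, 0.339, 0.320, 0.525,
intercept 2.548; names SSOV, SSA, EV, TPE, IE) plus Gaussian noise of sd
0.07, matching the magnitude of a realistic training RMSE on this response;
the stored LC column is its exponential so the ln-transform step is
exercised end to end. Optional near-duplicate columns (r > 0.99) exercise
pre-reduction. Ground truth travels in table metadata.

What the simulation does **not** emulate: real descriptor physics (the
planted signal columns are mutually independent, whereas real surface/volume
descriptors co-vary with the response drivers), measurement error in LC, and
the discrete design structure linking the two feed ratios of one polymer.
Passing tests therefore demonstrate that the pipeline recovers a known
ground truth under the assumed noise model — not that five descriptors
suffice for any particular real chemistry.

A loader for a hand-transcribed copy of the original study's data tables is
provided; tests that need those values skip when no transcription is
present.

## Numerical choices

- Sample sd (ddof = 1) everywhere a standard deviation appears.
- QR factorization for all least-squares solves; rank tolerance
  1e-10 × largest |R| diagonal.
- LOO via the hat identity; folds with hᵢᵢ ≥ 1 − 1e-12 raise.
- Standardized-residual guard: an essentially exact fit (residual sd below
  1e-10 relative to the response scale) reports zero standardized residuals
  rather than amplifying round-off.
- Exact-fit coefficient inference (zero residual variance) is flagged
  degenerate and warned about, with zero standard errors.
- Standardized coefficients use B·sd(x)/sd(y); with standardized predictors
  this is bounded by construction in magnitude near 1 — conventions that
  produce larger magnitudes exist in commercial software but are not
  identifiable, so the standard one is used.

## Problem sizes

Defaults used by the analysis scripts, tests and the acceptance script:
n = 30 samples (22 training / 8 test), 36 descriptors, subset size 5, GFA
population 60 × 40 generations, Y-randomization 500 rounds (5000 for the
null-mean check), 20 seeded runs for the recovery and exhaustive-agreement
rates. These sizes reproduce the study's design scale; larger GFA budgets
change nothing on problems of this size.

## Known limitations

- The exact ten-model list of any particular GFA implementation is not
  reproducible: selection/crossover internals and smoothness rescaling of
  commercial tools are proprietary. The package's contract is that its own
  search equals exhaustive enumeration on enumerable instances and recovers
  planted truth under the simulated conditions.
- The Duplex max-sum rule is one of two defensible readings of "furthest
  from the selected points"; the max-min variant can produce different (also
  defensible) splits.
- Y-randomization verdicts use the 0.5 threshold; the test's power at
  n = 22, p = 5 is limited since the refit null mean R² is already ≈ 0.24.
- Leverage-based domains assume approximately Gaussian descriptor clouds;
  strongly clustered designs can hide extrapolation at low leverage.
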