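# micelle-qspr

Quantitative structure–property relationship (QSPR) modeling of the
drug-loading capacity of polymeric micelles.

Amphiphilic star polymers (caprolactone / PDEA / PEGMA block arms)
self-assemble into nano-micelles that carry poorly soluble anticancer drugs
such as doxorubicin. Which polymer loads the most drug is expensive to
determine experimentally; this package builds regression models that predict
the drug-loading capacity (LC, % w/w) from computed molecular descriptors of
the polymer, and quantifies how far those models can be trusted.

The workflow, end to end:

1. **Pre-reduction** — drop constant, near-constant and pairwise-correlated
   (|r| > 0.99) descriptor columns; ln-transform LC; Mean/SD-standardize.
2. **Duplex splitting** — partition formulations into representative
   training and test sets by alternately assigning the most mutually distant
   samples (Euclidean metric in descriptor space).
3. **GFA model search** — a genetic algorithm evolves a population of
   fixed-size descriptor subsets; each subset's OLS fit is scored by
   Friedman's lack-of-fit

   LOF = (SSE/n) / [1 − λ(c + d·p)/n]²,

   which penalizes model size (c terms, p descriptors, smoothness d,
   safety factor λ) so that lower LOF balances accuracy against complexity.
4. **Validation battery** — internal: R², leave-one-out R²cv, RMSE, F;
   external: R²pred (training-mean reference), test RMSE, Roy's
   r̄m²/Δrm² from through-origin regressions; robustness: Y-randomization
   (refit on scrambled responses; both mean R² and mean R²cv must stay
   below 0.5).
5. **Applicability domain** — leverage h_i = x_i(XᵀX)⁻¹x_iᵀ against the
   warning value h* = 3(p+1)/n and standardized cross-validated residuals
   within ±3 (Williams plot).
6. **Interpretation** — monomer-segment/descriptor correlations and
   per-monomer contribution ratios against a reference monomer.

A synthetic-data module simulates the study design (15 polymers × 2
drug/polymer feed ratios, 36 standardized descriptors with correlated
blocks, ln-scale response from a planted 5-descriptor model), so every stage
is testable without proprietary descriptor software.

## Worked example

Run the numbered analysis scripts from the repository root:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess_split.py
python analysis/03_subset_size_sweep.py
python analysis/04_gfa_models.py
python analysis/05_validate_models.py
python analysis/06_applicability_domain.py
python analysis/07_interpretation.py
```

The subset-size sweep prints (simulated study, seed 2026):

```
 size       r2     r2cv
    1 0.619324 0.537502
    2 0.929013 0.908478
    3 0.964752 0.942922
    4 0.981870 0.966513
    5 0.999515 0.999113
    6 0.999630 0.999159
    7 0.999740 0.999299
recommended subset size: 5 (R2cv stops improving beyond it)
```

R²cv — the leave-one-out estimate of predictive ability — stops improving
once five descriptors are in the model, so five is the recommended subset
size; exactly the five planted signal descriptors are then selected:

```
best model: SSOV, SSA, EV, TPE, IE (LOF 0.006372, R2 1.000)
```

with coefficient estimates within confidence intervals of the planted
values (e.g. SSOV −1.9405 ± 0.034 vs planted −1.953). The validation table
ranks the ten best models; model 1 is best on every criterion, its
Y-randomization means (R² 0.233, R²cv −0.489) stay far below 0.5, and the
Williams table places all 30 formulations inside the applicability domain
(h* = 0.8182, residuals within ±3).

The same steps are available as subcommands of the `micelle-qspr` console
script (`simulate`, `prereduce`, `split`, `gfa`, `validate`, `ad`,
`run-all`), and `micelle_qspr.pipeline.run_all` drives the whole workflow
from one config with a single seed.

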