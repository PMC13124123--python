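# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `feedeff`.

## Models

All six analyses are linear mixed models solved through Henderson's
mixed-model equations (MME).  For a trait vector y (univariate or the
five-trait stack),

    y = X b + Σ_j Z_j u_j + e,   u_j ~ N(0, K_j ⊗ V_j),   e ~ N(0, ⊕_i R_p(i)),

the equations are C s = r with C = W'ΩW + ⊕_j (K_j⁻¹ ⊗ V_j⁻¹), W = [X Z] and
Ω the inverse residual covariance, block-diagonal with one block per record.
Residual variances are heterogeneous over five lactation-period classes
(weeks 1–4, 5–9, 10–13, 14–35, 36–44, approximating lactation months 1, 2, 3,
4–8 and 9–11; configurable).

The six specifications:

| name | response | fixed | random |
|---|---|---|---|
| `refi_rdc`, `refi_nrc2021` | DMI | eDMI regression nested in herd×year (HPY) | eDMI slopes for test group (HTM), permanent environment (pe), additive genetic (a) |
| `rfi` | DMI | ECM, MBW, BWL, BWG covariates + HPY classes | HTM, pe, a intercepts |
| `ece` | ECE | lactation-week classes + HPY classes | HTM, pe, a intercepts |
| `multitrait` | DMI, ECM, MBW, BWL, BWG | 4th-order Legendre lactation curve nested in herd + HPY | HTM, pe, a intercepts with 5×5 covariances |

Deliberate modelling points:

* The ReFI models have **no general intercept and no lactation-curve fixed
  effect** — every design column is the eDMI covariate.  This is unusual but
  intentional: the fixed per-HPY regression absorbs level differences, and an
  animal's genetic slope deviation is its efficiency.  A slope of the additive
  effect is a per-unit-eDMI quantity; for reporting and cross-metric
  comparison, breeding values and variance components are rescaled by the
  data-mean eDMI (so VarG_slope × mean(eDMI)² is on the kg² intake scale and
  can be combined with the intake-scale residual variance in heritability).
* HTM is a random **slope** in the ReFI models and a random **intercept**
  elsewhere.
* Fixed-effect identifiability is handled by explicit constraints: the ECE
  model drops the first HPY level (lactation-week classes span the
  intercept), the multi-trait model drops the first HPY level within each
  herd (the herd-nested Legendre P0 column is a herd intercept).  Constrained
  equations are pinned to zero inside the assembled system; the one-step RFI
  and ReFI models are full rank as specified and get no constraints.
* The expected intake reported from the one-step RFI fit (`edmi_fit`) is the
  fitted fixed part — energy-sink regression plus the HPY level — because the
  model has no global intercept and HPY carries the intake level.

Solving: sparse LU factorisation up to 60,000 equations (all shipped analyses
are far below this), Jacobi-preconditioned conjugate gradients beyond, with a
post-solve residual check (‖Cs − r‖/‖r‖ < 1e-6 enforced, typically ≲1e-12 for
the direct path).

## Relationship kernels

* `tabular_A` builds Wright's numerator relationships; diagonals are 1 + F.
* `a_inverse` builds the sparse inverse directly by Henderson's rules with
  inbreeding coefficients from the Meuwissen–Luo recursion.  Inbreeding is
  always accounted for: selected nucleus pedigrees are inbred, and ignoring F
  biases the Mendelian-sampling weights.  Unknown-parent groups
  (Quaas–Pollak absorption, equal-width birth-year bins within origin,
  boundary years to the earlier bin) are available but off by default; they
  are not supported inside EM-REML.
* `vanraden_G` is method 1, G* = ZZ′/(2Σp(1−p)), with allele frequencies
  computed from the observed genotyped animals (base-population frequencies
  are not available without real data).  G = 0.9·G* + 0.1·A22 guarantees
  invertibility; no further compatibility tuning of G to A22 is applied.
* `h_inverse` adds the dense G⁻¹ − A22⁻¹ correction onto the genotyped block
  of the sparse A⁻¹.  Dense inversion of G and A22 is acceptable at the
  scales involved (≈1,500 genotyped animals in a real dataset of this kind).

## EM-REML

Variance components are estimated by expectation–maximisation REML on the
MME.  The updates are the classical ones; the trace terms are computed
**exactly** from a dense inverse of the coefficient matrix rather than by
Monte-Carlo trace sampling — at a few thousand equations a dense
factorisation per sweep is cheap, and the estimating equations are identical.
Components are estimated under the pedigree kernel, the usual choice when the
same components are then used for single-step prediction.

Numerical choices:

* convergence when the global relative parameter change
  ‖θ_new − θ_old‖/‖θ_new‖ falls below `tol` (default 1e-6, max 500 sweeps; the
  shipped analyses use 1e-3, which changes recovered heritabilities by ≪0.01);
  a component collapsing to zero therefore cannot stall convergence,
* variances floored at 1e-10 × the phenotypic variance with a boundary flag,
* the restricted log-likelihood is evaluated every sweep and is
  non-decreasing (monitored in the tests),
* the five-trait EM is exposed at reduced synthetic scale only (guarded at
  8,000 equations): a dense inverse of the full-scale multi-trait system is
  disproportionate, and no published component values exist to recover.

Heritability is VarG/(VarPE + VarG + VarR̄) with VarR̄ the record-count
weighted average of the period residual variances; repeatability adds VarPE
to the numerator.  The HTM (contemporary-group) variance is excluded from the
phenotypic total, as is conventional for these models.  Standard errors use
the first-order delta method given a covariance of the component estimates.

## Synthetic herd generator

No public dataset contains weekly DMI with milk composition, body weight and
condition on a genotyped nucleus pedigree, so the generator emulates one.
Defaults (the emulated study conditions): 264 founders, two descendant
generations with three offspring per mating → 792 recorded cows with 28
weekly records each (22,176 records) in 4 herds over a ~24-year window;
~55 % of cows plus all founder sires genotyped at 1,000 unlinked SNPs
(founder MAF uniform on [0.05, 0.5], gene-dropped without linkage).

Generative structure:

* Energy sinks (ECM, MBW, latent daily BW change dBW, BCS) are multivariate:
  trait mean + lactation-stage curve (a Legendre-basis curve, so the
  multi-trait model's fixed regression can absorb it exactly) + HPY + HTM +
  pe + additive genetic + residual.  BWL/BWG are the sign split of dBW, so
  one is structurally zero in every record, and records in early lactation
  are predominantly losses.
* DMI = (α_HPY + β_HTM + pe_i + a_i) · eDMI(sinks) + e, with α_HPY ~ N(1,
  0.05²) and the efficiency components (β, pe, a) on the regression-slope
  scale — the ReFI structural assumption holds by construction, and the
  one-step RFI model sees intake-scale components ≈ slope components ×
  mean(eDMI)².  Generating slope components default to pe 0.00333, genetic
  0.00303 and a weighted-average residual of 2.502 kg² (pattern 1.20 : 1.10 :
  1.05 : 0.92 : 0.85 over the five periods), i.e. an intake-scale h² ≈ 0.24.
  The HTM slope variance (4e-4) is the package's own choice — small against
  the cow-level components, as a test-group feeding effect should be.
* MEI = DMI × dietary energy density (10.94 MJ ME/kg DM).  Milk composition
  is drawn around 44.3/36.3/45.0 g/kg (fat/protein/lactose) and milk yield is
  back-calculated so that the ECM formula reproduces the generated ECM
  exactly; BW = MBW^(4/3) likewise.  All derived columns in the emitted table
  come from the same `derive_columns` code path users run on real data.
* The 4×4 sink covariances per effect level are the package's own defaults
  (no published decomposition exists): marginal SDs ≈ observed phenotypic
  SDs, split 25 % genetic / 20 % pe / 5 % HTM / 50 % residual, moderate
  correlations.  Acceptance checks do not depend on these values beyond sign
  conventions.
* One seed fans out (`SeedSequence.spawn`) into independent streams for
  pedigree, gene drop, breeding values, records and genotyping status, so the
  whole study is reproducible and each stage independently so.
* Breeding values descend the pedigree as parent average + Mendelian
  sampling with variance V_a/2 by default; the inbreeding-adjusted
  d_i = ½ − (F_s + F_d)/4 is available behind a flag (synthetic pedigrees are
  shallow, so the correction is ~zero; real selected pedigrees are not).
* Optional pasture-gap emulation removes summer test weeks for
  autumn-calving cows (off by default).

What the generator does **not** emulate: selection or assortative mating in
the nucleus, linkage/LD between SNPs, lactation-curve shapes beyond the
fourth-order Legendre family, measurement error in sink recording, and the
multiplicative mean–variance coupling of real intake data.  Passing tests
therefore demonstrate internal consistency of the estimation machinery under
the stated generative model, not robustness to the many ways real data
violate it.

## Validation pipeline

`split_forward` removes the records of genotyped animals born at or after a
cutoff (and of their daughters) to form the reduced dataset; those animals
form the validation group.  `lr_validation` regresses full-data on
reduced-data (G)EBVs over the group by OLS — bias b₀, dispersion b₁,
accuracy = Pearson correlation — with ordinary nonparametric bootstrap SEs
over animals (default 1,000 resamples, seeded; resamples with zero variance
are skipped).  Granddaughters are not excluded (daughters only).  Adjusted
benchmark phenotypes subtract every fitted effect except the additive genetic
one and average within cow.  `run_comparison` orchestrates all six metrics ×
{pedigree, single-step} × {full, reduced}.

The working variance components used for BLUP inside `run_comparison` default
to the generator's truth for the ReFI/RFI models and to generator-implied
approximations for ECE and the multi-trait model (a linear lift of the sink
covariances with BWL/BWG ≈ ∓dBW/2 and a 10 % diagonal inflation to keep the
5×5 matrices positive definite despite the structural BWL/BWG
anticorrelation).  BLUP with approximate components remains a valid
predictor; only its shrinkage is mildly suboptimal.

## Problem sizes

The shipped analyses use two scales, chosen as the package's own defaults:
the full emulated study (792 cows × 28 weeks, ≈2,900 mixed-model equations
for the univariate models) for single-run parameter recovery, and a reduced
study (≈190 cows × 10 weeks) for replicated checks (LR calibration over 30
replicates, genomic-gain comparisons over 20).  One EM-REML sweep at full
scale costs one dense factorisation + inversion of the ≈2,900-equation
system, ≈2 s on one core; a full recovery run converges in ≈60 sweeps.

## Known limitations

* EM-REML convergence is first-order; near-boundary components converge
  slowly (mitigated by the global convergence norm and the variance floor).
* No reliabilities/prediction-error variances from the MME inverse; the
  bootstrap covers the validation statistics instead.
* Unknown-parent groups are not propagated into the genomic H⁻¹ by default,
  and no metafounder formulation is provided.
* The NRC 2021 intake equation is implemented in its published first-parity
  form with the whole-bracket days-in-milk multiplier; its typographic
  parenthesisation is ambiguous in secondary sources, and the alternative
  (multiplier on the BCS term only) is not offered.
* Milk contents are g/kg throughout; percentage inputs must be ×10 at
  ingestion (only g/kg makes the ECM formula return ECM ≈ milk yield).
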