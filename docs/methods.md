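# Methods

## Model

The package models the covariate-specific ROC curve of a continuous
diagnostic marker directly, rather than modelling the marker and deriving
the ROC. With q the false-positive rate and Φ the standard normal CDF,

    ROC(q | x) = Φ( α₁ + α₂ Φ⁻¹(q) + βᵀx ).

α₁ and α₂ are the binormal intercept and slope; β shifts the whole curve up
or down with the diseased subject's covariates. A positive coefficient
means the covariate improves discrimination; a negative one degrades it.
The model implies the closed-form covariate-specific AUROC
Φ((α₁ + βᵀx)/√(1 + α₂²)), which the code cross-checks against Gauss–
Legendre quadrature of the curve (agreement ≤ 1e-6 is a tested invariant).

Assumptions worth stating explicitly:

- **Binormal shape.** The probit link and linear Φ⁻¹(q) term assume the
  oriented marker is (transformable to) Gaussian within each group.
- **Covariates act on cases only.** The control (reference) distribution is
  the pooled empirical control sample; covariates are not used to adjust
  controls. This mirrors a design in which healthy eyes define a common
  reference and severity/geometry covariates are attributes of disease.
- **α₂ > 0** is required for a proper (non-crossing) ROC; the fit warns if
  the estimate is non-positive and `auc` refuses to evaluate.

## Estimation

Estimation follows the Alonzo–Pepe placement-value construction:

1. Orient the marker so larger = more diseased (OCT thicknesses are
   negated; `MarkerSpec.direction` controls this).
2. Placement value of case i: `pv_i = #{controls ≥ case_i} / n₀`. Ties are
   counted inclusively by default — a control equal to the case counts as
   at least as diseased — which is deterministic and conservative; a
   `strict` rule is available as a configuration switch.
3. Expand indicators `u_ij = 1{pv_i ≤ q_j}` over a grid of false-positive
   rates and regress u on `[1, Φ⁻¹(q_j), x_i]` by maximum-likelihood
   probit.

The FPR grid defaults to m = 100 midpoints q_j = (2j−1)/200: uniform over
(0, 1) and bounded away from the probit singularities at 0 and 1.
Covariates enter on their raw clinical scales (percent, years, diopters,
mm, mm²), uncentered, so intercepts are directly comparable to published
coefficient tables.

The probit solver is a vectorized Newton–Raphson iteration with step
halving (`_probit.py`), converging on the max-norm of the step at 1e-9
within 100 iterations. It exists because bootstrap and simulation studies
refit the same moderate-sized model thousands of times; a unit test pins
its agreement with `statsmodels` GLM (probit link) to below 1e-6.
Degenerate indicator sets (all 0/all 1, e.g. a constant marker) and
quasi-complete separation (|linear predictor| > 8 with diverging steps)
raise a warning and return the last stable iterate flagged unconverged;
genuine non-convergence is an error carrying the last iterate.

### Inference

Indicators within a case are correlated by construction, so the working
probit covariance is invalid; it is stored but labelled as such. Reported
inference is a stratified bootstrap: cases (with their covariate rows) and
controls resampled with replacement separately, the model refitted per
replicate, percentile 95% intervals, and two-sided p-values from a normal
approximation with the bootstrap SE. Replicates that fail to converge are
dropped; more than 10% failing aborts. Every stochastic stage (eye
selection, bootstrap, simulation) draws from a named substream of one
master seed, so stages are independently reproducible.

## Magnification correction

Instrument-measured disc areas are rescaled by Bennett's abbreviated-eye
factor, area × (3.382 × 0.01306 × (AL − 1.82))², with AL the axial length
in mm. The squared form is the authoritative one: it is the only reading
under which the factor is ≈ 1 at typical axial lengths (exactly 1 at
AL = 1.82 + 1/(3.382×0.01306) ≈ 24.4604 mm). Constants are configurable but
default-pinned; the corrected area is stored alongside, never over, the
measured value. Note that a group mean of corrected areas is a mean of
products — evaluating the factor at group-mean inputs (1.95 mm² at
24.69 mm → 1.99 mm²) approximates but does not equal it.

## Eligibility and visual-field rules

Exclusions (acuity worse than 20/40, IOP > 21 mmHg, cylinder outside ±3 D,
any OCT signal strength < 6) are applied before one-eye-per-subject random
selection; the ordering is a pipeline default, configurable by calling the
stages directly. 20/40 Snellen is mapped to 0.30 logMAR and the exclusion
is strict ("worse than"), with a 1e-9 tolerance so eyes recorded at exactly
0.30 survive. Missing optional fields warn rather than exclude — a record
should not be dropped by a rule that could not be evaluated.

The 30-2 defect classifier requires a cluster of ≥ 3 contiguous non-edge
points below the 5% pattern-deviation probability level, one below 1%, or
a glaucoma hemifield test outside normal limits, confirmed on two reliable
tests (fixation losses < 20%, false positives < 33%, both strict). Three
conventions the rule's usual statement leaves open are made explicit and
configurable:

- adjacency is the 8-neighbourhood on the 6° lattice (orthogonal +
  diagonal);
- clusters may not span the horizontal midline;
- "edge" means the outermost ring — any point with fewer than eight
  in-grid lattice neighbours, which marks 36 of the 76 points.

The grid itself (76 points at 6° spacing offset 3° from the meridians,
within 30°, minus the four (±21°, ±21°) corners; right-eye blind spot at
(+15°, ±3°)) ships as a packaged table with edge/blind-spot flags, so the
definitions are data, not code.

## Synthetic cohorts

The generator inverts the binormal identity: with the oriented control
marker ~ N(μ₀, σ₀²) and the oriented case marker, given covariates x,
~ N(μ₀ + (σ₀/α₂)(α₁ + βᵀx), (σ₀/α₂)²), the true covariate-specific ROC is
exactly Φ(α₁ + α₂Φ⁻¹(q) + βᵀx). Defaults emulate the motivating cohort:
group sizes 173/63; per-group covariate means and SDs matching its
published characteristics (e.g. case VFI 88.99 (9.85), control VFI
99.27 (1.08) truncated at 100; case AL 24.69 (1.48) mm vs control
24.12 (1.58) mm); control marker moments from the published control group
(e.g. average RNFL 93.05 (8.80) µm). Truncation (VFI ≤ 100, positive
areas/thicknesses, plausible physiological ranges) is enforced by rejection
resampling, so requested group sizes are exact. Quality fields are filled
with eligibility-passing values so a generated cohort traverses the full
pipeline unfiltered.

What the generator does **not** emulate: cross-covariate correlation
(covariates are drawn independently; real SE and AL are strongly
negatively correlated), measurement-level artefacts (signal-strength
effects, segmentation failure), non-Gaussian marker tails, and
between-eye correlation (every record is a distinct subject). Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to their violation.

## Simulation study sizes and numerical choices

- The parameter-recovery/coverage study runs 100 replicates at n = 600
  cases / 300 controls with B = 100 bootstrap replicates and an m = 25
  estimation grid — sizes chosen to give Monte-Carlo SEs small enough to
  detect meaningful bias while keeping the study a few minutes on one
  core. The default m = 100 grid is unchanged; the coarser grid is a
  simulation-harness choice (the estimator is consistent for any valid
  grid).
- Coverage of percentile 95% CIs over 100 replicates is checked against
  [0.88, 0.99], the two-sided binomial tolerance around 0.95 at that
  replicate count.
- Quadrature for the AUC oracle uses 256-node Gauss–Legendre on (0, 1);
  64 nodes already agree with the closed form to ~1e-9 for moderate
  coefficients.
- Placement values and indicators are computed by sorted search
  (`searchsorted`), exact for ties under either tie rule.

## Published-coefficient evaluation

`reference_coefficients.json` packages the coefficient sets reported by
the motivating clinical study for the three markers, with the evaluation
profiles it used (baseline age 55 y, SE −2.15 D, AL 24.5 mm, corrected
disc area 2 mm²; severity grid VFI 100/90/80/70; geometry series at VFI
92%). One transcription judgement: the published average-RNFL age
coefficient is printed with a positive sign that contradicts both its own
confidence interval (−0.0311, −0.0009) and the surrounding text; the
packaged file stores −0.0160 and documents the harmonisation. Reproduced
AUROCs match the published GCIPL values to four decimals; the RNFL column
agrees to ~0.001, consistent with four-decimal rounding of its printed
coefficients.

## Known limitations

- The control reference is pooled, so the model cannot express covariate
  effects on specificity; covariates only shift case discrimination.
- Percentile bootstrap intervals can undercover for the intercept at small
  control samples (the placement-value reference is itself estimated).
- The Fisher exact two-sided p uses the minimum-likelihood convention; other
  conventions (doubling) give slightly different values.
- The VF classifier takes pattern-deviation probability categories as
  input; it does not compute them from raw sensitivities.
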