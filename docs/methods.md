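# Methods

## Model and estimation

The measurement model is a second-order confirmatory factor model: a
single well-being factor (WBI, variance fixed to 1) loads on four
first-order components, and each of 14 observed indicators loads on
exactly one component (5 lifestyle, 4 social, 3 emotional, 2 mental-skill
indicators). Identification keeps every first-order factor at unit total
variance: the disturbance variance is tied to the second-order loading,
`ψ_k = 1 − β_k²`, leaving `|β_k| ≤ 1`. Free parameters are the 14 first-order
loadings, 14 residual variances and 4 second-order loadings (32 in all;
`df = 105 − 32 = 73` for the default structure).

Because each indicator carries its own free loading and residual
variance, the model is invariant to rescaling any indicator, so the
engine fits the sample **correlation** matrix internally. The minimized
discrepancy, χ², and all fit indices are identical to a covariance-metric
fit; the fitted parameters are directly the standardized solution, and
unstandardized loadings are recoverable through the stored indicator
standard deviations. This also makes the invariance of the standardized
solution to indicator rescaling exact rather than approximate.

Estimation minimizes the Wishart ML discrepancy
`F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` with an analytic gradient under
L-BFGS-B (β bounded at ±0.9995, residual variances floored at 1e-6), then
polishes the interior coordinates with damped Newton steps built from a
finite-difference Hessian of the analytic gradient. The polish exists
because L-BFGS-B's relative function tolerance leaves ~1e-8 parameter
noise — too coarse for the exact-invariance properties the test-suite
checks; Newton steps are accepted on gradient-norm descent, since near
the optimum the objective itself moves only at machine precision.
Starting values are 0.5 for loadings and second-order loadings and half
the indicator variance for residuals, overridable per call.

The sign of each (factor loading vector, second-order loading) pair is
jointly unidentified; after fitting, signs are aligned so every factor's
loading sum is positive and then the second-order loading sum is
positive. This convention is what allows a genuinely negative
Mental-skills loading to be recovered with its sign, rather than being
absorbed into a flipped factor.

χ² uses the `(n−1)` multiplier. The independence baseline for CFI has the
closed form `F_b = −ln|R|` on the correlation metric (df = p(p−1)/2), so
no second optimization is needed. RMSEA is
`sqrt(max(χ²−df, 0)/(df·(n−1)))`; SRMR is the RMS standardized residual
over the lower triangle, *including* the diagonal by default (switchable,
`srmr_diagonal=False`). Standard errors come from the inverse observed
information of `((n−1)/2)·F` on the standardized metric; they ignore the
sampling variability of the standardization itself, which is adequate for
the second-order loadings (already scale-free) and indicative for the
rest. Residual variances pinned at the 1e-6 floor are reported as Heywood
cases by indicator name; non-convergence sets a flag rather than raising.

Constraints (`fixed={"beta:MS": 0.0}`) are supported by masking
parameters out of the optimization, which is how the nested-model
monotonicity property is tested. Estimation is plain ML on complete cases
(listwise deletion) — the design excludes incomplete questionnaires
upstream, so no FIML path is provided.

## Instrument scoring

* **KIDSCREEN-52**: ten dimension scores; negatively worded items
  (moods & emotions, the negative self-perception items, all bullying
  items) are reverse-keyed as `6 − response`, the dimension's item mean is
  mapped linearly from [1,5] to [0,100]. Up to two missing items per
  dimension are tolerated (within-dimension mean imputation); more makes
  the dimension missing. Linear transformation of item means is used
  rather than Rasch person parameters with European norms: it is
  self-contained, order-preserving, and needs no external calibration
  sample. The reverse-key set and the diet-negative item set follow the
  cited instruments' published conventions and are module-level constants
  a deployment can override.
* **KIDMED**: +1 per affirmed diet-positive item (12), −1 per affirmed
  negative item (4). The canonical instrument spans −4..12; here negative
  totals are floored at zero so the index spans exactly 0–12
  (`floor_at_zero=False` restores the raw range). The bullying dimension
  is keyed so that higher = less bullied, keeping every indicator
  positively oriented within its component.
* **PAQ-C**: mean of the nine 1–5 items.
* **Stroop**: interference = colour-word count minus Golden's predicted
  score `W·C/(W+C)`; higher = better executive function.
* **School performance**: mean of three subject grades (1–10).

## Synthetic cohorts

The generator draws the hierarchy top-down (`WBI → components →
standardized indicator values → native scales`) and then *inverts the
scorers* to produce item-level responses: a target KIDSCREEN dimension
score becomes an integer item-sum spread as evenly as possible over the
dimension's items (reverse-keyed items stored flipped); a target diet
index becomes that many affirmed diet-positive items; the Stroop
interference is inverted against fixed word/colour baselines (100, 75);
PAQ-C and grades likewise via rounded sums. Re-scoring a generated record
therefore recovers the intended indicator value up to the item grid
(step `25/k` for a k-item KIDSCREEN dimension, 1 point for KIDMED and
Stroop, 1/9 and 1/3 for PAQ-C and grades). Quantization adds variance
`h²/12` for grid step `h`, which the moment-recovery tests account for
explicitly.

Default generating parameters are the study conditions: standardized
second-order loadings 0.954 (L), 0.972 (S), 0.949 (E), −0.1417 (MS);
first-order loadings 0.60 except the three reported-weak indicators
(diet, physical activity, executive function) at 0.20; 52 % male; age
N(12, 0.81²) clipped to [10, 14]; per-reason exclusion probabilities
57/1659, 169/1659, 185/1659. Native-scale means/SDs (KIDSCREEN dimensions
65 ± 12, KIDMED 6 ± 2.2, PAQ-C 2.9 ± 0.75, Stroop interference 1.5 ± 6.5,
grades 6.8 ± 1.3) were chosen once as realistic instrument values that
keep the Gaussian draws essentially inside each instrument's admissible
range, so range-clipping has negligible effect on the correlation
structure. Latents are Gaussian throughout — the implicit assumption of
ML covariance-structure estimation; the generator makes it explicit.

What the generator does **not** emulate: school-level clustering,
item-level local dependence beyond the single-factor-per-component
structure, ordinal-item floor/ceiling asymmetries beyond range clipping,
differential missingness (incompleteness blanks 1–3 random questionnaire
items independent of the latent score), or longitudinal change. Passing
recovery tests therefore certifies the estimator and index machinery
under the model's own assumptions — not robustness of the index to
real-data violations of them.

## Exclusion cascade

Stochastic injection draws the three disqualifiers independently per
student, so flags can overlap; the inclusion filter then counts each
excluded student once, under the first matching reason in the order
diagnosed condition → no consent → incomplete → age out of range. This
one-reason accounting is what makes the per-reason counts sum exactly to
the total excluded. A deterministic injection path flags disjoint blocks
with exact counts, reproducing a published cascade precisely
(1,659 − 57 − 169 − 185 = 1,248). Incompleteness is defined as any
missing item response, which makes the filter idempotent.

## Index construction

Per-student raw score: `Σ_j (λ_j/θ_j)·z_j` with z-scores computed against
the reference cohort's means/SDs and weights from the fitted standardized
solution. Contributions are reported per indicator and sum exactly to the
raw score. Cohort min/max anchor the 0–100 rescaling and are persisted
with the model, so later students can be scored against a stored
reference scale (values beyond it are clipped). Component sub-scores
restrict the weighted sum to one component's indicators and are rescaled
per component — components are on different effective scales, so sharing
the global extremes would compress some components into a narrow band;
the per-component choice is flagged here as a construction decision. The
β-weighted composite of standardized component scores is also reported.
The Mental-skills weight enters with its estimated (negative) sign — no
sign flip — so a high mental-skills component slightly *lowers* the
composite; reports keep both layers visible rather than reconciling them.
A degenerate cohort with all-equal raw scores maps to the midpoint 50
with a warning instead of failing. Students missing any indicator are
skipped and listed, mirroring complete-case estimation.

## Numerical and testing notes

* Problem sizes in the routine test-suite and acceptance runs — 20–50
  replicate cohorts of n = 1,248, Monte-Carlo checks at n = 100,000,
  exhaustive KIDMED enumeration at 2^16 — were chosen so the whole suite
  completes in well under a minute while keeping Monte-Carlo standard
  errors far below the tolerances being asserted.
* The independent oracle for estimator equivalence is a deliberately
  naive second-order ML fit (element-wise implied covariance, generic
  quasi-Newton with numerically differenced gradients) living in the test
  suite; it shares no code with the engine. Small oracle models use three
  factors × three indicators because a second-order structure over only
  two first-order factors leaves the two second-order loadings identified
  only through their product.
* The population correlation between the true WBI score and the
  λ/θ-weighted index under the default generating parameters has the
  closed form `w'(Λβ)/sqrt(w'Σw)` = 0.891; the factor-score validity test
  asserts the observed correlation against this value rather than a round
  threshold.
* Determinism: one `numpy` Generator per cohort, seeded explicitly;
  identical (params, n, seed) produce byte-identical CSV artifacts, and
  the pipeline manifest records SHA-256 hashes to make reruns checkable.

## Known limitations

Standard errors are unadjusted for standardization and for the β bound;
near-boundary estimates (|β| → 1) are truncated rather than profiled.
Ordinal KIDSCREEN items are scored and modelled as continuous (no
polychoric path). The engine handles one structure family — single
second-order factor over disjoint indicator blocks — not general SEM.
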