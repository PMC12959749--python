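# Methods

## Data model

A *token* is one vowel production: `(speaker, session, vowel, f1, f2)` with
formants in Hz. Sessions are restricted to `baseline` and `post`. The vowel
inventory is ten monophthongs, stored as ARPABET codes
(`IY IH EY EH AE AH UW UH OW AA`) with a bijective mapping to IPA; the four
*corner vowels* are /i/ (IY), /æ/ (AE), /ɑ/ (AA), /u/ (UW). Input validation
treats a missing required column, a non-numeric formant, or a duplicated
(speaker, session, vowel, repetition) key as errors; physiologically
implausible values (formants outside 100–4000 Hz, or F2 ≤ F1) are surfaced as
warnings in a `ValidationReport` rather than rejected, because disordered
speech legitimately produces unusual formant patterns.

## The three vowel-space metrics

**AAVS.** `sqrt(det(S))`, with `S` the 2 × 2 sample covariance (ddof = 1) of
the (F1, F2) rows. The literature is ambiguous about whether the covariance is
taken over all tokens or over the ten per-vowel means; the two differ because
token-level covariance adds within-vowel scatter to between-vowel dispersion.
Both are implemented (`session_metrics(..., mode="tokens"|"means")`), with
token-level as the default since AAVS was introduced precisely to use all
tokens rather than reduce to category means. The packaged change-score
fixture consumes printed deltas, so no headline result depends on this
choice.

**qVSA.** The absolute shoelace area of the quadrilateral through the four
corner-vowel means in the (F2, F1) plane, traversed IY → AE → AA → UW. For
typical vowel configurations this order walks the quadrilateral boundary
(front-close → front-open → back-open → back-close). With severely compressed
or crossed vowel spaces the fixed traversal can self-intersect, in which case
the shoelace value is not the enclosed area; the implementation detects
self-intersection with a segment-crossing test and emits a `UserWarning`
rather than silently reporting a misleading number. A missing corner vowel
raises `MissingCornerError`.

**VSAhull.** The area of the convex hull of all of the session's tokens in
the (F2, F1) plane, computed with Andrew's monotone-chain algorithm
(implemented here; the hull is the scientific primitive under study, and the
implementation is cross-checked in the tests against an O(n³) supporting-line
oracle on 1,000 random instances). Collinear point sets raise
`DegenerateGeometryError`; collinear boundary points are excluded from the
vertex list.

When a session lacks the data a metric needs (fewer than three distinct
points, missing corners, degenerate geometry), `session_metrics` reports that
metric as `None` with a human-readable note instead of failing the whole
session.

## Change scores and regression

Per speaker, `Δmetric = post − baseline`; speakers missing either session or
either metric value are excluded with a recorded reason. The model is
ordinary least squares with intercept:

```
gain = β0 + β1·ΔAAVS + β2·ΔqVSA + β3·ΔVSAhull + ε
```

The fit is delegated to `statsmodels.OLS` behind a `Model`/`Results` pair
(`IntelligibilityModel` → `IntelligibilityResults`) exposing `params`, `bse`,
`tvalues`, `pvalues`, `conf_int`, `resid`, `fittedvalues`, `rsquared`,
`vif()`, `diagnostics()`, and `summary()`. Fitting requires at least five
rows (one more than the number of parameters) and a design matrix of full
column rank after scaling; rank deficiency raises `CollinearityError`.

**VIF.** For each predictor *j*, regress it on the other two with intercept
and report `VIF_j = 1 / (1 − R²_j)`; auxiliary R² above 1 − 1e-12 reports
infinity.

**Diagnostics.** Shapiro–Wilk on residuals (normality), Breusch–Pagan
(heteroscedasticity), and the slope of |residual| on fitted values as a
scale-location summary. These need at least three residual degrees of
freedom; below that the pipeline records diagnostics as unavailable rather
than reporting unstable statistics.

### The multicollinearity discrepancy

The source analysis of the packaged 13-speaker fixture reports all predictor
VIFs below 2. Recomputing from the fixture's printed change scores gives
VIF(ΔAAVS) = 4.18, VIF(ΔqVSA) = 1.62, VIF(ΔVSAhull) = 5.07; the correlation
between ΔAAVS and ΔVSAhull alone is 0.83, which already forces their VIFs
above 2. The coefficient table itself reproduces exactly at printed precision
from the same fixture, so the fixture transcription is not the cause. The
package reports the computed VIFs, and the corresponding end-to-end test is
deliberately left failing rather than loosened.

## Synthetic cohorts

`generate_tokens(CohortConfig)` draws, for each speaker × session × vowel ×
repetition,

```
(f1, f2) = vowel_target + speaker_offset + (post ? session_shift : 0) + noise
```

with `speaker_offset ~ N(0, speaker_sd²·I)` (one draw per speaker, a global
translation of their vowel space) and `noise ~ N(0, token_sd²·I)` per token.
`simulate_gains` then sets
`gain = β0 + β·Δmetrics + N(0, outcome_sd²)` using each speaker's realised
change scores. Randomness uses `numpy.random.SeedSequence` spawning one
stream per speaker plus one for gains, so token draws are reproducible and
independent of speaker count ordering effects.

### Defaults and their rationale

These are this package's own illustrative choices for generating plausible
disordered-speech cohorts; they are not estimates from any dataset.

- `n_speakers = 13`, `reps = 3`, two sessions, ten vowels — the design shape
  of the packaged cohort fixture.
- `vowel_targets` — the packaged disordered-group formant means, so synthetic
  spaces resemble a compressed vowel configuration; the typically-developing
  column is available for contrast.
- `token_sd = 50` Hz — within-vowel repetition scatter of roughly 50 Hz per
  formant, a plausible magnitude for repeated /hVt/ productions.
- `speaker_sd = 40` Hz — between-speaker translation of the whole space,
  smaller than within-vowel scatter so speakers share a recognisable
  configuration.
- `outcome_coefs = (−0.027, −0.00022, −0.00001, 0.00004)` — the fitted
  coefficients from the packaged fixture, so simulated cohorts are centred on
  the estimated effect sizes.
- `outcome_sd = 4.0` — approximately the residual standard deviation of that
  fit, so simulated gains have realistic unexplained spread.

### What the simulation does and does not show

`recover_parameters` refits the model on replicate cohorts and reports
per-coefficient bias, Monte-Carlo SE, empirical SE, and 95% CI coverage. At
200 speakers × 1,000 replicates the estimator is unbiased (bias within 2
Monte-Carlo SEs of zero) with nominal coverage (0.93–0.97) — a calibration
check of the generator-plus-estimator pair, not evidence about any real
cohort. At the study's own n = 13 the empirical SEs are wide (the intercept's
spread exceeds its true value), illustrating how little information 13 points
carry about four parameters. The generator's translation-only speaker effect
cannot produce between-speaker differences in vowel-space *shape*, and the
gain model is exactly the fitted linear form — so recovery success shows
internal consistency, not realism.

## Numerical choices

- Shoelace and monotone-chain are evaluated in float64; areas are exact up to
  cancellation at the coordinate scale (~1e-9 relative for Hz-scale inputs).
- Covariance determinants of near-collinear clouds cancel to ~1e-8 of
  `sqrt(s11·s22)`; tests bound AAVS degeneracy relative to that scale.
- Confidence ellipses use the eigendecomposition of the sample covariance
  with semi-axes `sqrt(λ_i · χ²₂(coverage))`.
- Replicate seeds derive from `SeedSequence(seed).generate_state(n)` so a
  recovery run is reproducible given `(config, replicates)`.

## Problem sizes exercised

Unit suites run speakers × sessions × 30 tokens up to a few hundred points;
hull oracles run 1,000 random instances up to 60 points; the Monte-Carlo area
oracle uses adaptively sized rejection sampling (oracle relative SE ≤ 1e-3);
calibration runs 1,000 replicates of 200-speaker cohorts (~3.5 minutes); the
LLN covariance check uses 1,000 repetitions of a single vowel.

## Limitations

- Two-session, single-group designs only; no mixed-effects or longitudinal
  structure.
- The corner-vowel traversal order is fixed; pathological configurations are
  flagged, not re-ordered.
- Classical OLS inference (homoscedastic, normal errors) at very small n;
  the diagnostics report, but cannot rescue, violations.
- Formant measurement error is treated as part of token scatter; no explicit
  errors-in-variables correction, although attenuation from measurement error
  in the Δ predictors plausibly biases coefficients toward zero.
- The packaged group-level formant means are summary statistics of raw audio
  this package has no access to; they are carried as pinned fixtures and used
  as plotting/simulation inputs, not recomputed.
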