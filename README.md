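# vowelspace

Acoustic vowel-space metrics and their relationship to speech-intelligibility
gains, for small clinical cohorts measured at two sessions (baseline and
post-intervention).

## Scientific problem

A speaker's *acoustic vowel space* is the region of the first-by-second
formant (F1 × F2) plane covered by their vowel productions. Compressed vowel
spaces are a hallmark of reduced articulatory working space in motor-speech
disorders, and expansion of the space under intervention is a candidate
acoustic explanation for gains in intelligibility. This package computes three
standard area-type summaries of a speaker-session's formant tokens:

- **AAVS** — the articulatory-acoustic vowel space, the square root of the
  generalised variance of (F1, F2): `AAVS = sqrt(det(S))` where `S` is the
  2 × 2 sample covariance matrix (denominator *n* − 1). It uses every token,
  not just corner vowels. Units: Hz².
- **qVSA** — the quadrilateral vowel space area: the shoelace area of the
  polygon through the four corner-vowel means /i/, /æ/, /ɑ/, /u/ (in that
  traversal order) in the (F2, F1) plane. Units: Hz².
- **VSAhull** — the area of the convex hull of all tokens in the (F2, F1)
  plane. Units: Hz².

From a two-session cohort it derives per-speaker change scores
(Δ = post − baseline) and fits the ordinary-least-squares model

```
gain_i = β0 + β1·ΔAAVS_i + β2·ΔqVSA_i + β3·ΔVSAhull_i + ε_i,   ε_i ~ N(0, σ²)
```

where `gain_i` is the speaker's intelligibility gain (word-level percent
correct, post − baseline). The package also provides variance inflation
factors and residual diagnostics for that fit, a synthetic-cohort generator
with a parameter-recovery harness, publication-style figures, and a CLI.

## Running the tests

```
python -m pytest -q tests/
```

One test is expected to fail: `tests/test_acceptance.py::test_predictor_vifs_stay_below_two`
checks an external multicollinearity claim (all predictor VIFs below 2) that
the packaged 13-speaker fixture does not support — the computed maximum VIF is
5.07. The test is kept red deliberately rather than weakened; see
`docs/methods.md` for the analysis.

## Worked example

Fit the model on the packaged 13-speaker change-score fixture:

```python
from vowelspace import fit_intelligibility_model, load_change_scores_fixture

fit = fit_intelligibility_model(load_change_scores_fixture())
print(fit.summary())
```

Output:

```
OLS: wcab_ae_gain ~ dAAVS + dqVSA + dVSAhull
n = 13, residual df = 9, R² = 0.4809, adj. R² = 0.3079

Predictor       Estimate   Std_Error  t_value  p_value
(Intercept)     -0.02694    1.368374   -0.020   0.9847
dAAVS           -0.00022    0.000084   -2.628   0.0275
dqVSA           -0.00001    0.000007   -1.596   0.1450
dVSAhull         0.00004    0.000013    2.870   0.0185

VIF: dAAVS = 4.183, dqVSA = 1.622, dVSAhull = 5.069
```

Metrics from raw tokens:

```python
import numpy as np
from vowelspace import compute_aavs, compute_vsa_hull, session_metrics, read_formant_table

tokens, report = read_formant_table("cohort.csv")   # speaker, session, vowel, f1, f2
one = [t for t in tokens if t.speaker == "S001" and t.session == "baseline"]
m = session_metrics(one)                             # AAVS, qVSA, VSAhull + notes
```

End-to-end on synthetic data from the shell:

```
vowelspace simulate --n-speakers 13 --seed 42 -o tokens.csv --gains-output gains.csv
python - <<'PY'
import pandas as pd
df = pd.read_csv("tokens.csv")
df[df.session == "baseline"].to_csv("baseline.csv", index=False)
df[df.session == "post"].to_csv("post.csv", index=False)
PY
vowelspace run --input-baseline baseline.csv --input-post post.csv \
    --gains gains.csv --out out/
```

which writes `out/metrics.csv`, `out/changes.csv`, `out/model.json`,
`out/report.html`, `out/run.log`, and the three figures (each SVG with a
companion CSV data table). `vowelspace recover` runs the coefficient-recovery
simulation (bias, empirical SE, confidence-interval coverage over replicate
cohorts).

## Layout

```
src/vowelspace/     io, vowels, geometry, metrics, model, simulate, plots, report, cli
src/vowelspace/data/  packaged fixtures (group formant means; cohort change scores)
tests/              unit suites per module + tests/test_acceptance.py (end-to-end)
scripts/acceptance.py  headline-results reproduction
docs/methods.md     statistical methods, defaults and their rationale, limitations
```
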