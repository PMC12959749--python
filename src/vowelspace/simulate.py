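"""Synthetic speaker cohorts with the study's design structure.

A cohort mirrors the elicitation design the analysis assumes: each
speaker produces the 10-vowel /hVt/ inventory in two sessions
(baseline, post) with a fixed number of repetitions per vowel. A
token's formants are

    (F1, F2) = vowel target + speaker offset + session shift + noise

where the per-vowel targets default to the study cohort's baseline
group means, the speaker offset is a single (F1, F2) translation drawn
per speaker (translation leaves all three vowel-space metrics
invariant, so it encodes speaker identity without touching vowel-space
size), the session shift is a per-vowel displacement applied only at
post (zero by default), and the token noise is bivariate normal.

Gain scores follow the linear outcome model the regression assumes:

    gain = β0 + β·Δmetrics + ε,  ε ~ N(0, outcome_sd²)

with Δmetrics computed from the generated tokens by the real metrics
pipeline, so simulated cohorts exercise every stage end to end.
Generation is bit-reproducible under a fixed (config, seed): one seed
sequence per cohort, split by speaker index, plus one child stream for
outcome noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import FormantToken, load_group_means_fixture, tokens_to_frame
from .metrics import (
    MEAN_LEVEL,
    TOKEN_LEVEL,
    compute_aavs,
)
from .geometry import convex_hull, polygon_area
from .model import PREDICTORS, IntelligibilityModel
from .vowels import ALL_VOWELS, CORNER_ORDER, VowelLabel

SESSIONS = ("baseline", "post")


def _default_targets() -> dict[VowelLabel, tuple[float, float]]:
    return {
        m.vowel: (m.f1_mean, m.f2_mean) for m in load_group_means_fixture("DS")
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study design: 13 speakers, 2 sessions,
    10 vowels × 3 repetitions, vowel targets at the cohort's published
    baseline group means, and outcome coefficients at the published
    regression estimates. ``token_sd`` (within-vowel scatter) and
    ``outcome_sd`` (gain noise) have no published counterparts; their
    defaults are illustrative working values, not study estimates.
    """

    n_speakers: int = 13
    vowel_targets: Mapping[VowelLabel, tuple[float, float]] = field(
        default_factory=_default_targets
    )
    speaker_sd: float = 40.0  # Hz, per-speaker (F1, F2) translation
    token_sd: float | Mapping[VowelLabel, np.ndarray] = 50.0  # Hz or per-vowel 2×2 cov
    session_shift: Mapping[VowelLabel, tuple[float, float]] = field(default_factory=dict)
    reps: int = 3
    outcome_coefs: tuple[float, float, float, float] = (-0.027, -0.00022, -0.00001, 0.00004)
    outcome_sd: float = 4.0  # gain-score units
    aavs_mode: str = TOKEN_LEVEL
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_speakers < 1:
            problems.append("n_speakers must be >= 1")
        if self.reps < 1:
            problems.append("reps must be >= 1")
        if self.speaker_sd < 0:
            problems.append("speaker_sd must be >= 0")
        if isinstance(self.token_sd, (int, float)) and self.token_sd < 0:
            problems.append("token_sd must be >= 0")
        if self.outcome_sd < 0:
            problems.append("outcome_sd must be >= 0")
        if set(self.vowel_targets) != set(ALL_VOWELS):
            problems.append("vowel_targets must cover the full 10-vowel inventory")
        if len(self.outcome_coefs) != 4:
            problems.append("outcome_coefs must be (b0, b_aavs, b_qvsa, b_vsahull)")
        if self.aavs_mode not in (TOKEN_LEVEL, MEAN_LEVEL):
            problems.append(f"aavs_mode must be {TOKEN_LEVEL!r} or {MEAN_LEVEL!r}")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def token_cov(self, vowel: VowelLabel) -> np.ndarray:
        if isinstance(self.token_sd, (int, float)):
            return np.eye(2) * float(self.token_sd) ** 2
        return np.asarray(self.token_sd[vowel], dtype=float)


@dataclass
class SyntheticCohort:
    """Generated tokens (both sessions) plus the generating truth."""

    token_array: np.ndarray  # (n_speakers, 2 sessions, 10 vowels, reps, 2) as (f1, f2)
    speakers: list[str]
    config: CohortConfig
    true_gains: Optional[dict[str, float]] = None
    true_coefs: Optional[tuple[float, float, float, float]] = None

    @property
    def seed(self) -> int:
        return self.config.seed

    def to_frame(self) -> pd.DataFrame:
        """Long-format token table in the canonical CSV layout."""
        n_sp, n_sess, n_vow, reps, _ = self.token_array.shape
        rows = []
        for i, sp in enumerate(self.speakers):
            for j, sess in enumerate(SESSIONS):
                for k, vowel in enumerate(ALL_VOWELS):
                    for r in range(reps):
                        f1, f2 = self.token_array[i, j, k, r]
                        rows.append((sp, sess, vowel.value, r + 1, f1, f2))
        return pd.DataFrame(
            rows, columns=["speaker", "session", "vowel", "repetition", "f1_hz", "f2_hz"]
        )

    def to_tokens(self) -> list[FormantToken]:
        return [
            FormantToken(
                str(r.speaker),
                str(r.session),
                VowelLabel(r.vowel),
                int(r.repetition),
                float(r.f1_hz),
                float(r.f2_hz),
            )
            for r in self.to_frame().itertuples(index=False)
        ]


def generate_tokens(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort of formant tokens, deterministically by seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_speakers + 1)  # last stream reserved for gains
    n_vow, reps = len(ALL_VOWELS), config.reps

    targets = np.array([config.vowel_targets[v] for v in ALL_VOWELS], dtype=float)
    shifts = np.array(
        [config.session_shift.get(v, (0.0, 0.0)) for v in ALL_VOWELS], dtype=float
    )
    chols = [np.linalg.cholesky(config.token_cov(v) + 1e-300 * np.eye(2)) for v in ALL_VOWELS]

    arr = np.empty((config.n_speakers, 2, n_vow, reps, 2))
    for i in range(config.n_speakers):
        rng = np.random.default_rng(children[i])
        offset = rng.normal(0.0, config.speaker_sd, size=2)
        noise = rng.standard_normal((2, n_vow, reps, 2))
        for k in range(n_vow):
            noise[:, k] = noise[:, k] @ chols[k].T
        arr[i] = targets[None, :, None, :] + offset + noise
        arr[i, 1] += shifts[:, None, :]
    speakers = [f"S{i + 1:03d}" for i in range(config.n_speakers)]
    return SyntheticCohort(token_array=arr, speakers=speakers, config=config)


# corner-vowel positions within ALL_VOWELS, in quadrilateral perimeter order
_CORNER_IDX = [ALL_VOWELS.index(v) for v in CORNER_ORDER]


def cohort_change_matrix(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-speaker Δmetrics (post − baseline) via the metrics pipeline.

    Fast array path over the cohort's regular design; agreement with
    the public per-session :func:`vowelspace.metrics.session_metrics`
    route is pinned by tests.
    """
    cfg = cohort.config
    arr = cohort.token_array
    n_sp = arr.shape[0]
    vowel_means = arr.mean(axis=3)  # (n_sp, 2, 10, 2) as (f1, f2)
    out = np.empty((n_sp, 3))
    for i in range(n_sp):
        per_session = np.empty((2, 3))
        for j in range(2):
            tokens = arr[i, j].reshape(-1, 2)  # (f1, f2)
            if cfg.aavs_mode == TOKEN_LEVEL:
                aavs = compute_aavs(tokens)
            else:
                aavs = compute_aavs(vowel_means[i, j])
            quad = vowel_means[i, j][_CORNER_IDX][:, ::-1]  # (f2, f1)
            qvsa = polygon_area(quad)
            hull = convex_hull(tokens[:, ::-1]).area
            per_session[j] = (aavs, qvsa, hull)
        out[i] = per_session[1] - per_session[0]
    return pd.DataFrame(out, columns=list(PREDICTORS), index=cohort.speakers)


def simulate_gains(cohort: SyntheticCohort) -> SyntheticCohort:
    """Attach outcome gains: linear in the speaker's true Δmetrics plus noise."""
    cfg = cohort.config
    deltas = cohort_change_matrix(cohort)
    b0, b1, b2, b3 = cfg.outcome_coefs
    mean_gain = b0 + deltas.to_numpy() @ np.array([b1, b2, b3])
    gain_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(cfg.n_speakers + 1)[-1]
    )
    gains = mean_gain + gain_rng.normal(0.0, cfg.outcome_sd, size=len(mean_gain))
    cohort.true_gains = dict(zip(cohort.speakers, gains.tolist()))
    cohort.true_coefs = cfg.outcome_coefs
    return cohort


def cohort_regression_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Change-score DataFrame (Δmetrics + gain) ready for the model."""
    if cohort.true_gains is None:
        raise ValueError("cohort has no gains; call simulate_gains first")
    df = cohort_change_matrix(cohort).reset_index(names="speaker")
    df["wcab_ae_gain"] = [cohort.true_gains[s] for s in df["speaker"]]
    return df


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of coefficient recovery across replicates."""

    coef_names: tuple[str, ...]
    true_coefs: np.ndarray
    estimates: np.ndarray  # (n_ok, 4)
    covered: np.ndarray  # (n_ok, 4) bool, 95% CI contains truth
    rsquared: np.ndarray  # (n_ok,)
    n_replicates: int
    n_failed: int

    @property
    def bias(self) -> np.ndarray:
        return self.estimates.mean(axis=0) - self.true_coefs

    @property
    def empirical_se(self) -> np.ndarray:
        return self.estimates.std(axis=0, ddof=1)

    @property
    def mc_se(self) -> np.ndarray:
        """Standard error of the bias estimate itself."""
        return self.empirical_se / np.sqrt(len(self.estimates))

    @property
    def coverage(self) -> np.ndarray:
        return self.covered.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true": self.true_coefs,
                "mean_estimate": self.estimates.mean(axis=0),
                "bias": self.bias,
                "mc_se": self.mc_se,
                "empirical_se": self.empirical_se,
                "ci95_coverage": self.coverage,
            },
            index=list(self.coef_names),
        )


def recover_parameters(
    config: CohortConfig, n_replicates: int, *, ci_alpha: float = 0.05
) -> RecoverySummary:
    """Generate–simulate–refit loop measuring bias, SE, and CI coverage.

    Each replicate draws a fresh cohort (seeds derived from
    ``config.seed``), simulates gains, refits the change-score OLS, and
    records estimates and whether each ``1−ci_alpha`` confidence
    interval contains the generating coefficient. Replicate failures
    (for example degenerate geometry at extreme settings) are counted,
    not fatal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    estimates, covered, rsquared = [], [], []
    n_failed = 0
    truth = np.asarray(config.outcome_coefs)
    for s in rep_seeds:
        try:
            cohort = simulate_gains(generate_tokens(replace(config, seed=int(s))))
            res = IntelligibilityModel.from_dataframe(cohort_regression_frame(cohort)).fit()
            est = res.params.to_numpy()
            ci = res.conf_int(ci_alpha).to_numpy()
            estimates.append(est)
            covered.append((ci[:, 0] <= truth) & (truth <= ci[:, 1]))
            rsquared.append(res.rsquared)
        except Exception:
            n_failed += 1
    if not estimates:
        raise RuntimeError("all replicates failed")
    return RecoverySummary(
        coef_names=("const",) + tuple(PREDICTORS),
        true_coefs=truth,
        estimates=np.array(estimates),
        covered=np.array(covered),
        rsquared=np.array(rsquared),
        n_replicates=n_replicates,
        n_failed=n_failed,
    )
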