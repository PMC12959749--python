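"""Change-score regression linking vowel-space change to intelligibility gain.

The model is an ordinary least-squares fit of the intelligibility gain
score (post − baseline growth-scale value) on the three vowel-space
change scores::

    gain ~ 1 + ΔAAVS + ΔqVSA + ΔVSAhull

with classical standard errors from σ̂²(XᵀX)⁻¹, σ̂² = RSS/df_resid, and
two-sided p-values from the t distribution with n − 4 residual degrees
of freedom. Multicollinearity is quantified by variance inflation
factors (VIF_j = 1/(1 − R²_j) from regressing predictor j on the other
two with intercept), and residual assumptions by Shapiro–Wilk normality
and Breusch–Pagan homoscedasticity tests — numeric counterparts of the
usual visual diagnostic plots, whose underlying point sets are also
exposed as plain tables.

The public surface follows the model/results idiom: build an
:class:`IntelligibilityModel` from change records or a DataFrame, call
:meth:`~IntelligibilityModel.fit`, and read estimates, uncertainties,
diagnostics and a rendered summary table off the returned
:class:`IntelligibilityResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import (
    CollinearityError,
    DegeneratePredictorError,
    EmptyInputError,
    InsufficientDataError,
)
from .io import ChangeRecord, changes_to_frame
from .metrics import VowelSpaceMetrics

PREDICTORS = ("d_aavs", "d_qvsa", "d_vsahull")
RESPONSE = "wcab_ae_gain"

#: Display names used in summary tables.
TERM_LABELS = {
    "const": "(Intercept)",
    "d_aavs": "dAAVS",
    "d_qvsa": "dqVSA",
    "d_vsahull": "dVSAhull",
}


def compute_change_scores(
    baseline: Sequence[VowelSpaceMetrics],
    post: Sequence[VowelSpaceMetrics],
    gains: Mapping[str, float],
) -> tuple[list[ChangeRecord], list[str]]:
    """Post-minus-baseline metric changes joined with gain scores.

    A speaker missing either session, any of the three metrics, or a
    gain score is excluded; the second return value lists exclusions
    with reasons.
    """
    base = {m.speaker: m for m in baseline}
    after = {m.speaker: m for m in post}
    records: list[ChangeRecord] = []
    excluded: list[str] = []
    for speaker in sorted(set(base) | set(after) | set(gains)):
        b, p = base.get(speaker), after.get(speaker)
        if b is None or p is None:
            excluded.append(f"{speaker}: missing {'baseline' if b is None else 'post'} session")
            continue
        if speaker not in gains:
            excluded.append(f"{speaker}: missing gain score")
            continue
        missing = [
            name
            for name in ("aavs", "qvsa", "vsahull")
            if getattr(b, name) is None or getattr(p, name) is None
        ]
        if missing:
            excluded.append(f"{speaker}: metric(s) unavailable: {', '.join(missing)}")
            continue
        records.append(
            ChangeRecord(
                speaker=speaker,
                d_aavs=p.aavs - b.aavs,
                d_qvsa=p.qvsa - b.qvsa,
                d_vsahull=p.vsahull - b.vsahull,
                wcab_ae_gain=float(gains[speaker]),
            )
        )
    if not records:
        raise EmptyInputError("no speaker has both sessions' metrics and a gain score")
    return records, excluded


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Numeric residual checks plus the data behind the four usual plots."""

    shapiro_stat: float
    shapiro_p: float
    breusch_pagan_stat: float
    breusch_pagan_p: float
    abs_resid_on_fitted_slope: float
    plot_data: dict  # name -> DataFrame

    def to_dict(self) -> dict:
        return {
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "breusch_pagan_stat": self.breusch_pagan_stat,
            "breusch_pagan_p": self.breusch_pagan_p,
            "abs_resid_on_fitted_slope": self.abs_resid_on_fitted_slope,
        }


class IntelligibilityModel:
    """OLS model of gain scores on the three vowel-space change scores.

    Parameters
    ----------
    data
        DataFrame with columns ``d_aavs``, ``d_qvsa``, ``d_vsahull``,
        ``wcab_ae_gain`` and optionally ``speaker``.
    """

    def __init__(self, data: pd.DataFrame):
        required = set(PREDICTORS) | {RESPONSE}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        n = len(self.data)
        if n < 5:
            raise InsufficientDataError(
                f"need at least 5 observations (intercept + 3 predictors + 1 df), got {n}"
            )
        self.endog = self.data[RESPONSE].to_numpy(dtype=float)
        self.exog = sm.add_constant(
            self.data[list(PREDICTORS)].astype(float), has_constant="add"
        )
        self._check_rank()

    @classmethod
    def from_change_records(cls, records: Sequence[ChangeRecord]) -> "IntelligibilityModel":
        return cls(changes_to_frame(records))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "IntelligibilityModel":
        return cls(data)

    def _check_rank(self) -> None:
        x = self.exog.to_numpy(dtype=float)
        # column-scaled rank check so Hz²-scale predictors do not mask
        # exact linear dependence
        scale = np.linalg.norm(x, axis=0)
        scale[scale == 0] = 1.0
        rank = np.linalg.matrix_rank(x / scale)
        if rank < x.shape[1]:
            dependent = _dependent_columns(x / scale, list(self.exog.columns))
            raise CollinearityError(
                f"design matrix is rank deficient; dependent column(s): {dependent}"
            )

    def fit(self) -> "IntelligibilityResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return IntelligibilityResults(self, res)


def _dependent_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    full = np.linalg.matrix_rank(x)
    out = []
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j])
    return out


class IntelligibilityResults:
    """Fitted change-score regression.

    Exposes estimates (``params``), classical standard errors (``bse``),
    t statistics, two-sided p-values, R², residuals and fitted values;
    :meth:`vif`, :meth:`diagnostics` and :meth:`summary` provide the
    collinearity and assumption checks and a rendered coefficient table.
    """

    def __init__(self, model: IntelligibilityModel, res):
        self.model = model
        self._res = res

    # -- estimates ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._res.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.columns = ["lower", "upper"]
        return ci

    # -- collinearity ------------------------------------------------
    def vif(self) -> dict[str, float]:
        return compute_vif(self.model.data)

    # -- residual checks ---------------------------------------------
    def diagnostics(self) -> ResidualDiagnostics:
        return residual_diagnostics(self)

    # -- rendering ---------------------------------------------------
    def coefficient_table(self) -> pd.DataFrame:
        """Full-precision term table: estimate, SE, t, p per term."""
        return pd.DataFrame(
            {
                "term": [TERM_LABELS.get(t, t) for t in self.params.index],
                "estimate": self.params.to_numpy(),
                "std_error": self.bse.to_numpy(),
                "t_value": self.tvalues.to_numpy(),
                "p_value": self.pvalues.to_numpy(),
            }
        )

    def summary(self) -> str:
        """Aligned text table at conventional printed precision.

        Estimates to 5 decimals, standard errors to 6, t to 3, p to 4;
        raw values remain available at full precision via the result
        attributes and :meth:`to_dict`.
        """
        lines = [
            f"OLS: {RESPONSE} ~ dAAVS + dqVSA + dVSAhull",
            f"n = {self.nobs}, residual df = {self.df_resid}, "
            f"R² = {self.rsquared:.4f}, adj. R² = {self.rsquared_adj:.4f}",
            "",
            f"{'Predictor':<12}{'Estimate':>12}{'Std_Error':>12}{'t_value':>9}{'p_value':>9}",
        ]
        for _, row in self.coefficient_table().iterrows():
            lines.append(
                f"{row['term']:<12}{row['estimate']:>12.5f}{row['std_error']:>12.6f}"
                f"{row['t_value']:>9.3f}{row['p_value']:>9.4f}"
            )
        vifs = self.vif()
        lines.append("")
        lines.append(
            "VIF: " + ", ".join(f"{TERM_LABELS.get(k, k)} = {v:.3f}" for k, v in vifs.items())
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable report at full precision (JSON-safe)."""
        return {
            "terms": [
                {
                    "name": TERM_LABELS.get(t, t),
                    "estimate": float(self.params[t]),
                    "std_error": float(self.bse[t]),
                    "t_value": float(self.tvalues[t]),
                    "p_value": float(self.pvalues[t]),
                }
                for t in self.params.index
            ],
            "n": self.nobs,
            "df_resid": self.df_resid,
            "r_squared": self.rsquared,
            "adj_r_squared": self.rsquared_adj,
            "vif": {TERM_LABELS.get(k, k): v for k, v in self.vif().items()},
            "residuals": self.resid.tolist(),
            "fitted": self.fittedvalues.tolist(),
        }


def fit_intelligibility_model(records: Sequence[ChangeRecord]) -> IntelligibilityResults:
    """Convenience wrapper: build the model from change records and fit."""
    return IntelligibilityModel.from_change_records(records).fit()


def compute_vif(data: pd.DataFrame | Sequence[ChangeRecord]) -> dict[str, float]:
    """Variance inflation factors for the three change-score predictors.

    ``VIF_j = 1/(1 − R²_j)`` from regressing predictor j on the other
    two with intercept. Perfect collinearity yields ``inf``; a constant
    predictor raises :class:`DegeneratePredictorError`.
    """
    if not isinstance(data, pd.DataFrame):
        data = changes_to_frame(data)
    x = data[list(PREDICTORS)].astype(float)
    for name in PREDICTORS:
        if np.ptp(x[name].to_numpy()) == 0:
            raise DegeneratePredictorError(f"predictor {name} is constant")
    out: dict[str, float] = {}
    for name in PREDICTORS:
        others = [c for c in PREDICTORS if c != name]
        aux = sm.OLS(x[name], sm.add_constant(x[others], has_constant="add")).fit()
        r2 = aux.rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def residual_diagnostics(result: IntelligibilityResults) -> ResidualDiagnostics:
    """Numeric counterparts of the standard visual assumption checks."""
    if result.df_resid < 3:
        raise InsufficientDataError("diagnostics need at least 3 residual degrees of freedom")
    resid = result.resid
    fitted = result.fittedvalues
    sw_stat, sw_p = sps.shapiro(resid)
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, result.model.exog.to_numpy(dtype=float))

    slope_fit = sm.OLS(np.abs(resid), sm.add_constant(fitted)).fit()
    slope = float(slope_fit.params[1])

    influence = result._res.get_influence()
    std_resid = influence.resid_studentized_internal
    leverage = influence.hat_matrix_diag
    osm, osr = sps.probplot(resid, dist="norm", fit=False)
    plot_data = {
        "residual_vs_fitted": pd.DataFrame({"fitted": fitted, "residual": resid}),
        "qq": pd.DataFrame({"theoretical": osm, "sample": osr}),
        "scale_location": pd.DataFrame(
            {"fitted": fitted, "sqrt_abs_std_resid": np.sqrt(np.abs(std_resid))}
        ),
        "leverage": pd.DataFrame({"leverage": leverage, "std_resid": std_resid}),
    }
    return ResidualDiagnostics(
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        breusch_pagan_stat=float(bp_stat),
        breusch_pagan_p=float(bp_p),
        abs_resid_on_fitted_slope=slope,
        plot_data=plot_data,
    )
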