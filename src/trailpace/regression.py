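"""Terrain-segment regression models for total race time.

Each of the three terrain segments (ascent #1, descent, ascent #2)
gets an ordinary-least-squares model of total time TT on that
segment's predictor triple — weighted time WT_n, weighted-time
variability WTV_{n,n+2}, and checkpoint percentile rank CPR_n — with
all three predictors entered simultaneously ("enter" method).  The
fit ships with the full diagnostic battery used in applied pacing
work: adjusted R^2 and the standard error of estimate, Durbin–Watson
residual autocorrelation, variance inflation factors, Cook's-distance
and |standardized residual| > 3 SD case screening (one flag-and-refit
pass), standardized betas, and Bland–Altman agreement between the
model's predictions and actual finish times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import (
    OLSInfluence,
    variance_inflation_factor,
)
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .stats import NormalityResult, normality_screen

__all__ = [
    "SEGMENTS",
    "RegressionResult",
    "AgreementSummary",
    "fit_segment_model",
    "durbin_watson",
    "vif",
    "cooks_distance",
    "bland_altman",
]

# segment -> (early section, late section, CPR checkpoint); the WTV
# pair skips the intervening opposite-slope section.
SEGMENTS: dict[str, tuple[int, int, int]] = {
    "ascent1": (1, 3, 1),
    "descent": (2, 4, 2),
    "ascent2": (3, 5, 3),
}


def segment_columns(segment: str) -> tuple[str, str, str]:
    """Feature-table column names of a segment's predictor triple."""
    try:
        a, b, k = SEGMENTS[segment]
    except KeyError:
        raise ValueError(f"unknown segment {segment!r}; expected one of {list(SEGMENTS)}")
    return f"WT_{a}", f"WTV_{a}{b}", f"CPR_{k}"


@dataclass(frozen=True)
class Coefficient:
    name: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    beta: float | None  # standardized; None for the constant
    p: float


@dataclass(frozen=True)
class RegressionResult:
    """One fitted segment model with diagnostics."""

    segment: str
    coefficients: tuple[Coefficient, ...]  # constant first
    r: float
    r2: float
    adj_r2: float
    see: float
    dw: float
    vif: dict[str, float]
    excluded_cases: tuple[str, ...]
    n_used: int
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> Coefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def coef_values(self) -> dict[str, float]:
        return {c.name: c.b for c in self.coefficients}

    def predict(self, X: pd.DataFrame | dict) -> np.ndarray:
        """Evaluate the linear model on named predictor columns."""
        if isinstance(X, dict):
            X = pd.DataFrame(X)
        out = np.full(len(X), self.coef("constant").b, dtype=float)
        for c in self.coefficients:
            if c.name != "constant":
                out = out + c.b * np.asarray(X[c.name], dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "segment": self.segment,
            "coefficients": [
                {"name": c.name, "b": c.b, "se": c.se,
                 "ci_low": c.ci_low, "ci_high": c.ci_high,
                 "beta": c.beta, "p": c.p}
                for c in self.coefficients
            ],
            "r": self.r, "r2": self.r2, "adj_r2": self.adj_r2,
            "see": self.see, "dw": self.dw, "vif": self.vif,
            "excluded_cases": list(self.excluded_cases),
            "n_used": self.n_used,
        }


def durbin_watson(residuals) -> float:
    """Durbin–Watson statistic, sum of squared successive residual
    differences over the residual sum of squares; 2 = no
    autocorrelation, values in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("Durbin-Watson needs >= 2 residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_dw(e))


def vif(design: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Variance inflation factor per predictor: 1/(1 - R^2_j) from
    regressing predictor j on the others (with intercept).

    Perfect collinearity is reported as ``inf`` rather than raised.
    """
    if isinstance(design, np.ndarray):
        design = pd.DataFrame(design, columns=[f"x{i + 1}" for i in range(design.shape[1])])
    if design.shape[1] < 2:
        raise ValueError("VIF needs >= 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    out: dict[str, float] = {}
    for j, name in enumerate(design.columns, start=1):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = variance_inflation_factor(X, j)
        out[name] = float(v) if np.isfinite(v) else float("inf")
    return out


def cooks_distance(fit) -> np.ndarray:
    """Per-case Cook's distance of a fitted statsmodels OLS result."""
    return np.asarray(OLSInfluence(fit).cooks_distance[0], dtype=float)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_segment_model(
    features: pd.DataFrame,
    segment: str,
    *,
    exclude_influential: bool = True,
    ci_alpha: float = 0.05,
) -> RegressionResult:
    """Fit one terrain segment's TT model with the full diagnostics.

    Rows missing any of the segment's predictor triple or TT are
    dropped pairwise.  Influence screening (Cook's distance > 1 or
    |standardized residual| > 3) is a single flag-and-refit pass;
    the flagged runner ids are reported in ``excluded_cases``.
    """
    cols = list(segment_columns(segment))
    needed = cols + ["TT"]
    data = features.dropna(subset=needed)
    if len(data) < 10:
        raise ValueError(
            f"segment {segment}: need >= 10 complete rows, got {len(data)}"
        )
    X = data[cols].astype(float)
    rank = np.linalg.matrix_rank(sm.add_constant(X.to_numpy(), has_constant="add"))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"segment {segment}: rank-deficient design; most collinear pair {worst}"
        )
    y = data["TT"].to_numpy(dtype=float)

    fit = _fit_ols(y, X)
    excluded: tuple[str, ...] = ()
    if exclude_influential:
        d = cooks_distance(fit)
        std_resid = np.asarray(OLSInfluence(fit).resid_studentized_internal)
        flag = (d > 1.0) | (np.abs(std_resid) > 3.0)
        if flag.any():
            excluded = tuple(str(r) for r in data.loc[flag, "runner_id"]) \
                if "runner_id" in data.columns else tuple(map(str, data.index[flag]))
            data = data.loc[~flag]
            X = data[cols].astype(float)
            y = data["TT"].to_numpy(dtype=float)
            fit = _fit_ols(y, X)

    ci = fit.conf_int(alpha=ci_alpha)
    sy = y.std(ddof=1)
    coefs = []
    for key in ["const"] + cols:
        name = "constant" if key == "const" else key
        beta = None
        if name != "constant":
            beta = float(fit.params[key] * X[name].std(ddof=1) / sy)
        coefs.append(Coefficient(
            name=name, b=float(fit.params[key]), se=float(fit.bse[key]),
            ci_low=float(ci.loc[key, 0]), ci_high=float(ci.loc[key, 1]),
            beta=beta, p=float(fit.pvalues[key]),
        ))

    resid = np.asarray(fit.resid)
    return RegressionResult(
        segment=segment,
        coefficients=tuple(coefs),
        r=float(np.sqrt(fit.rsquared)),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        see=float(np.sqrt(fit.mse_resid)),
        dw=durbin_watson(resid),
        vif=vif(X),
        excluded_cases=excluded,
        n_used=int(fit.nobs),
        fitted=np.asarray(fit.fittedvalues),
        residuals=resid,
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman agreement between predicted and actual times."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    pct_outside: float
    n: int
    residual_normality: NormalityResult | None
    degenerate: bool = False


def bland_altman(predicted, actual, *, alpha: float = 0.05) -> AgreementSummary:
    """Bias and ±1.96 SD limits of agreement of predicted - actual.

    Differences are taken against pair means in the usual Bland–Altman
    construction; a zero-variance difference (exact or constant-offset
    agreement) is flagged degenerate rather than screened for
    normality.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must be paired")
    mask = ~(np.isnan(predicted) | np.isnan(actual))
    diff = predicted[mask] - actual[mask]
    n = len(diff)
    if n < 3:
        raise ValueError("Bland-Altman needs >= 3 complete pairs")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    degenerate = sd == 0
    outside = float(np.mean((diff < loa_low) | (diff > loa_high))) if not degenerate else 0.0
    normality = None if degenerate else normality_screen(diff, alpha=alpha)
    return AgreementSummary(
        bias=bias, sd=sd, loa_low=loa_low, loa_high=loa_high,
        pct_outside=outside, n=n, residual_normality=normality,
        degenerate=degenerate,
    )
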