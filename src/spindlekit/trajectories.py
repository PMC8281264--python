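"""Maturational-trajectory statistics for spindle and sigma outcomes.

Cross-sectional: covariate-adjusted polynomial age models with top-down
degree selection (cubic -> quadratic -> linear on the highest-order term at
alpha = 0.05, lower-order terms always retained), predicted population mean
curves with pointwise 95% CIs, ages at the minimum/maximum of the predicted
curve over 6-21 years, and standardized piece-wise slopes (outcome divided
by its full-sample SD).  Group contrasts (sex, Tanner 1-3 vs 4-5) use
ANCOVA with least-squares adjusted means obtained by marginal
standardization over the observed covariate distribution.

Longitudinal: the within-subject percent change
[(follow-up - baseline)/baseline] x 100 is modelled with general linear
models additionally adjusted for the baseline value and the length of
follow-up.  Agreement between contralateral and ipsilateral derivations is
quantified with Lin's concordance correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as _st

__all__ = [
    "DEFAULT_COVARIATES",
    "CROSS_SECTIONAL_SEGMENTS",
    "LONGITUDINAL_AGE_GROUPS",
    "TrajectoryFit",
    "PiecewiseBeta",
    "AdjustedMeans",
    "ConcordanceResult",
    "percent_change",
    "select_polynomial_degree",
    "predict_mean_curve",
    "locate_extrema",
    "piecewise_standardized_slopes",
    "groupwise_adjusted_means",
    "pearson_matrix",
    "lin_concordance",
]

#: Adjustment covariates for the cross-sectional models.
DEFAULT_COVARIATES = ("sex", "race_ethnicity", "bmi", "ahi", "disorder_flag",
                      "psg_system")

#: Developmentally appropriate cross-sectional age segments (whole years).
CROSS_SECTIONAL_SEGMENTS = ((6, 10), (11, 14), (15, 17), (18, 21))

#: Follow-up age groups for the longitudinal percent-change models.
LONGITUDINAL_AGE_GROUPS = ((12, 14), (15, 17), (18, 22))

_CATEGORICAL = {"sex", "race_ethnicity", "psg_system", "disorder_flag"}


def _covariate_terms(covariates: Sequence[str]) -> list[str]:
    return [f"C({c})" if c in _CATEGORICAL else c for c in covariates]


def percent_change(baseline: float, followup: float) -> float:
    """[(follow-up - baseline) / baseline] x 100; undefined at baseline 0."""
    if baseline == 0:
        raise ValueError("percent change undefined for zero baseline")
    return (followup - baseline) / baseline * 100.0


def percent_change_table(
    table: pd.DataFrame, outcomes: Sequence[str]
) -> pd.DataFrame:
    """Add ``<outcome>_pct_change`` columns; rows with a zero baseline are
    excluded (logged via the returned table's attrs)."""
    out = table.copy()
    dropped: dict[str, int] = {}
    for oc in outcomes:
        base = out[f"{oc}_baseline"]
        bad = base == 0
        dropped[oc] = int(bad.sum())
        out = out[~bad]
        base = out[f"{oc}_baseline"]
        out[f"{oc}_pct_change"] = (out[oc] - base) / base * 100.0
    out.attrs["n_dropped_zero_baseline"] = dropped
    return out


# ---------------------------------------------------------------------------
# polynomial trajectory models

_AGE_TERMS = {1: ["age"], 2: ["age", "I(age**2)"], 3: ["age", "I(age**2)", "I(age**3)"]}
_HIGHEST = {1: "age", 2: "I(age ** 2)", 3: "I(age ** 3)"}


@dataclass
class TrajectoryFit:
    """A selected covariate-adjusted polynomial age model."""

    outcome: str
    selected_degree: int
    result: object                    # statsmodels RegressionResults
    data: pd.DataFrame = field(repr=False)
    age_range: tuple[float, float] = (6.0, 21.0)
    degree_pvalues: dict[int, float] = field(default_factory=dict)

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)

    @property
    def coefficients(self) -> pd.DataFrame:
        res = self.result
        return pd.DataFrame({
            "coef": res.params, "se": res.bse, "p_value": res.pvalues,
        })

    def age_polynomial(self) -> np.ndarray:
        """Coefficients (const-free) of the age polynomial, ascending powers
        starting at age^1."""
        coefs = []
        for d in range(1, self.selected_degree + 1):
            coefs.append(float(self.result.params[_HIGHEST[d]]))
        return np.array(coefs)


def _fit_formula(table: pd.DataFrame, outcome: str, degree: int,
                 covariates: Sequence[str]):
    terms = _AGE_TERMS[degree] + _covariate_terms(covariates)
    formula = f"{outcome} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = model.exog_names
        # name the collinear columns: those whose removal restores full rank
        collinear = [nm for j, nm in enumerate(names)
                     if np.linalg.matrix_rank(np.delete(model.exog, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return model.fit()


def select_polynomial_degree(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_range: tuple[float, float] = (6.0, 21.0),
    alpha: float = 0.05,
    max_degree: int = 3,
) -> TrajectoryFit:
    """Top-down polynomial degree selection on the highest age term.

    Fits the cubic model (with quadratic and linear terms retained); if the
    cubic term is not significant at ``alpha`` refits the quadratic, then
    the linear model, which is kept regardless of significance.
    """
    if len(table) < 20:
        raise ValueError("need >= 20 rows for trajectory fitting")
    if table["age"].nunique() < max_degree + 1:
        raise ValueError("insufficient age variation for polynomial fitting")
    covariates = [c for c in covariates if c in table.columns]
    pvals: dict[int, float] = {}
    for degree in range(max_degree, 0, -1):
        res = _fit_formula(table, outcome, degree, covariates)
        p_high = float(res.pvalues[_HIGHEST[degree]])
        pvals[degree] = p_high
        if p_high < alpha or degree == 1:
            return TrajectoryFit(
                outcome=outcome, selected_degree=degree, result=res,
                data=table, age_range=age_range, degree_pvalues=pvals,
            )
    raise AssertionError("unreachable")


def _marginal_prediction(fit: TrajectoryFit, age: float) -> tuple[float, float]:
    """Mean prediction and its SE with covariates marginalized over the
    observed sample (continuous at their values, categoricals at observed
    proportions): the average design row is linear in beta, so the variance
    is x_bar' Cov x_bar."""
    res = fit.result
    design_info = res.model.data.design_info
    cf = fit.data.copy()
    cf["age"] = age
    (X,) = build_design_matrices([design_info], cf)
    xbar = np.asarray(X).mean(axis=0)
    mean = float(xbar @ res.params)
    var = float(xbar @ res.cov_params() @ xbar)
    return mean, math.sqrt(max(var, 0.0))


def predict_mean_curve(
    fit: TrajectoryFit, ages: Sequence[float] | None = None
) -> pd.DataFrame:
    """Population mean curve with pointwise 95% CI over ages 6-21.

    Ages outside the fit's age range are refused (no extrapolation).
    """
    lo, hi = fit.age_range
    if ages is None:
        ages = np.round(np.arange(lo, hi + 1e-9, 0.25), 4)
    ages = np.asarray(ages, dtype=float)
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        raise ValueError(f"ages outside [{lo}, {hi}]: extrapolation refused")
    crit = _st.t.ppf(0.975, df=fit.result.df_resid)
    rows = []
    for a in ages:
        mean, se = _marginal_prediction(fit, float(a))
        rows.append((a, mean, mean - crit * se, mean + crit * se))
    return pd.DataFrame(rows, columns=["age", "mean", "ci_low", "ci_high"])


def locate_extrema(fit: TrajectoryFit) -> tuple[float, float]:
    """(age_at_min, age_at_max) of the predicted curve over the age range.

    Interior stationary points come from the roots of the age-polynomial
    derivative, compared against the endpoints; reported to 0.1 year.
    """
    lo, hi = fit.age_range
    coefs = fit.age_polynomial()               # ascending, powers 1..d
    poly = np.polynomial.Polynomial(np.concatenate([[0.0], coefs]))
    candidates = [lo, hi]
    if fit.selected_degree >= 2:
        roots = poly.deriv().roots()
        candidates += [float(r.real) for r in roots
                       if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
    vals = poly(np.asarray(candidates))
    age_min = float(np.clip(candidates[int(np.argmin(vals))], lo, hi))
    age_max = float(np.clip(candidates[int(np.argmax(vals))], lo, hi))
    return round(age_min, 1), round(age_max, 1)


# ---------------------------------------------------------------------------
# piece-wise standardized slopes

@dataclass
class PiecewiseBeta:
    """Standardized age slope within one whole-year age segment."""

    segment: tuple[int, int]
    beta_s: float    # per SD of outcome, per year
    se: float
    p_value: float
    n: int


def _segment_mask(age: pd.Series, segment: tuple[int, int]) -> pd.Series:
    # closed interval of whole years: ages with floor(age) in [lo, hi]
    fl = np.floor(age)
    return (fl >= segment[0]) & (fl <= segment[1])


def piecewise_standardized_slopes(
    table: pd.DataFrame,
    outcome: str,
    segments: Sequence[tuple[int, int]] = CROSS_SECTIONAL_SEGMENTS,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_rows: int = 10,
) -> list[PiecewiseBeta]:
    """Covariate-adjusted linear age slopes on the SD-standardized outcome.

    The outcome SD is computed once over the full analysis sample so the
    beta_s are comparable across segments; empty/short segments are omitted.
    """
    covariates = [c for c in covariates if c in table.columns]
    sd = float(table[outcome].std(ddof=1))
    if sd == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    work = table.copy()
    work["_y_std"] = work[outcome] / sd
    out: list[PiecewiseBeta] = []
    for seg in segments:
        sub = work[_segment_mask(work["age"], seg)]
        if len(sub) < min_rows:
            continue
        terms = ["age"] + _covariate_terms(covariates)
        res = smf.ols("_y_std ~ " + " + ".join(terms), data=sub).fit()
        out.append(PiecewiseBeta(
            segment=tuple(seg), beta_s=float(res.params["age"]),
            se=float(res.bse["age"]), p_value=float(res.pvalues["age"]),
            n=len(sub),
        ))
    return out


# ---------------------------------------------------------------------------
# group contrasts (ANCOVA adjusted means)

@dataclass
class AdjustedMeans:
    """Covariate-adjusted stratum means within one age group."""

    outcome: str
    group_var: str
    age_group: tuple[int, int]
    means: dict[str, tuple[float, float, float]]   # stratum -> (mean, lo, hi)
    p_value: float
    n: int


def groupwise_adjusted_means(
    table: pd.DataFrame,
    outcome: str,
    group_var: str,
    age_group: tuple[int, int],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    longitudinal_baseline: str | None = None,
) -> AdjustedMeans:
    """ANCOVA stratum contrast within an age group.

    Adjusted (least-squares) means are computed by marginal standardization:
    every subject's covariate row is evaluated under each stratum and
    averaged.  For longitudinal percent-change outcomes pass the baseline
    column name via ``longitudinal_baseline``; the model then additionally
    adjusts for the baseline value and ``followup_years``.
    """
    sub = table[_segment_mask(table["age"], age_group)].copy()
    sub = sub.dropna(subset=[outcome, group_var])
    strata = sorted(sub[group_var].astype(str).unique())
    if len(strata) < 2:
        raise ValueError(
            f"single-stratum age group {age_group}: contrast undefined "
            f"(strata present: {strata})"
        )
    covariates = [c for c in covariates if c in sub.columns and c != group_var]
    terms = [f"C({group_var})"] + _covariate_terms(covariates)
    if longitudinal_baseline is not None:
        terms += [longitudinal_baseline, "followup_years"]
    res = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=sub).fit()

    design_info = res.model.data.design_info
    crit = _st.t.ppf(0.975, df=res.df_resid)
    means: dict[str, tuple[float, float, float]] = {}
    for s in strata:
        cf = sub.copy()
        cf[group_var] = s
        (X,) = build_design_matrices([design_info], cf)
        xbar = np.asarray(X).mean(axis=0)
        m = float(xbar @ res.params)
        se = math.sqrt(max(float(xbar @ res.cov_params() @ xbar), 0.0))
        means[s] = (m, m - crit * se, m + crit * se)

    group_terms = [nm for nm in res.params.index if nm.startswith(f"C({group_var})")]
    if len(group_terms) == 1:
        p = float(res.pvalues[group_terms[0]])
    else:  # joint Wald test across all stratum coefficients
        p = float(res.f_test([f"{t} = 0" for t in group_terms]).pvalue)
    return AdjustedMeans(outcome=outcome, group_var=group_var,
                         age_group=tuple(age_group), means=means,
                         p_value=p, n=len(sub))


# ---------------------------------------------------------------------------
# correlations and concordance

def pearson_matrix(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson coefficients over complete cases per pair.

    Zero-variance columns yield NaN in their row/column.
    """
    if len(table.dropna(subset=list(columns))) < 3:
        raise ValueError("need >= 3 complete rows for a correlation matrix")
    return table[list(columns)].corr(method="pearson")


@dataclass
class ConcordanceResult:
    rho_c: float
    ci_low: float
    ci_high: float
    n: int


def lin_concordance(x: Sequence[float], y: Sequence[float],
                    alpha: float = 0.05) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),
    penalizing both decorrelation and location/scale shift, so
    rho_c <= |Pearson r| with equality iff means and variances match.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d vectors with n >= 3")
    n = len(x)
    sx2, sy2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("concordance undefined for constant input")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    dmean = float(np.mean(x) - np.mean(y))
    rho_c = 2.0 * sxy / (sx2 + sy2 + dmean**2)
    r = sxy / math.sqrt(sx2 * sy2)
    # Lin (1989) variance of the z-transformed estimate
    u = dmean / (sx2 * sy2) ** 0.25
    rho_c_cl = min(max(rho_c, -1 + 1e-12), 1 - 1e-12)
    r_cl = min(max(abs(r), 1e-12), 1 - 1e-12) * np.sign(r if r != 0 else 1.0)
    var_z = (
        (1 - r_cl**2) * rho_c_cl**2 / ((1 - rho_c_cl**2) * r_cl**2)
        + 2 * rho_c_cl**3 * (1 - rho_c_cl) * u**2 / (r_cl * (1 - rho_c_cl**2) ** 2)
        - rho_c_cl**4 * u**4 / (2 * r_cl**2 * (1 - rho_c_cl**2) ** 2)
    ) / (n - 2)
    z = np.arctanh(rho_c_cl)
    d = _st.norm.ppf(1 - alpha / 2) * math.sqrt(max(var_z, 0.0))
    return ConcordanceResult(
        rho_c=float(rho_c), ci_low=float(np.tanh(z - d)),
        ci_high=float(np.tanh(z + d)), n=n,
    )
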