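"""Covariate models for ordination scores.

Ordinary least squares of per-specimen shape scores on participant
covariates (age group, sex, height, log body mass, muscle volume, physical
activity, and the age-by-sex interaction), with backward stepwise reduction,
partial r-squared per term, normality-gated two-group comparisons, and the
partial-residual data behind effect plots.

Age is modelled as the binary young/older cohort group. No multiple-testing
correction is applied across muscles or axes; this is recorded in the model
metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

#: canonical model terms; ``age_group:sex`` is the interaction
DEFAULT_TERMS = ("log_mass", "age_group", "sex", "volume", "metmin",
                 "height", "age_group:sex")

_CATEGORIES = {"age_group": ["young", "older"], "sex": ["female", "male"]}
_NUMERIC_COLUMNS = ("height", "mass", "volume", "metmin")


def validate_covariates(covars: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table and normalize its dtypes.

    Requires unique specimen ids, valid category labels and finite positive
    numeric covariates; returns a copy with fixed category ordering
    (reference levels: young, female) and a ``log_mass`` column.
    """
    df = covars.copy()
    required = {"specimen_id", "age_group", "sex", *_NUMERIC_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        raise ValueError("specimen_id values must be unique")
    for col, cats in _CATEGORIES.items():
        bad = set(df[col]) - set(cats)
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
        df[col] = pd.Categorical(df[col], categories=cats)
    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col])
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"covariate {col!r} must be finite and positive")
        df[col] = vals.astype(float)
    df["log_mass"] = np.log(df["mass"])
    return df


@dataclass
class ModelFit:
    """A fitted OLS model of one ordination axis on covariates."""

    response: str
    terms: list[str]
    coefficients: pd.DataFrame      # per design column: coef, se, t, p, term
    residual_df: int
    aic: float
    r_squared: float
    partial_r2: dict[str, float]
    data: pd.DataFrame = field(repr=False)
    sm_result: object = field(repr=False, default=None)
    metadata: dict = field(default_factory=lambda: {
        "multiple_testing_correction": "none"})

    def term_pvalue(self, term: str) -> float:
        rows = self.coefficients[self.coefficients["term"] == term]
        if rows.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(rows["p"].iloc[0])


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_ols(data: pd.DataFrame, response: str,
            terms: list[str] | tuple[str, ...]) -> ModelFit:
    """OLS of ``response`` on ``terms`` over an already-prepared table.

    The generic fitting core: no covariate-schema validation, so it also
    serves arbitrary designs (simulation studies, stepwise refits).
    """
    terms = list(terms)
    res = smf.ols(_formula(response, terms), data=data).fit()
    exog = res.model.exog
    if len(data) <= exog.shape[1] + 1:
        raise ValueError(
            f"{len(data)} observations cannot identify {exog.shape[1]} "
            "coefficients")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # identify offending terms by near-zero R diagonal of a QR
        diag = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        names = np.asarray(res.model.exog_names)
        bad = names[diag < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient: {list(bad)}")

    design_info = res.model.data.design_info
    col_term = {}
    for term_obj, slc in design_info.term_name_slices.items():
        for name in design_info.column_names[slc]:
            col_term[name] = str(term_obj)
    params = pd.DataFrame({
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    params["term"] = [col_term.get(ix, ix) for ix in params.index]
    params = params.fillna({"t": 0.0, "p": 1.0})

    dfres = int(res.df_resid)
    pr2 = {}
    for name, row in params.iterrows():
        if row["term"] == "Intercept":
            continue
        pr2[row["term"]] = partial_r2(float(row["t"]), dfres)
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    return ModelFit(response=response, terms=terms,
                    coefficients=params, residual_df=dfres,
                    aic=float(res.aic), r_squared=r2, partial_r2=pr2,
                    data=data, sm_result=res)


def fit_glm(scores, covars: pd.DataFrame,
            terms: list[str] | tuple[str, ...] = DEFAULT_TERMS,
            response: str = "score") -> ModelFit:
    """OLS fit of shape scores on covariate terms.

    ``scores`` is a mapping/Series keyed by specimen id, or an array aligned
    with the covariate rows. Categorical terms are dummy-coded against the
    young / female reference levels; body mass enters as its natural log.
    Specimens without a covariate row are dropped from the fit (inner join,
    logged).
    """
    terms = list(terms)
    df = validate_covariates(covars)
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    if isinstance(scores, dict):
        before = len(df)
        df = df[df["specimen_id"].isin(scores)].reset_index(drop=True)
        if len(df) < before:
            log.info("dropped %d covariate rows without scores",
                     before - len(df))
        df[response] = df["specimen_id"].map(scores).astype(float)
    else:
        vals = np.asarray(scores, dtype=float)
        if len(vals) != len(df):
            raise ValueError("scores length must match covariate rows")
        df[response] = vals

    return fit_ols(df, response, terms)


def _interaction_components(term: str) -> set[str]:
    return set(term.split(":"))


def _droppable(terms: list[str]) -> list[str]:
    """Terms removable under marginality: a main effect stays while any
    retained interaction contains it; interactions are always droppable."""
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
            continue
        protected = any(":" in u and t in _interaction_components(u)
                        for u in terms)
        if not protected:
            out.append(t)
    return out


def backward_stepwise(fit: ModelFit, criterion: str = "aic",
                      alpha: float = 0.05) -> ModelFit:
    """Backward elimination of model terms.

    ``aic`` mode drops, at each step, the term whose removal lowers the AIC
    the most, stopping when no removal improves it; ``alpha`` mode drops the
    term with the largest p-value above ``alpha``. Marginality is respected:
    an interaction is removed before its main effects, and main effects are
    kept while their interaction remains.
    """
    if criterion not in ("aic", "alpha"):
        raise ValueError("criterion must be 'aic' or 'alpha'")
    current = fit
    while True:
        cand = _droppable(current.terms)
        if not cand:
            return current
        if criterion == "aic":
            best_fit, best_aic = None, current.aic
            for t in sorted(cand):
                reduced = fit_ols(current.data,
                                  current.response,
                                  [u for u in current.terms if u != t])
                if reduced.aic < best_aic - 1e-10:
                    best_fit, best_aic = reduced, reduced.aic
            if best_fit is None:
                return current
            current = best_fit
        else:
            pvals = {t: current.term_pvalue(t) for t in cand}
            worst = max(sorted(pvals), key=lambda t: pvals[t])
            if pvals[worst] <= alpha:
                return current
            current = fit_ols(current.data, current.response,
                              [u for u in current.terms if u != worst])


def partial_r2(t_stat: float, residual_df: int) -> float:
    """Partial r-squared of one term from its t statistic: t^2/(t^2+df)."""
    if residual_df < 1:
        raise ValueError("residual_df must be at least 1")
    t2 = float(t_stat) ** 2
    return t2 / (t2 + residual_df)


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    test_used: str          # "welch_t", "mann_whitney" or "skipped"
    mean_difference: float = 0.0


def compare_groups(x, y, normality_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk on each sample decides the test: both consistent with
    normality at ``normality_alpha`` gives a Welch t-test, otherwise a
    two-sided Mann-Whitney U. Degenerate zero-variance pairs are flagged
    and skipped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return GroupComparison(0.0, np.nan, "skipped",
                               float(x.mean() - y.mean()))

    def _normal(a: np.ndarray) -> bool:
        if np.ptp(a) == 0:
            return False
        return sps.shapiro(a).pvalue > normality_alpha

    diff = float(x.mean() - y.mean())
    if _normal(x) and _normal(y):
        res = sps.ttest_ind(x, y, equal_var=False)
        return GroupComparison(float(res.statistic), float(res.pvalue),
                               "welch_t", diff)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(float(res.statistic), float(res.pvalue),
                           "mann_whitney", diff)


@dataclass
class EffectPlotData:
    """Partial-residual data behind one term's effect plot."""

    term: str
    table: pd.DataFrame      # x, partial_residual, line, line_ci_low/high
    coef: float
    se: float
    coef_ci_low: float
    coef_ci_high: float


def effect_plot_data(fit: ModelFit, term: str) -> EffectPlotData:
    """Partial residuals and partial-regression line for one model term.

    Partial residuals are the model residuals plus the term's fitted
    contribution; the partial-regression line has the term's coefficient as
    slope and passes through the covariate-adjusted means. The 95% band
    derives from the coefficient's standard error (exactly
    ``1.96 * se`` per unit of x in the large-df limit).
    """
    res = fit.sm_result
    rows = fit.coefficients[fit.coefficients["term"] == term]
    if rows.empty:
        raise KeyError(f"term {term!r} not in model")
    col_name = rows.index[0]
    coef = float(rows["coef"].iloc[0])
    se = float(rows["se"].iloc[0])
    j = list(res.model.exog_names).index(col_name)
    x = res.model.exog[:, j]
    presid = res.resid.to_numpy() + coef * x

    tcrit = float(sps.t.ppf(0.975, fit.residual_df))
    xbar = x.mean()
    intercept_adj = presid.mean() - coef * xbar
    line = intercept_adj + coef * x
    half = tcrit * se * np.abs(x - xbar)
    table = pd.DataFrame({
        "x": x, "partial_residual": presid, "line": line,
        "line_ci_low": line - half, "line_ci_high": line + half,
    })
    return EffectPlotData(term=term, table=table, coef=coef, se=se,
                          coef_ci_low=coef - tcrit * se,
                          coef_ci_high=coef + tcrit * se)
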