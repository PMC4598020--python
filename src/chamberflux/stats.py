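"""Case-study statistics.

Two questions are answered here.  First, chamber equivalence: do two
chamber designs return the same metabolic rates, tested with a paired t
(same colonies in both chambers) or an independent t (different colonies)?
Second, species x habitat structure: hourly rates are compared across
species and sites with a linear mixed-effects model

    C_ij = alpha + X_ij beta + b_j + eps_ij,   b_j ~ N(0, sigma_d^2)

where C is the metabolic parameter, X the fixed-effect design (species
and/or site contrasts), and b_j a random intercept for sampling day j —
consecutive-day measurements share weather, tide and light, so days are a
grouping factor, not replicates.  Variance components are estimated by
REML; fixed-effect model comparison refits under ML, as REML likelihoods
of models with different fixed effects are not comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "LMESpec",
    "LMEResult",
    "LRTestResult",
    "compare_chambers",
    "fit_metabolic_lme",
    "select_model",
    "residual_diagnostics",
]


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample comparison of one metabolic metric between chamber designs."""

    metric: str
    design: str
    n_a: int
    n_b: int
    t: float
    p: float
    mean_diff: float
    se_diff: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def compare_chambers(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    design: str = "independent",
    metric: str = "rate",
) -> ComparisonResult:
    """Two-sided t comparison of a metabolic metric between two chambers.

    ``design="paired"`` requires equal-length vectors matched by colony
    (the same colonies measured in both chamber types); ``"independent"``
    compares different colonies.  The mean difference (a - b) and its
    standard error are reported as the effect size.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires matched, equal-length vectors")
        d = a - b
        se = float(d.std(ddof=1) / np.sqrt(len(d)))
        if np.allclose(d, d[0]) and np.isclose(se, 0.0):
            # identical or constant-shift pairs: zero-variance difference
            t_stat, p = (0.0, 1.0) if np.isclose(d.mean(), 0.0) else (np.inf, 0.0)
        else:
            t_stat, p = sps.ttest_rel(a, b)
        return ComparisonResult(metric, design, len(a), len(b), float(t_stat),
                                float(p), float(d.mean()), se)
    if design == "independent":
        t_stat, p = sps.ttest_ind(a, b)
        se = float(
            np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        )
        return ComparisonResult(metric, design, len(a), len(b), float(t_stat),
                                float(p), float(a.mean() - b.mean()), se)
    raise ValueError(f"design={design!r}: expected 'paired' or 'independent'")


@dataclass(frozen=True)
class LMESpec:
    """Specification of a random-intercept mixed model.

    ``fixed`` lists categorical fixed effects (e.g. ["species", "site"]);
    ``reference`` pins the treatment-coding reference level per factor, so
    the intercept's meaning is always explicit (refitting with a rotated
    reference changes labels, never fitted values).  ``intercept=False``
    with a single fixed factor gives cell-means coding.  ``group`` is the
    random-intercept grouping column (sampling day).
    """

    response: str
    fixed: Sequence[str] = ("species", "site")
    group: str = "day"
    reference: Dict[str, str] = field(default_factory=dict)
    intercept: bool = True
    reml: bool = True

    def formula(self) -> str:
        terms = []
        for f in self.fixed:
            if f in self.reference:
                terms.append(f"C({f}, Treatment(reference={self.reference[f]!r}))")
            else:
                terms.append(f"C({f})")
        rhs = " + ".join(terms) if terms else "1"
        if not self.intercept:
            rhs = "0 + " + rhs
        return f"{self.response} ~ {rhs}"


@dataclass
class LMEResult:
    """REML (or ML) estimates of an :class:`LMESpec` fit."""

    spec: LMESpec
    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    fittedvalues: pd.Series
    residuals: pd.Series
    n_obs: int
    n_groups: int
    llf: float
    converged: bool
    k_fixed: int

    def conf_int(self, alpha: float = 0.05, df_method: str = "groups") -> pd.DataFrame:
        """Fixed-effect confidence intervals.

        ``df_method="groups"`` uses a t reference with (number of days - 1)
        degrees of freedom — a conservative small-sample choice when the
        day variance is estimated from only a handful of days;
        ``"normal"`` uses the usual Wald z interval.
        """
        if df_method == "groups":
            crit = sps.t.ppf(1 - alpha / 2, df=max(self.n_groups - 1, 1))
        elif df_method == "normal":
            crit = sps.norm.ppf(1 - alpha / 2)
        else:
            raise ValueError(f"df_method={df_method!r}")
        lo = self.params - crit * self.bse
        hi = self.params + crit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _complete_cases(data: pd.DataFrame, spec: LMESpec) -> pd.DataFrame:
    cols = [spec.response, spec.group, *spec.fixed]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data missing columns: {missing}")
    sub = data[cols].copy()
    n_dropped = int(sub.isna().any(axis=1).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} incomplete row(s) before the fit")
        sub = sub.dropna()
    return sub


def fit_metabolic_lme(data: pd.DataFrame, spec: LMESpec) -> LMEResult:
    """Fit the random-intercept mixed model for one metabolic parameter.

    Requires at least two grouping levels (days): with one day the day
    variance is inestimable, and the fit is refused rather than silently
    degraded to an ordinary regression.  Each fixed factor must have at
    least two levels.
    """
    sub = _complete_cases(data, spec)
    n_groups = sub[spec.group].nunique()
    if n_groups < 2:
        raise ValueError(
            f"random effect over {spec.group!r} needs >= 2 levels, got {n_groups}"
        )
    for f in spec.fixed:
        if sub[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has fewer than 2 levels")
        if f in spec.reference and spec.reference[f] not in set(sub[f]):
            raise ValueError(
                f"reference level {spec.reference[f]!r} absent from factor {f!r}"
            )
    formula = spec.formula()
    model = smf.mixedlm(formula, data=sub, groups=sub[spec.group])
    fe_names = model.exog_names
    if np.linalg.matrix_rank(model.exog) < len(fe_names):
        raise ValueError("singular fixed-effect design matrix")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=spec.reml)
        if not np.all(np.isfinite(np.asarray(fit.fe_params))):
            raise np.linalg.LinAlgError("non-finite fixed effects")
        params = pd.Series(np.asarray(fit.fe_params), index=fe_names)
        bse = fit.bse[fe_names]
        tvalues = fit.tvalues[fe_names]
        pvalues = fit.pvalues[fe_names]
        group_var = float(np.squeeze(fit.cov_re))
        resid_var = float(fit.scale)
        llf = float(fit.llf)
        converged = bool(fit.converged)
        # conditional day intercepts; zero when the day variance hits the
        # boundary (the generalized-least-squares limit of no day effect)
        if group_var > 1e-10:
            re = fit.random_effects
            re_vals = np.array(
                [float(np.squeeze(re[g])) for g in sub[spec.group]]
            )
        else:
            re_vals = np.zeros(len(sub))
        fitted_arr = model.exog @ params.to_numpy() + re_vals
    except (np.linalg.LinAlgError, ValueError):
        # degenerate limit (e.g. noiseless data): the mixed fit collapses
        # to ordinary least squares with zero variance components
        ols = sm.OLS(model.endog, model.exog).fit()
        params = pd.Series(np.asarray(ols.params), index=fe_names)
        bse = pd.Series(np.asarray(ols.bse), index=fe_names)
        tvalues = pd.Series(np.asarray(ols.tvalues), index=fe_names)
        pvalues = pd.Series(np.asarray(ols.pvalues), index=fe_names)
        group_var = 0.0
        resid_var = float(ols.scale)
        llf = float(ols.llf)
        converged = True
        fitted_arr = np.asarray(ols.fittedvalues)

    fitted = pd.Series(fitted_arr, index=sub.index)
    resid = sub[spec.response] - fitted
    return LMEResult(
        spec=spec,
        formula=formula,
        params=params,
        bse=bse,
        tvalues=tvalues,
        pvalues=pvalues,
        group_var=group_var,
        resid_var=resid_var,
        fittedvalues=fitted,
        residuals=resid,
        n_obs=len(sub),
        n_groups=int(n_groups),
        llf=llf,
        converged=converged,
        k_fixed=len(fe_names),
    )


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio comparison of nested fixed-effect structures."""

    lr: float
    df: int
    p: float
    full_formula: str
    reduced_formula: str


def _is_nested(full: LMESpec, reduced: LMESpec) -> bool:
    return (
        set(reduced.fixed) <= set(full.fixed)
        and reduced.response == full.response
        and reduced.group == full.group
    )


def select_model(
    data: pd.DataFrame, full: LMESpec, reduced: LMESpec
) -> LRTestResult:
    """Likelihood-ratio test of a reduced against a full fixed-effect model.

    Both models are refit under maximum likelihood internally (REML
    likelihoods are not comparable across fixed-effect structures); the
    statistic is referred to chi-square with df equal to the difference in
    fixed-effect count.
    """
    if not _is_nested(full, reduced):
        raise ValueError("reduced model is not nested in the full model")
    full_ml = fit_metabolic_lme(data, replace_reml(full, False))
    red_ml = fit_metabolic_lme(data, replace_reml(reduced, False))
    df = full_ml.k_fixed - red_ml.k_fixed
    if df < 0:
        raise ValueError("reduced model has more fixed effects than the full model")
    lr = max(2.0 * (full_ml.llf - red_ml.llf), 0.0)
    p = float(sps.chi2.sf(lr, df)) if df > 0 else 1.0
    return LRTestResult(
        lr=float(lr), df=int(df), p=p,
        full_formula=full_ml.formula, reduced_formula=red_ml.formula,
    )


def replace_reml(spec: LMESpec, reml: bool) -> LMESpec:
    return LMESpec(
        response=spec.response,
        fixed=tuple(spec.fixed),
        group=spec.group,
        reference=dict(spec.reference),
        intercept=spec.intercept,
        reml=reml,
    )


def residual_diagnostics(result: LMEResult, data: pd.DataFrame) -> pd.DataFrame:
    """Advisory residual checks, emitted as a table, never as a gate.

    Rows: Shapiro-Wilk normality of residuals; Levene homogeneity of
    residual variance across each fixed factor; residual-vs-fitted
    correlation (should be ~0 for a well-specified mean structure).
    """
    rows = []
    res = np.asarray(result.residuals, dtype=float)
    if 3 <= len(res) <= 5000:
        w, p = sps.shapiro(res)
        rows.append({"check": "shapiro_wilk_residuals", "statistic": float(w),
                     "p": float(p)})
    for f in result.spec.fixed:
        groups = [res[(data.loc[result.residuals.index, f] == lv).to_numpy()]
                  for lv in data.loc[result.residuals.index, f].unique()]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            w, p = sps.levene(*groups)
            rows.append({"check": f"levene_{f}", "statistic": float(w), "p": float(p)})
    if len(res) >= 3 and np.std(res) > 0 and np.std(result.fittedvalues) > 0:
        r, p = sps.pearsonr(result.fittedvalues, res)
        rows.append({"check": "resid_vs_fitted_corr", "statistic": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows, columns=["check", "statistic", "p"])
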