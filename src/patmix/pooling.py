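"""Substantive model, Rubin's rules, and the MAR-vs-MNAR comparison.

The substantive model is a single-level binary logistic regression of
30-day postoperative mortality on Dukes' stage and configured covariates,
fitted to each completed dataset and pooled with Rubin's rules:

    Qbar = mean of estimates
    W    = mean of squared standard errors   (within-imputation variance)
    B    = sample variance of estimates      (between-imputation variance)
    T    = W + (1 + 1/m) B
    nu   = (m - 1) (1 + W / ((1 + 1/m) B))^2   (large-sample MI df)

Odds ratios, Wald confidence intervals and p-values are reported on the
exponentiated scale.  The sensitivity comparison reports, per coefficient,
the relative change in odds ratio (MNAR - MAR)/MAR and flags estimates
that fall outside the other assumption's confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._core import STAGES, ValidationError

__all__ = [
    "SubstantiveFit",
    "PooledFit",
    "SensitivityReport",
    "fit_substantive",
    "rubin_pool",
    "pool_stack",
    "compare_assumptions",
]

#: Reference level per categorical covariate of the substantive model.
REFERENCE_LEVELS = {
    "stage": "A",
    "sex": "F",
    "admission_type": "elective",
    "resection_type": "elective",
    "imd_quintile": 1,
    "charlson_band": "0",
    "tumour_site": "colon",
}

_CATEGORY_ORDERS = {
    "stage": list(STAGES),
    "sex": ["F", "M"],
    "admission_type": ["elective", "emergency"],
    "resection_type": ["elective", "emergency"],
    "imd_quintile": [1, 2, 3, 4, 5],
    "charlson_band": ["0", "1", "2", "3+"],
    "tumour_site": ["colon", "rectosigmoid", "rectum"],
}

DEFAULT_COVARIATES = ("stage", "AGE")


@dataclass(frozen=True)
class SubstantiveFit:
    """One completed-data logistic fit: estimates, covariance, model size."""

    params: pd.Series
    cov: pd.DataFrame
    nobs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def _design_matrix(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy-coded design with fixed reference levels, plus intercept."""
    pieces = [pd.Series(1.0, index=table.index, name="const")]
    for cov in covariates:
        col = table[cov]
        order = _CATEGORY_ORDERS.get(cov)
        if order is not None:
            cat = pd.Categorical(col, categories=order)
            if cat.isna().any() and not col.isna().any():
                raise ValidationError(f"{cov!r} contains levels outside {order}")
            dummies = pd.get_dummies(
                pd.Series(cat, index=table.index), prefix=cov, drop_first=True, dtype=float
            )
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).rename(cov))
    return pd.concat(pieces, axis=1)


def _ridge_logit(y: np.ndarray, X: np.ndarray, ridge: float = 1e-4, max_iter: int = 200):
    """Newton fit of a ridge-penalised logistic model (separation fallback)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - ridge * beta
        w = mu * (1.0 - mu)
        info = (X.T * w) @ X + ridge * np.eye(p)
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(info)
    return beta, cov


def fit_substantive(
    table: pd.DataFrame,
    outcome: str = "MORT",
    covariates=DEFAULT_COVARIATES,
    formula: str | None = None,
    ridge_fallback: float = 1e-4,
) -> SubstantiveFit:
    """Maximum-likelihood logistic fit of the substantive outcome model.

    Categorical covariates are dummy-coded against fixed reference levels
    (stage A, female, elective, quintile 1, colon, Charlson band 0).  On
    separation or non-convergence the fit falls back to a weak ridge
    penalty and warns.  A patsy ``formula`` may be given instead of the
    covariate list.
    """
    if table[outcome].isna().any():
        raise ValidationError(f"outcome {outcome!r} contains missing values")
    if formula is not None:
        import statsmodels.formula.api as smf

        res = smf.logit(formula, data=table).fit(disp=0, maxiter=200)
        return SubstantiveFit(
            params=res.params, cov=pd.DataFrame(res.cov_params()), nobs=int(res.nobs)
        )
    X = _design_matrix(table, covariates)
    y = table[outcome].to_numpy(dtype=float)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("did not converge")
        params = res.params
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    except Exception:
        import warnings

        warnings.warn(
            "substantive logit did not converge (possible separation); "
            f"refitting with ridge penalty {ridge_fallback}",
            RuntimeWarning,
            stacklevel=2,
        )
        beta, cov_arr = _ridge_logit(y, X.to_numpy(), ridge=ridge_fallback)
        params = pd.Series(beta, index=X.columns)
        cov = pd.DataFrame(cov_arr, index=X.columns, columns=X.columns)
    return SubstantiveFit(params=params, cov=cov, nobs=len(table))


@dataclass(frozen=True)
class PooledFit:
    """Rubin-pooled substantive-model inference for one assumption.

    ``table`` is indexed by coefficient with columns estimate, se, W, B, T,
    df, p, ci_low, ci_high (log-odds scale) and odds_ratio, or_ci_low,
    or_ci_high (exponentiated).
    """

    table: pd.DataFrame
    m: int
    assumption: str

    def odds_ratios(self) -> pd.DataFrame:
        return self.table[["odds_ratio", "or_ci_low", "or_ci_high", "p"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="coefficient")

    @classmethod
    def from_odds_ratios(cls, summary: dict, assumption: str, m: int = 10) -> "PooledFit":
        """Build a pooled fit from reported odds ratios and 95% CIs.

        ``summary`` maps coefficient name to (OR, ci_low, ci_high).  The
        log-scale standard error is recovered from the CI width assuming a
        normal Wald interval — the form in which published multiply-imputed
        analyses are reported.
        """
        rows = {}
        for name, (or_, lo, hi) in summary.items():
            est = np.log(or_)
            se = (np.log(hi) - np.log(lo)) / (2.0 * stats.norm.ppf(0.975))
            z = est / se if se > 0 else np.inf
            rows[name] = {
                "estimate": est,
                "se": se,
                "W": se**2,
                "B": 0.0,
                "T": se**2,
                "df": np.inf,
                "p": 2.0 * stats.norm.sf(abs(z)),
                "ci_low": np.log(lo),
                "ci_high": np.log(hi),
                "odds_ratio": or_,
                "or_ci_low": lo,
                "or_ci_high": hi,
            }
        return cls(table=pd.DataFrame(rows).T, m=m, assumption=assumption)


def rubin_pool(
    fits: list,
    assumption: str = "MAR",
    df_method: str = "large-sample",
    complete_df: float | None = None,
) -> PooledFit:
    """Pool m completed-data fits with Rubin's rules.

    ``fits`` is a list of :class:`SubstantiveFit` or ``(params, bse)``
    pairs with identical coefficient names.  ``df_method`` is the
    large-sample MI formula by default; ``'barnard-rubin'`` applies the
    small-sample adjustment and requires ``complete_df`` (n - p of one
    completed-data fit).
    """
    m = len(fits)
    if m < 2:
        raise ValidationError("rubin_pool requires m >= 2 fits")
    if df_method not in ("large-sample", "barnard-rubin"):
        raise ValidationError(f"unknown df_method {df_method!r}")

    def unpack(f):
        if isinstance(f, SubstantiveFit):
            return f.params, f.bse
        params, bse = f
        return pd.Series(params), pd.Series(bse)

    params0, _ = unpack(fits[0])
    names = list(params0.index)
    est = np.empty((m, len(names)))
    var = np.empty((m, len(names)))
    for t, f in enumerate(fits):
        p, s = unpack(f)
        if list(p.index) != names:
            raise ValidationError(
                f"fit {t} has coefficient names {list(p.index)} != {names}"
            )
        est[t] = p.to_numpy(dtype=float)
        var[t] = s.to_numpy(dtype=float) ** 2

    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t_var = w + (1.0 + 1.0 / m) * b
    se = np.sqrt(t_var)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (1.0 + 1.0 / m) * b / w
        nu = (m - 1.0) * (1.0 + 1.0 / np.where(rel > 0, rel, np.inf)) ** 2
    nu = np.where(b > 0, nu, np.inf)
    if df_method == "barnard-rubin":
        if complete_df is None:
            raise ValidationError("barnard-rubin df requires complete_df")
        lam = (1.0 + 1.0 / m) * b / t_var
        nu_obs = (complete_df + 1.0) / (complete_df + 3.0) * complete_df * (1.0 - lam)
        with np.errstate(divide="ignore"):
            nu = 1.0 / (1.0 / nu + 1.0 / nu_obs)

    tcrit = stats.t.ppf(0.975, nu)
    p_val = 2.0 * stats.t.sf(np.abs(qbar) / se, nu)
    ci_low = qbar - tcrit * se
    ci_high = qbar + tcrit * se

    table = pd.DataFrame(
        {
            "estimate": qbar,
            "se": se,
            "W": w,
            "B": b,
            "T": t_var,
            "df": nu,
            "p": p_val,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "odds_ratio": np.exp(qbar),
            "or_ci_low": np.exp(ci_low),
            "or_ci_high": np.exp(ci_high),
        },
        index=pd.Index(names, name="coefficient"),
    )
    return PooledFit(table=table, m=m, assumption=assumption)


def pool_stack(stack, outcome: str = "MORT", covariates=DEFAULT_COVARIATES, **kw) -> PooledFit:
    """Fit the substantive model on every imputation and Rubin-pool."""
    fits = [fit_substantive(df, outcome=outcome, covariates=covariates) for df in stack.imputations]
    return rubin_pool(fits, assumption=stack.assumption, **kw)


@dataclass(frozen=True)
class SensitivityReport:
    """Paired MAR-vs-MNAR comparison of pooled odds ratios.

    ``table`` columns: or_mar, or_mnar (with CIs and p-values),
    pct_change = 100 (OR_MNAR - OR_MAR)/OR_MAR (MAR is always the
    denominator), mar_outside_mnar_ci / mnar_outside_mar_ci flags, and a
    direction-of-association agreement indicator.
    """

    table: pd.DataFrame
    m_mar: int
    m_mnar: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="coefficient")

    def to_json(self) -> str:
        return json.dumps(
            {"comparison": self.table.reset_index().to_dict(orient="records")},
            indent=2,
            default=lambda v: None if pd.isna(v) else float(v) if isinstance(v, (np.floating,)) else v,
        )

    def render(self) -> str:
        """Report-style layout: AOR (95% CI), p per assumption, % change."""
        lines = [
            f"{'coefficient':<28}{'AOR (MAR)':>22}{'p':>8}{'AOR (MNAR)':>22}{'p':>8}{'change':>9}"
        ]
        for name, row in self.table.iterrows():
            mar = f"{row['or_mar']:.2f} ({row['or_mar_ci_low']:.2f}-{row['or_mar_ci_high']:.2f})"
            mnar = f"{row['or_mnar']:.2f} ({row['or_mnar_ci_low']:.2f}-{row['or_mnar_ci_high']:.2f})"
            p1 = "<0.001" if row["p_mar"] < 0.001 else f"{row['p_mar']:.3f}"
            p2 = "<0.001" if row["p_mnar"] < 0.001 else f"{row['p_mnar']:.3f}"
            lines.append(
                f"{name:<28}{mar:>22}{p1:>8}{mnar:>22}{p2:>8}{row['pct_change']:>+8.1f}%"
            )
        return "\n".join(lines)


def compare_assumptions(mar: PooledFit, mnar: PooledFit) -> SensitivityReport:
    """Sensitivity comparison of two pooled fits (MAR vs MNAR).

    Relative changes use the MAR odds ratio as denominator in both
    directions, so a report of "-7.3%" reads "the OR decreases by 7.3%
    under MNAR".  Swapping the labels changes the denominator and hence
    the magnitude, not just the sign.
    """
    if mar.assumption == mnar.assumption:
        raise ValidationError(
            f"both pooled fits carry assumption {mar.assumption!r}; expected one MAR and one MNAR"
        )
    if list(mar.table.index) != list(mnar.table.index):
        raise ValidationError("pooled fits have different coefficient sets")

    a, b = mar.table, mnar.table
    pct = 100.0 * (b["odds_ratio"] - a["odds_ratio"]) / a["odds_ratio"]
    table = pd.DataFrame(
        {
            "or_mar": a["odds_ratio"],
            "or_mar_ci_low": a["or_ci_low"],
            "or_mar_ci_high": a["or_ci_high"],
            "p_mar": a["p"],
            "or_mnar": b["odds_ratio"],
            "or_mnar_ci_low": b["or_ci_low"],
            "or_mnar_ci_high": b["or_ci_high"],
            "p_mnar": b["p"],
            "pct_change": pct,
            "mar_outside_mnar_ci": (a["odds_ratio"] < b["or_ci_low"]) | (a["odds_ratio"] > b["or_ci_high"]),
            "mnar_outside_mar_ci": (b["odds_ratio"] < a["or_ci_low"]) | (b["odds_ratio"] > a["or_ci_high"]),
            "direction_agrees": np.sign(a["estimate"]) == np.sign(b["estimate"]),
        }
    )
    return SensitivityReport(table=table, m_mar=mar.m, m_mnar=mnar.m)
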