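"""Predictors of stage-missingness: indicator + backwards elimination.

First step of the sensitivity analysis: regress a binary indicator of
Dukes' stage being missing on candidate covariates (complete cases of the
candidates) and backwards-eliminate at a 1% level, testing multi-level
categorical covariates with a joint likelihood-ratio test.  The surviving
covariates — in the motivating setting, dichotomised age and 30-day
mortality — define the pattern cells used for elicitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._core import ValidationError

__all__ = ["SelectionResult", "missingness_indicator", "backward_eliminate"]


def missingness_indicator(table: pd.DataFrame, variable: str = "stage") -> pd.Series:
    """Binary indicator: 1 where ``variable`` is missing, else 0."""
    if variable not in table.columns:
        raise ValidationError(f"variable {variable!r} not in table")
    return table[variable].isna().astype(int).rename(f"{variable}_missing")


@dataclass
class SelectionResult:
    """Outcome of backwards elimination on the missingness model.

    ``retained`` rows carry the final-model coefficient summary per level
    plus the covariate's joint LRT p-value; ``eliminated`` rows carry the
    p-value at the step the covariate was dropped.
    """

    retained: pd.DataFrame  # index: covariate; columns incl. joint_p
    retained_levels: pd.DataFrame  # per-level coef, OR, CI, p
    eliminated: pd.DataFrame  # index: covariate; column p_at_elimination
    alpha: float
    candidates: tuple[str, ...]

    def top_k(self, k: int = 2) -> list[str]:
        """The k most predictive retained covariates.

        Ranked by joint p-value, ties broken by the largest |log OR| among
        the covariate's levels (ranking criterion documented in the methods
        note; the field convention is not settled).
        """
        if self.retained.empty:
            return []
        order = self.retained.assign(
            _abs=self.retained["max_abs_coef"]
        ).sort_values(["joint_p", "_abs"], ascending=[True, False])
        return list(order.index[:k])

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "candidates": list(self.candidates),
                "retained": self.retained.reset_index().to_dict(orient="records"),
                "retained_levels": self.retained_levels.reset_index().to_dict(orient="records"),
                "eliminated": self.eliminated.reset_index().to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )

    def __str__(self) -> str:
        lines = [f"Backwards elimination at alpha={self.alpha}"]
        lines.append("Retained:")
        for cov, row in self.retained.iterrows():
            lines.append(f"  {cov}: joint p = {row['joint_p']:.3g}")
        lines.append("Eliminated:")
        for cov, row in self.eliminated.iterrows():
            lines.append(f"  {cov}: p at elimination = {row['p_at_elimination']:.3g}")
        return "\n".join(lines)


def _covariate_columns(table: pd.DataFrame, cov: str) -> pd.DataFrame:
    """Design columns for one covariate: numeric as-is, categorical dummied."""
    col = table[cov]
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
        return pd.DataFrame({cov: col.astype(float)})
    if pd.api.types.is_numeric_dtype(col) and col.nunique() <= 2:
        return pd.DataFrame({cov: col.astype(float)})
    dummies = pd.get_dummies(col.astype("category"), prefix=cov, drop_first=True, dtype=float)
    return dummies


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        return model.fit(disp=0, maxiter=200)
    except Exception as exc:  # non-convergence, separation
        raise ValidationError(f"missingness logit failed to converge: {exc}") from exc


def backward_eliminate(
    table: pd.DataFrame,
    indicator: pd.Series,
    candidates: tuple[str, ...] | list[str],
    alpha: float = 0.01,
) -> SelectionResult:
    """Backwards elimination of missingness predictors at level ``alpha``.

    Fits a logistic regression of the missingness indicator on all
    candidates (complete cases of the candidates), then iteratively drops
    the candidate with the largest joint p-value >= alpha, where the joint
    test is the likelihood-ratio test of all the covariate's levels at
    once.  Deterministic given the data; covariates once dropped are never
    re-entered.
    """
    candidates = tuple(candidates)
    complete = table[list(candidates)].notna().all(axis=1) if candidates else pd.Series(True, index=table.index)
    data = table.loc[complete]
    y = indicator.loc[complete].to_numpy()

    blocks = {cov: _covariate_columns(data, cov) for cov in candidates}
    current = list(candidates)
    eliminated_rows = []

    def fit_for(covs: list[str]):
        if covs:
            X = pd.concat([blocks[c] for c in covs], axis=1)
        else:
            X = pd.DataFrame(index=data.index)
        return _fit_logit(y, X)

    full_fit = fit_for(current)
    while current:
        pvals = {}
        for cov in current:
            reduced = fit_for([c for c in current if c != cov])
            lr = 2.0 * (full_fit.llf - reduced.llf)
            df = blocks[cov].shape[1]
            pvals[cov] = stats.chi2.sf(max(lr, 0.0), df)
        worst = max(current, key=lambda c: pvals[c])
        if pvals[worst] < alpha:
            break
        eliminated_rows.append({"covariate": worst, "p_at_elimination": pvals[worst]})
        current.remove(worst)
        full_fit = fit_for(current)

    # final-model summaries
    retained_rows, level_rows = [], []
    if current:
        final_pvals = {}
        for cov in current:
            reduced = fit_for([c for c in current if c != cov])
            lr = 2.0 * (full_fit.llf - reduced.llf)
            final_pvals[cov] = stats.chi2.sf(max(lr, 0.0), blocks[cov].shape[1])
        ci = full_fit.conf_int()
        for cov in current:
            coefs = []
            for colname in blocks[cov].columns:
                est = full_fit.params[colname]
                coefs.append(abs(est))
                level_rows.append(
                    {
                        "covariate": cov,
                        "term": colname,
                        "coef": est,
                        "odds_ratio": float(np.exp(est)),
                        "ci_low": float(np.exp(ci.loc[colname, 0])),
                        "ci_high": float(np.exp(ci.loc[colname, 1])),
                        "p": float(full_fit.pvalues[colname]),
                    }
                )
            retained_rows.append(
                {"covariate": cov, "joint_p": final_pvals[cov], "max_abs_coef": max(coefs)}
            )

    retained = pd.DataFrame(retained_rows, columns=["covariate", "joint_p", "max_abs_coef"]).set_index("covariate")
    retained_levels = pd.DataFrame(
        level_rows, columns=["covariate", "term", "coef", "odds_ratio", "ci_low", "ci_high", "p"]
    ).set_index("covariate")
    eliminated = pd.DataFrame(eliminated_rows, columns=["covariate", "p_at_elimination"]).set_index("covariate")
    return SelectionResult(
        retained=retained,
        retained_levels=retained_levels,
        eliminated=eliminated,
        alpha=alpha,
        candidates=candidates,
    )
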