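"""Expert elicitation of the missing-data stage distribution.

Experts are shown the MAR-implied stage probabilities per pattern cell and
asked what they believe the probabilities are *in the missing data*.  Their
responses (a probability per expert x cell x stage) are aggregated into
per-cell means pi_rj and between-expert variances V_rj, and a Dirichlet
prior is fitted per cell by moment matching:

    S_rj = pi_rj (1 - pi_rj) / V_rj - 1        (from Var = pi(1-pi)/(S+1))
    E[S_r] = mean_j S_rj                       (per-category estimates pooled)
    gamma_rj = E[S_r] * pi_rj

so that the Dirichlet mean equals the elicited mean and its spread reflects
how much the experts disagreed.  Smaller elicited variances give a larger
concentration S and hence a more confident MNAR prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import CELLS, CELL_LABELS, STAGES, ValidationError

__all__ = [
    "ExpertResponseSet",
    "ElicitedPrior",
    "DirichletSpec",
    "read_questionnaire",
    "aggregate_experts",
    "fit_dirichlet",
    "make_questionnaire_template",
    "synthesize_questionnaire",
    "plot_prior_vs_mar",
    "DEMO_ELICITED_MEANS",
    "DEMO_ELICITED_VARIANCES",
    "LATE_STAGE_SHIFT_MEANS",
    "LATE_STAGE_SHIFT_VARIANCES",
]

#: Per-(expert, cell) probabilities must sum to 1 within this tolerance
#: before renormalisation — questionnaire entries are typically rounded
#: to 2 decimals, so sums of 0.99-1.01 are accepted.
ROW_SUM_TOLERANCE = 0.02

_INDEX = pd.Index(CELLS, name="r")

#: Demonstration elicited prior: consensus beliefs of a small expert panel
#: about the Dukes'-stage distribution of patients whose stage is missing,
#: per age x mortality pattern cell.  The panel believed late-stage (D)
#: disease is markedly more common among the missing than the MAR profile
#: implies, especially among patients who died within 30 days.
DEMO_ELICITED_MEANS = pd.DataFrame(
    [
        [0.21, 0.32, 0.28, 0.19],
        [0.05, 0.17, 0.38, 0.40],
        [0.24, 0.37, 0.23, 0.17],
        [0.08, 0.26, 0.36, 0.29],
    ],
    index=_INDEX,
    columns=list(STAGES),
)

#: Between-expert variances paired with :data:`DEMO_ELICITED_MEANS`.
DEMO_ELICITED_VARIANCES = pd.DataFrame(
    [
        [0.008, 0.010, 0.005, 0.045],
        [0.001, 0.002, 0.002, 0.001],
        [0.013, 0.016, 0.009, 0.046],
        [0.003, 0.010, 0.012, 0.025],
    ],
    index=_INDEX,
    columns=list(STAGES),
)


#: A second bundled prior encoding the belief "patients with missing stage
#: are late-stage, whether or not they survived": the same elevated
#: distribution in every pattern cell.  Because it is flat across cells it
#: weakens the stage-mortality contrast carried by the imputed values and
#: therefore attenuates stage odds ratios relative to MAR — the canonical
#: sensitivity-analysis direction check.  (A prior anchored cell by cell on
#: the MAR profile, like :data:`DEMO_ELICITED_MEANS`, can instead sharpen
#: the contrast; see docs/methods.md.)
LATE_STAGE_SHIFT_MEANS = pd.DataFrame(
    [[0.08, 0.27, 0.35, 0.30]] * 4, index=_INDEX, columns=list(STAGES)
)

#: Between-expert variances paired with :data:`LATE_STAGE_SHIFT_MEANS`.
LATE_STAGE_SHIFT_VARIANCES = pd.DataFrame(
    [[0.002, 0.004, 0.004, 0.004]] * 4, index=_INDEX, columns=list(STAGES)
)


@dataclass(frozen=True)
class ExpertResponseSet:
    """Validated long-format questionnaire responses.

    ``responses`` has columns (expert_id, cell, stage, probability) with one
    row per expert x cell x stage.
    """

    responses: pd.DataFrame
    expert_ids: tuple
    K: int


def read_questionnaire(source) -> ExpertResponseSet:
    """Read and validate a questionnaire CSV (or pre-loaded DataFrame).

    Expected columns: expert_id, cell (1-4), stage (A-D), probability.
    Rejects duplicate (expert, cell, stage) entries, probabilities outside
    [0, 1], and (expert, cell) rows whose four probabilities do not sum to
    1 within :data:`ROW_SUM_TOLERANCE`.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"expert_id", "cell", "stage", "probability"}
    if not required <= set(df.columns):
        raise ValidationError(f"questionnaire must have columns {sorted(required)}")
    df["cell"] = df["cell"].astype(int)
    if not set(df["cell"]) <= set(CELLS):
        raise ValidationError("cell must be one of 1, 2, 3, 4")
    if not set(df["stage"]) <= set(STAGES):
        raise ValidationError("stage must be one of A, B, C, D")
    dup = df.duplicated(subset=["expert_id", "cell", "stage"])
    if dup.any():
        rows = df.loc[dup, ["expert_id", "cell", "stage"]].to_dict(orient="records")
        raise ValidationError(f"duplicate questionnaire entries: {rows}")
    bad = (df["probability"] < 0) | (df["probability"] > 1) | df["probability"].isna()
    if bad.any():
        rows = df.loc[bad, ["expert_id", "cell", "stage", "probability"]].to_dict(orient="records")
        raise ValidationError(f"probabilities outside [0, 1]: {rows}")
    sums = df.groupby(["expert_id", "cell"])["probability"].sum()
    off = sums[(sums - 1.0).abs() > ROW_SUM_TOLERANCE]
    if not off.empty:
        expert, cell = off.index[0]
        raise ValidationError(
            f"probabilities for expert {expert!r}, cell {cell} sum to "
            f"{off.iloc[0]:.3f}, outside 1 +/- {ROW_SUM_TOLERANCE}"
        )
    counts = df.groupby("expert_id")["probability"].count()
    if (counts != len(CELLS) * len(STAGES)).any():
        raise ValidationError("each expert must answer all 4 cells x 4 stages")
    experts = tuple(pd.unique(df["expert_id"]))
    return ExpertResponseSet(responses=df.reset_index(drop=True), expert_ids=experts, K=len(experts))


@dataclass(frozen=True)
class ElicitedPrior:
    """Aggregated expert opinion: means pi_rj and variances V_rj.

    ``pi`` rows are renormalised to sum exactly to 1 (questionnaire rounding
    leaves raw sums at 0.99-1.01); variances are left untouched.
    """

    pi: pd.DataFrame
    var: pd.DataFrame
    K: int

    def __post_init__(self) -> None:
        if ((self.pi <= 0) | (self.pi >= 1)).any().any():
            raise ValidationError(
                "elicited means must be strictly inside (0, 1); a category "
                "believed impossible cannot be given a Dirichlet prior"
            )
        if (self.var < 0).any().any():
            raise ValidationError("elicited variances must be non-negative")

    @classmethod
    def from_arrays(cls, means, variances, K: int = 2) -> "ElicitedPrior":
        """Build directly from 4x4 mean/variance tables (rows r=1..4, cols A-D)."""
        pi = pd.DataFrame(np.asarray(means, dtype=float), index=_INDEX, columns=list(STAGES))
        pi = pi.div(pi.sum(axis=1), axis=0)
        var = pd.DataFrame(np.asarray(variances, dtype=float), index=_INDEX, columns=list(STAGES))
        return cls(pi=pi, var=var, K=K)


def aggregate_experts(response_set: ExpertResponseSet) -> ElicitedPrior:
    """Means and between-expert variances of the elicited probabilities.

    pi_rj is the mean over experts and V_rj the sample variance (divisor
    K - 1), so K >= 2 is required.  Mean rows are renormalised to the
    probability simplex.
    """
    if response_set.K < 2:
        raise ValidationError("at least 2 experts are required to estimate between-expert variance")
    wide = response_set.responses.pivot_table(
        index=["cell"], columns="stage", values="probability", aggfunc="mean"
    ).reindex(index=CELLS, columns=list(STAGES))
    var = response_set.responses.pivot_table(
        index=["cell"], columns="stage", values="probability", aggfunc=lambda s: s.var(ddof=1)
    ).reindex(index=CELLS, columns=list(STAGES))
    wide.index.name = var.index.name = "r"
    return ElicitedPrior.from_arrays(wide.to_numpy(), var.to_numpy(), K=response_set.K)


@dataclass(frozen=True)
class DirichletSpec:
    """Moment-matched Dirichlet prior per pattern cell.

    ``gamma``: 4x4 concentrations; ``s_per_category``: per-category
    concentration-sum estimates S_rj; ``s_mean``: pooled E[S_r] per cell.
    By construction gamma_rj / sum_j gamma_rj equals the elicited mean.
    """

    gamma: pd.DataFrame
    s_per_category: pd.DataFrame
    s_mean: pd.Series
    aggregator: str = "mean"

    def mean(self) -> pd.DataFrame:
        return self.gamma.div(self.gamma.sum(axis=1), axis=0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "aggregator": self.aggregator,
                "gamma": {str(r): list(self.gamma.loc[r]) for r in self.gamma.index},
                "s_mean": {str(r): float(self.s_mean.loc[r]) for r in self.s_mean.index},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DirichletSpec":
        payload = json.loads(text)
        gamma = pd.DataFrame(
            [payload["gamma"][str(r)] for r in CELLS], index=_INDEX, columns=list(STAGES)
        )
        s_mean = pd.Series([payload["s_mean"][str(r)] for r in CELLS], index=_INDEX)
        s_cat = gamma.mul(0.0)  # not round-tripped; derived values only
        return cls(gamma=gamma, s_per_category=s_cat, s_mean=s_mean, aggregator=payload["aggregator"])


_AGGREGATORS = ("mean", "median", "precision")


def fit_dirichlet(
    prior: ElicitedPrior,
    aggregator: str = "mean",
    variance_floor: float | None = None,
) -> DirichletSpec:
    """Moment-match a Dirichlet prior per cell to the elicited moments.

    Per cell r: S_rj = pi_rj(1-pi_rj)/V_rj - 1 from the Dirichlet marginal
    variance pi(1-pi)/(S+1); the per-category estimates are pooled into
    E[S_r] by the chosen ``aggregator`` ('mean' — arithmetic mean, the
    default; 'median'; 'precision' — weighting each S_rj by the inverse of
    its implied variance contribution pi_rj(1-pi_rj)); finally
    gamma_rj = E[S_r] * pi_rj.

    ``variance_floor`` (default None) replaces smaller variances before
    fitting; with the default, a zero variance is an error.
    """
    if aggregator not in _AGGREGATORS:
        raise ValidationError(f"unknown aggregator {aggregator!r}; expected one of {_AGGREGATORS}")
    pi = prior.pi.to_numpy()
    var = prior.var.to_numpy(copy=True)
    if variance_floor is not None:
        var = np.maximum(var, variance_floor)
    if (var == 0).any():
        raise ValidationError(
            "elicited variance is zero for some category (all experts agreed "
            "exactly); the implied prior is degenerate — set a variance_floor"
        )
    bernoulli = pi * (1.0 - pi)
    if (var >= bernoulli).any():
        r_idx, j_idx = np.argwhere(var >= bernoulli)[0]
        raise ValidationError(
            f"elicited variance {var[r_idx, j_idx]:.4g} for cell {CELLS[r_idx]}, "
            f"stage {STAGES[j_idx]} is >= pi(1-pi) = {bernoulli[r_idx, j_idx]:.4g}; "
            "implied concentration would be non-positive"
        )
    s = bernoulli / var - 1.0
    if aggregator == "mean":
        s_pooled = s.mean(axis=1)
    elif aggregator == "median":
        s_pooled = np.median(s, axis=1)
    else:  # precision
        w = bernoulli
        s_pooled = (s * w).sum(axis=1) / w.sum(axis=1)
    gamma = s_pooled[:, None] * pi
    return DirichletSpec(
        gamma=pd.DataFrame(gamma, index=_INDEX, columns=list(STAGES)),
        s_per_category=pd.DataFrame(s, index=_INDEX, columns=list(STAGES)),
        s_mean=pd.Series(s_pooled, index=_INDEX, name="E[S_r]"),
        aggregator=aggregator,
    )


def make_questionnaire_template(cell_table, path=None) -> pd.DataFrame:
    """Questionnaire template embedding the MAR profile as reference columns.

    One row per cell x stage with the MAR-implied probability (rounded to
    2 decimals, as shown to experts) and an empty ``probability`` column
    for the expert to fill in.
    """
    rows = []
    probs = cell_table.rounded(2) if hasattr(cell_table, "rounded") else pd.DataFrame(cell_table).round(2)
    for r in CELLS:
        for stage in STAGES:
            rows.append(
                {
                    "cell": r,
                    "cell_description": CELL_LABELS[r],
                    "stage": stage,
                    "mar_probability": float(probs.loc[r, stage]),
                    "probability": "",
                }
            )
    template = pd.DataFrame(rows)
    if path is not None:
        template.to_csv(path, index=False)
    return template


def synthesize_questionnaire(
    means, variances, n_experts: int = 6, seed: int = 0, decimals: int = 3
) -> pd.DataFrame:
    """Synthetic questionnaire whose aggregate approximates given moments.

    Draws each synthetic expert's per-cell probability vector from a
    Dirichlet whose mean is ``means`` and whose concentration is moment-
    matched to ``variances``, then rounds to ``decimals``.  Used for demos
    and tests in place of a real expert panel.
    """
    pi = pd.DataFrame(np.asarray(means, dtype=float), index=_INDEX, columns=list(STAGES))
    pi = pi.div(pi.sum(axis=1), axis=0)
    var = np.asarray(variances, dtype=float)
    s = ((pi.to_numpy() * (1 - pi.to_numpy())) / var - 1.0).mean(axis=1)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xE11C)))
    rows = []
    for v in range(1, n_experts + 1):
        for i, r in enumerate(CELLS):
            draw = rng.dirichlet(s[i] * pi.to_numpy()[i])
            draw = np.round(draw, decimals)
            draw[-1] = round(1.0 - draw[:-1].sum(), decimals)  # keep the row on the simplex
            for j, stage in enumerate(STAGES):
                rows.append(
                    {"expert_id": f"expert_{v}", "cell": r, "stage": stage, "probability": float(draw[j])}
                )
    return pd.DataFrame(rows)


def plot_prior_vs_mar(prior: ElicitedPrior, cell_table, path=None):
    """Dot plot of elicited means against the MAR profile, one panel per cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mar = cell_table.probs if hasattr(cell_table, "probs") else pd.DataFrame(cell_table)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    x = np.arange(len(STAGES))
    for ax, r in zip(axes.ravel(), CELLS):
        ax.plot(x, mar.loc[r], "o-", label="MAR profile")
        ax.errorbar(
            x,
            prior.pi.loc[r],
            yerr=3 * np.sqrt(prior.var.loc[r].to_numpy() / prior.K),
            fmt="s",
            capsize=3,
            label="elicited mean",
        )
        ax.set_xticks(x, STAGES)
        ax.set_title(CELL_LABELS[r], fontsize=9)
        ax.set_ylim(0, None)
    axes[0, 0].legend(fontsize=8)
    fig.suptitle("Elicited missing-data stage beliefs vs MAR profile")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
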