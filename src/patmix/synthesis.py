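"""Synthetic colorectal-cancer registry generator.

The real motivating data — a national registry of patients who underwent
major resection for colorectal cancer, with Dukes' stage partially missing —
are not publicly deposited.  This module generates registries with the same
analytic structure so that every downstream stage of the sensitivity
analysis (imputation, profiling, elicitation, re-imputation, pooling) is
testable end to end:

* covariates: age in years (and its dichotomisation AGE at 70), 30-day
  postoperative mortality MORT, sex, deprivation quintile, admission type,
  Charlson comorbidity band, tumour site, resection type, year of diagnosis;
* Dukes' stage (A-D) drawn from a multinomial logistic model with MORT and
  AGE as covariates — the same two-covariate family the analysis profiles,
  so parameter recovery is a well-posed check;
* a missingness mechanism that blanks stage with a configurable rate per
  pattern cell r (age x mortality), optionally shifted per true stage to
  create a genuinely MNAR mechanism.

Default cell-wise missingness rates are (0.16, 0.25, 0.14, 0.22) for
r = 1..4: missingness is roughly 60% more common among patients who died
within 30 days of surgery, which is what makes the stage distribution of
the missing group clinically contentious and worth eliciting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import (
    CELLS,
    STAGES,
    ValidationError,
    categorical_draw,
    check_probability,
    derived_rng,
    pattern_cell,
    softmax_reference,
)

MECHANISMS = ("MCAR", "MAR-on-cells", "MNAR-on-stage")

#: Column order of a registry table as written to CSV.
REGISTRY_COLUMNS = (
    "age_years",
    "AGE",
    "MORT",
    "stage",
    "sex",
    "imd_quintile",
    "admission_type",
    "charlson_band",
    "tumour_site",
    "resection_type",
    "year_dx",
    "r",
)


@dataclass(frozen=True)
class StageLogitParams:
    """Reference-category multinomial-logit parameters for Dukes' stage.

    For j in (B, C, D): log P(stage=j)/P(stage=A) = alpha_j
    + beta_mort_j * MORT + beta_age_j * AGE.
    """

    alpha: tuple[float, float, float] = (0.990, 1.099, -0.080)
    beta_mort: tuple[float, float, float] = (0.364, 0.536, 0.996)
    beta_age: tuple[float, float, float] = (0.206, -0.080, -0.405)

    def linear_predictor(self, mort: np.ndarray, age: np.ndarray) -> np.ndarray:
        """(n, 3) array of log-odds of stages B, C, D versus A."""
        a = np.asarray(self.alpha, dtype=float)
        bm = np.asarray(self.beta_mort, dtype=float)
        ba = np.asarray(self.beta_age, dtype=float)
        return a[None, :] + np.outer(mort, bm) + np.outer(age, ba)

    def cell_probabilities(self) -> pd.DataFrame:
        """Implied stage distribution per pattern cell r=1..4 (rows sum to 1)."""
        age = np.array([0, 0, 1, 1], dtype=float)
        mort = np.array([0, 1, 0, 1], dtype=float)
        probs = softmax_reference(self.linear_predictor(mort, age))
        return pd.DataFrame(probs, index=pd.Index(CELLS, name="r"), columns=list(STAGES))


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for 30-day mortality given stage and dichotomised age.

    When configured, the generator draws stage given AGE only (the stage
    model's MORT coefficients are unused) and then mortality given stage,
    so the joint distribution is a coherent DAG with mortality downstream
    of stage — the setting needed to study attenuation of stage odds
    ratios under MNAR re-imputation.
    """

    intercept: float = -3.8
    stage: tuple[float, float, float] = (0.215, 0.432, 0.908)  # log-OR of B, C, D vs A
    age: float = 0.916  # log-OR for age > 70


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of a synthetic registry draw.

    Covariate marginals default to values typical of a large colorectal
    resection registry (about 53% of patients over 70; 30-day mortality
    6.8%; three-quarters elective admissions).  Stage-model defaults give
    cell-wise stage distributions of the shape seen in such registries:
    stage C most common, stage D enriched among early deaths.
    """

    n_patients: int = 20_000
    stage_logit_params: StageLogitParams = field(default_factory=StageLogitParams)
    p_age: float = 0.53
    p_mort: float = 0.068
    p_male: float = 0.55
    imd_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    admission_probs: tuple[float, float] = (0.75, 0.25)  # elective, emergency
    charlson_probs: tuple[float, ...] = (0.70, 0.18, 0.08, 0.04)  # bands 0,1,2,3+
    site_probs: tuple[float, ...] = (0.60, 0.10, 0.30)  # colon, rectosigmoid, rectum
    resection_probs: tuple[float, float] = (0.75, 0.25)  # elective, emergency
    outcome_model: OutcomeModel | None = None
    missingness_rates: tuple[float, float, float, float] = (0.16, 0.25, 0.14, 0.22)
    mechanism: str = "MAR-on-cells"
    mnar_shift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError(f"n_patients must be positive; got {self.n_patients}")
        for name in ("p_age", "p_mort", "p_male"):
            check_probability(name, getattr(self, name))
        for name, probs, k in (
            ("imd_probs", self.imd_probs, 5),
            ("admission_probs", self.admission_probs, 2),
            ("charlson_probs", self.charlson_probs, 4),
            ("site_probs", self.site_probs, 3),
            ("resection_probs", self.resection_probs, 2),
        ):
            check_probability(name, probs)
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-8:
                raise ValidationError(f"{name} must be {k} probabilities summing to 1")
        if len(self.missingness_rates) != 4:
            raise ValidationError("missingness_rates must have exactly 4 entries (cells r=1..4)")
        check_probability("missingness_rates", self.missingness_rates)
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if len(self.mnar_shift) != 4:
            raise ValidationError("mnar_shift must have one entry per stage A-D")
        shifts_zero = all(s == 0.0 for s in self.mnar_shift)
        if self.mechanism == "MNAR-on-stage" and shifts_zero:
            raise ValidationError("mechanism=MNAR-on-stage requires a nonzero mnar_shift")
        if self.mechanism != "MNAR-on-stage" and not shifts_zero:
            raise ValidationError("mnar_shift must be all zero unless mechanism=MNAR-on-stage")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def generate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a complete synthetic registry (no missing values).

    Stage is drawn from the configured multinomial logit given (AGE, MORT).
    If an :class:`OutcomeModel` is configured, the causal order is reversed:
    stage given AGE, then MORT given stage — see :class:`OutcomeModel`.
    Bit-reproducible given ``config.seed``.
    """
    config.validate()
    rng = derived_rng(config.seed, 0)
    n = config.n_patients

    age_years = rng.uniform(40.0, 90.0, n)
    age = (age_years > 70.0).astype(int)
    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    imd = categorical_draw(rng, np.tile(config.imd_probs, (n, 1))) + 1
    admission = np.where(rng.random(n) < config.admission_probs[1], "emergency", "elective")
    charlson = np.array(["0", "1", "2", "3+"])[categorical_draw(rng, np.tile(config.charlson_probs, (n, 1)))]
    site = np.array(["colon", "rectosigmoid", "rectum"])[categorical_draw(rng, np.tile(config.site_probs, (n, 1)))]
    resection = np.where(rng.random(n) < config.resection_probs[1], "emergency", "elective")
    year_dx = rng.integers(1998, 2007, n)

    slp = config.stage_logit_params
    if config.outcome_model is None:
        mort = (rng.random(n) < config.p_mort).astype(int)
        stage_probs = softmax_reference(slp.linear_predictor(mort, age))
        stage_idx = categorical_draw(rng, stage_probs)
    else:
        stage_probs = softmax_reference(slp.linear_predictor(np.zeros(n), age))
        stage_idx = categorical_draw(rng, stage_probs)
        om = config.outcome_model
        stage_effect = np.concatenate([[0.0], om.stage])[stage_idx]
        eta = om.intercept + stage_effect + om.age * age
        mort = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    df = pd.DataFrame(
        {
            "age_years": age_years,
            "AGE": age,
            "MORT": mort,
            "stage": np.array(STAGES)[stage_idx],
            "sex": sex,
            "imd_quintile": imd,
            "admission_type": admission,
            "charlson_band": charlson,
            "tumour_site": site,
            "resection_type": resection,
            "year_dx": year_dx,
            "r": pattern_cell(age, mort),
        },
        columns=list(REGISTRY_COLUMNS),
    )
    return df


def apply_missingness(
    table: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Blank the stage column according to the configured mechanism.

    Returns ``(masked_table, mask)`` where ``mask`` is a boolean Series over
    the input index marking the entries that were set to missing (the truth
    mask).  The mask exists so that recovery tests can compare imputations
    against the generating values; analysis modules must never consume it.

    Mechanisms:

    * ``MCAR`` — a single rate, the mean of the four cell rates, for all rows;
    * ``MAR-on-cells`` — each patient's cell rate (depends only on AGE, MORT);
    * ``MNAR-on-stage`` — the cell rate's log-odds shifted by
      ``mnar_shift[stage]``, so missingness depends on the value itself.
    """
    config.validate()
    if table["stage"].isna().any():
        raise ValidationError("input table must be complete before applying missingness")
    rng = derived_rng(config.seed, 1)
    rates = np.asarray(config.missingness_rates, dtype=float)
    r = table["r"].to_numpy()

    if config.mechanism == "MCAR":
        p = np.full(len(table), rates.mean())
    elif config.mechanism == "MAR-on-cells":
        p = rates[r - 1]
    elif config.mechanism == "MNAR-on-stage":
        stage_idx = pd.Categorical(table["stage"], categories=list(STAGES)).codes
        shift = np.asarray(config.mnar_shift, dtype=float)[stage_idx]
        with np.errstate(divide="ignore"):
            logit = np.log(rates[r - 1]) - np.log1p(-rates[r - 1])
        p = 1.0 / (1.0 + np.exp(-(logit + shift)))
        p[rates[r - 1] == 0.0] = 0.0
    else:  # pragma: no cover - validate() already rejects this
        raise ValidationError(f"unknown mechanism {config.mechanism!r}")

    mask = pd.Series(rng.random(len(table)) < p, index=table.index, name="stage_missing")
    out = table.copy()
    out.loc[mask, "stage"] = np.nan
    return out, mask


def write_registry_csv(table: pd.DataFrame, path) -> None:
    """Write a registry as CSV, missing stage encoded as an empty field."""
    table.to_csv(path, index=False)


def read_registry_csv(path) -> pd.DataFrame:
    """Read a registry CSV, recomputing the derived pattern cell r."""
    df = pd.read_csv(path, dtype={"stage": "string"})
    df["stage"] = df["stage"].astype(object).where(df["stage"].notna(), np.nan)
    for col in ("AGE", "MORT"):
        if col not in df.columns:
            raise ValidationError(f"registry CSV missing required column {col!r}")
    df["r"] = pattern_cell(df["AGE"], df["MORT"])
    return df
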