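"""Pattern-mixture MNAR re-imputation.

The bridge from MAR to MNAR: for each MAR-imputed dataset and each pattern
cell r, draw one probability vector from the elicited Dirichlet prior and
redraw every originally-missing stage in that cell from the corresponding
categorical distribution, replacing the MAR-imputed value.  Observed values
are untouched, so the observed- and missing-data stage distributions now
differ — the defining feature of a pattern-mixture MNAR model.

One Dirichlet draw is taken per (imputation x cell) by default: the draw
varies across imputations, so the prior's spread propagates into the
between-imputation variance that Rubin's rules capture.  A per-record
variant is exposed for comparison; it averages the prior away within each
imputation and understates prior uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import CELLS, STAGES, ValidationError, categorical_draw, spawn_rngs
from .elicitation import DirichletSpec
from .impute import ImputationStack

__all__ = ["mnar_reimpute"]

_REIMPUTE_STREAM = 0xD112


def mnar_reimpute(
    stack: ImputationStack,
    spec: DirichletSpec,
    mask: pd.Series | None = None,
    seed: int = 0,
    granularity: str = "cell",
) -> ImputationStack:
    """Replace MAR-imputed stages with Dirichlet-categorical draws.

    ``mask`` marks the originally-missing stage entries (defaults to the
    stack's own record).  A mask naming an entry the stack observed is an
    information-barrier breach and raises.  Reproducible given ``seed``.
    """
    if granularity not in ("cell", "record"):
        raise ValidationError(f"unknown draw granularity {granularity!r}; expected 'cell' or 'record'")
    if stack.assumption != "MAR":
        raise ValidationError(f"expected a MAR stack; got assumption={stack.assumption!r}")
    if "stage" not in stack.missing_mask.columns:
        raise ValidationError("stack has no imputed stage values to replace")
    original_missing = stack.missing_mask["stage"]
    if mask is None:
        mask = original_missing
    mask = mask.astype(bool)
    breach = mask & ~original_missing
    if breach.any():
        raise ValidationError(
            f"mask marks {int(breach.sum())} entries whose stage was observed; "
            "only originally-missing values may be re-imputed"
        )

    gamma = spec.gamma
    rngs = spawn_rngs(seed, _REIMPUTE_STREAM, stack.m)
    stages = np.array(STAGES)

    new_imputations = []
    for t, df in enumerate(stack.imputations):
        rng = rngs[t]
        out = df.copy()
        r_values = out["r"].to_numpy()
        for r in CELLS:
            in_cell = mask.to_numpy() & (r_values == r)
            n_cell = int(in_cell.sum())
            if n_cell == 0:
                continue
            if r not in gamma.index:
                raise ValidationError(f"Dirichlet spec has no cell r={r}")
            g = gamma.loc[r].to_numpy()
            if granularity == "cell":
                p = rng.dirichlet(g)
                codes = categorical_draw(rng, np.tile(p, (n_cell, 1)))
            else:
                p_each = rng.dirichlet(g, size=n_cell)
                codes = categorical_draw(rng, p_each)
            out.loc[in_cell, "stage"] = stages[codes]
        new_imputations.append(out)

    return ImputationStack(
        imputations=new_imputations,
        assumption="MNAR",
        missing_mask=stack.missing_mask,
        m=stack.m,
        cycles=stack.cycles,
        seed=seed,
    )
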