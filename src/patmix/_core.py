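"""Shared constants and small numeric helpers used across the package."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Dukes' stage categories, least (A) to most (D) severe. Stage A is the
#: reference category everywhere a reference is needed.
STAGES: tuple[str, ...] = ("A", "B", "C", "D")
N_STAGES = len(STAGES)

#: Human-readable labels for the four missingness-pattern cells r = 1..4,
#: defined by dichotomised age (<=70 / >70) x 30-day mortality (alive/dead).
CELL_LABELS: dict[int, str] = {
    1: "alive 30 days after surgery, age <= 70",
    2: "dead 30 days after surgery, age <= 70",
    3: "alive 30 days after surgery, age > 70",
    4: "dead 30 days after surgery, age > 70",
}
CELLS = (1, 2, 3, 4)


class ValidationError(ValueError):
    """Raised when an input table, config or questionnaire fails validation."""


def pattern_cell(age: np.ndarray | pd.Series, mort: np.ndarray | pd.Series) -> np.ndarray:
    """Map dichotomised age and 30-day mortality to the pattern cell r.

    r = 1 for (AGE=0, MORT=0), 2 for (AGE=0, MORT=1),
    r = 3 for (AGE=1, MORT=0), 4 for (AGE=1, MORT=1).
    """
    return 1 + 2 * np.asarray(age, dtype=int) + np.asarray(mort, dtype=int)


def softmax_reference(eta: np.ndarray) -> np.ndarray:
    """Probabilities from reference-category logits.

    ``eta`` has shape (n, K-1): log-odds of categories 2..K versus the
    reference (first) category.  Returns an (n, K) row-stochastic matrix.
    """
    eta = np.asarray(eta, dtype=float)
    full = np.column_stack([np.zeros(len(eta)), eta])
    full -= full.max(axis=1, keepdims=True)  # overflow guard
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def categorical_draw(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorised draw of category codes 0..K-1, one per row of ``probs``."""
    probs = np.asarray(probs, dtype=float)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0  # guard against rounding shortfall
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1)


def check_probability(name: str, value) -> None:
    """Raise :class:`ValidationError` naming ``name`` unless value(s) in [0, 1]."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError(f"{name} must be a probability in [0, 1]; got {value!r}")


def derived_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named stream of a run-level seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


def spawn_rngs(seed: int, stream: int, n: int) -> list[np.random.Generator]:
    """n independent child generators for a named stream (one per imputation)."""
    ss = np.random.SeedSequence((int(seed), int(stream)))
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def draw_mvnormal(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """One multivariate-normal draw via Cholesky, with a jitter fallback."""
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(1.0, np.trace(cov) / len(mean))
        chol = np.linalg.cholesky(cov + jitter * np.eye(len(mean)))
    return mean + chol @ rng.standard_normal(len(mean))
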