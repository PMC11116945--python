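"""Permutation variable importance of RA site scores on environment + space.

A bagged ensemble of regression trees is fit with the first-axis site scores
as response and the soil variables plus plot coordinates as predictors.
Importance of a variable is the mean percent increase in out-of-bag squared
error when that variable is shuffled (the %IncMSE convention). Per-variable
significance comes from a response-permutation null: the whole procedure is
refit on shuffled responses and the observed importance is compared to the
resulting null importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .core import ValidationError

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p: float) -> str:
    for level, code in STAR_LEVELS:
        if p < level:
            return code
    return "ns"


@dataclass
class ImportanceResult:
    """Per-variable importances sorted from greatest to least."""

    table: pd.DataFrame  # columns: variable, importance, p, rank, signif
    n_trees: int
    n_perms: int
    seed: int
    settings: dict = field(default_factory=dict)


def _oob_importances(
    x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean % increase in OOB MSE per variable for one bagged forest."""
    n, p = x.shape
    max_features = max(1, p // 3)  # regression-forest mtry convention
    base_sse = 0.0
    perm_sse = np.zeros(p)
    n_oob_total = 0
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[idx], y[idx])
        resid = y[oob] - tree.predict(x[oob])
        base_sse += float(resid @ resid)
        n_oob_total += oob.size
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            rj = y[oob] - tree.predict(xp)
            perm_sse[j] += float(rj @ rj)
    if n_oob_total == 0 or base_sse == 0.0:
        raise ValidationError("degenerate forest: no out-of-bag error")
    return 100.0 * (perm_sse - base_sse) / base_sse


def importance_analysis(
    site_scores: np.ndarray,
    variables: pd.DataFrame,
    n_trees: int = 500,
    n_perms: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Rank environmental/spatial variables by permutation importance.

    Parameters
    ----------
    site_scores : array-like, one value per sample (the gradient response).
    variables : DataFrame of predictors, typically SM, ST, pH, STC, STN, STP,
        longitude, latitude, aligned to the same samples.
    n_trees : trees in each bagged ensemble.
    n_perms : response permutations for the significance null.

    Returns
    -------
    ImportanceResult with one row per variable: importance (% increase in
    OOB MSE), permutation p, rank (1 = most important) and a star code.
    """
    y = np.asarray(site_scores, dtype=float)
    x = variables.to_numpy(dtype=float)
    if y.ndim != 1 or x.shape[0] != y.size:
        raise ValidationError("site_scores and variables must align by sample")
    if y.size < 8:
        raise ValidationError("importance analysis needs at least 8 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values in inputs")
    if np.ptp(y) == 0:
        raise ValidationError("constant response: no gradient to explain")

    rng = np.random.default_rng(seed)
    obs = _oob_importances(x, y, n_trees, rng)

    exceed = np.zeros(x.shape[1])
    for _ in range(n_perms):
        y_null = rng.permutation(y)
        null_imp = _oob_importances(x, y_null, n_trees, rng)
        exceed += null_imp >= obs
    p_vals = (1.0 + exceed) / (1.0 + n_perms)

    order = np.argsort(-obs, kind="stable")
    table = pd.DataFrame(
        {
            "variable": variables.columns[order],
            "importance": obs[order],
            "p": p_vals[order],
            "rank": np.arange(1, x.shape[1] + 1),
            "signif": [significance_code(p) for p in p_vals[order]],
        }
    ).reset_index(drop=True)
    return ImportanceResult(
        table=table,
        n_trees=n_trees,
        n_perms=n_perms,
        seed=seed,
        settings={"max_features": max(1, x.shape[1] // 3)},
    )
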