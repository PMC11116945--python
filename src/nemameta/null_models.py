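"""Randomization engines and null-distribution bookkeeping.

Two randomizations are used throughout:

* ``row_fixed`` — every null matrix keeps each site's richness (row sum) and
  places presences in columns with probability proportional to the observed
  genus totals. This is the convention of standard metacommunity-structure
  software and drives the coherence/turnover nulls.
* ``fixed_fixed`` — a sequential checkerboard-swap Markov chain that preserves
  both row and column sums exactly; it drives the co-occurrence (C-score)
  null. Samples are taken from one chain after a burn-in of 10x the matrix
  fill, thinned by one fill's worth of attempted swaps.

Observed statistics are compared to a null by a Z-test:
z = (obs - mean_null) / sd_null, with a two-tailed normal p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .core import IncidenceMatrix

NULL_METHODS = ("row_fixed", "fixed_fixed")


class DegenerateNullError(ValueError):
    """Raised when a null distribution has zero spread."""


@dataclass
class NullDistribution:
    """Simulated statistic values with summary moments and provenance."""

    values: np.ndarray
    method: str
    seed: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a null distribution needs at least 2 simulations")
        if self.sd == 0.0:
            self.degenerate = True

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    @property
    def n_sims(self) -> int:
        return int(self.values.size)

    def to_frame(self):
        """Values plus provenance as a DataFrame (one row per simulation)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "sim": np.arange(self.n_sims),
                "value": self.values,
                "method": self.method,
                "seed": self.seed,
            }
        )

    def to_csv(self, path, sep: str = ",") -> None:
        """Serialize the full distribution to delimited text for audit."""
        self.to_frame().to_csv(path, sep=sep, index=False)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def randomize_row_fixed(m: IncidenceMatrix, seed) -> IncidenceMatrix:
    """Row-sum-preserving randomization with column-proportional placement.

    Each row receives exactly its observed number of presences, in columns
    drawn without replacement with probability proportional to the observed
    column totals.
    """
    rng = _as_rng(seed)
    data = m.data
    n, p = data.shape
    col_prob = data.sum(axis=0).astype(float)
    col_prob /= col_prob.sum()
    out = np.zeros_like(data)
    row_sums = data.sum(axis=1)
    for i in range(n):
        k = int(row_sums[i])
        if k > p:
            raise ValueError("row sum exceeds number of columns")
        cols = rng.choice(p, size=k, replace=False, p=col_prob)
        out[i, cols] = 1
    return IncidenceMatrix(out, list(m.row_labels), list(m.col_labels))


def swap_fixed_fixed(m: IncidenceMatrix, n_swaps: int, seed) -> IncidenceMatrix:
    """Attempt ``n_swaps`` random 2x2 checkerboard swaps (margins preserved).

    Each attempt picks two distinct rows and two distinct columns; if the 2x2
    submatrix is a checkerboard it is flipped, otherwise nothing happens. A
    matrix with no checkerboard submatrix is returned unchanged.
    """
    rng = _as_rng(seed)
    out = m.data.copy()
    _swap_inplace(out, n_swaps, rng)
    return IncidenceMatrix(out, list(m.row_labels), list(m.col_labels))


def _swap_inplace(data: np.ndarray, n_swaps: int, rng: np.random.Generator) -> None:
    n, p = data.shape
    if n < 2 or p < 2 or n_swaps <= 0:
        return
    # Draw attempt indices in chunks to keep the Python loop tight.
    chunk = min(n_swaps, 16384)
    done = 0
    while done < n_swaps:
        todo = min(chunk, n_swaps - done)
        r1 = rng.integers(0, n, size=todo)
        r2 = rng.integers(0, n - 1, size=todo)
        r2 += r2 >= r1  # distinct second row, uniform over the rest
        c1 = rng.integers(0, p, size=todo)
        c2 = rng.integers(0, p - 1, size=todo)
        c2 += c2 >= c1
        for t in range(todo):
            a, b, x, y = r1[t], r2[t], c1[t], c2[t]
            d_ax = data[a, x]
            if d_ax == data[b, y] and data[a, y] == data[b, x] and d_ax != data[a, y]:
                data[a, x] = data[b, y] = 1 - d_ax
                data[a, y] = data[b, x] = d_ax
        done += todo


def null_distribution(
    stat: Callable[[IncidenceMatrix], float],
    m: IncidenceMatrix,
    method: str = "row_fixed",
    n_sims: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Simulate the null distribution of ``stat`` under a randomization.

    ``row_fixed`` draws independent matrices, one per simulation, each from a
    counter-derived child seed so results do not depend on evaluation order.
    ``fixed_fixed`` samples one swap chain: burn-in of 10x fill attempted
    swaps, then one sample every fill attempted swaps.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be at least 2")
    if method not in NULL_METHODS:
        raise ValueError(f"unknown null method: {method!r}")
    values = np.empty(n_sims, dtype=float)
    if method == "row_fixed":
        children = np.random.SeedSequence(seed).spawn(n_sims)
        for i in range(n_sims):
            values[i] = stat(randomize_row_fixed(m, np.random.default_rng(children[i])))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        fill = max(m.fill, 1)
        data = m.data.copy()
        labels = (list(m.row_labels), list(m.col_labels))
        _swap_inplace(data, 10 * fill, rng)  # burn-in
        for i in range(n_sims):
            _swap_inplace(data, fill, rng)  # thinning
            values[i] = stat(IncidenceMatrix(data.copy(), *labels))
    return NullDistribution(values=values, method=method, seed=seed)


def z_and_p(obs: float, null: NullDistribution) -> tuple[float, float]:
    """Z-score of an observation against a null, with two-tailed normal p."""
    if null.sd == 0.0:
        raise DegenerateNullError("degenerate null: zero standard deviation")
    z = (obs - null.mean) / null.sd
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def z_from_moments(obs: float, mean: float, sd: float) -> tuple[float, float]:
    """Z-test from printed summary moments (mean, SD) of a null."""
    if sd <= 0.0:
        raise DegenerateNullError("degenerate null: zero standard deviation")
    z = (obs - mean) / sd
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
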