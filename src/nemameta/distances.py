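"""Dissimilarity matrices and the Mantel test.

Community dissimilarity is Bray-Curtis on abundances; environmental distance
is Euclidean on standardized soil variables; spatial distance defaults to
great-circle kilometres on plot coordinates (plain Euclidean on decimal
degrees is available). The Mantel test correlates two distance matrices by
Spearman rank correlation of their condensed (upper-triangle) entries, with a
permutation p-value from relabelling one matrix. The default alternative is
one-tailed positive (the distance-decay direction).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core import EnvTable, ValidationError

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    data: np.ndarray
    labels: list
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix must be square")
        if not np.allclose(self.data, self.data.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if (self.data < 0).any():
            raise ValidationError("distances must be non-negative")
        if len(self.labels) != n:
            raise ValidationError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    alternative: str


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("abundances must be non-negative")
    zero = vals.sum(axis=1) == 0
    if zero.any():
        raise ValidationError(
            f"all-zero abundance rows: {list(counts.index[zero])}"
        )
    return DistanceMatrix(
        squareform(pdist(vals, metric="braycurtis")),
        labels=list(counts.index),
        kind="bray_curtis",
    )


def euclidean_env(env: EnvTable | pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (by default z-standardized) environment variables.

    Zero-variance variables cannot be standardized and are dropped with a
    warning.
    """
    data = env.data if isinstance(env, EnvTable) else env
    vals = data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("environment table has missing values")
    if standardize:
        sd = vals.std(axis=0)
        flat = sd == 0
        if flat.any():
            _warnings.warn(
                f"dropping zero-variance variables: {list(data.columns[flat])}",
                stacklevel=2,
            )
            vals = vals[:, ~flat]
            sd = sd[~flat]
        vals = (vals - vals.mean(axis=0)) / sd
    return DistanceMatrix(
        squareform(pdist(vals, metric="euclidean")),
        labels=list(data.index),
        kind="euclidean_env",
    )


def geographic_distance(lonlat: pd.DataFrame, mode: str = "great_circle") -> DistanceMatrix:
    """Pairwise spatial distance from decimal-degree (longitude, latitude).

    ``great_circle`` (default) is the haversine distance on a sphere of
    radius 6371 km; ``euclidean_degrees`` is plain Euclidean distance on the
    raw coordinates.
    """
    lon = lonlat["longitude"].to_numpy(dtype=float)
    lat = lonlat["latitude"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValidationError("coordinates out of range (|lat|<=90, |lon|<=180)")
    if mode == "euclidean_degrees":
        d = squareform(pdist(np.column_stack([lon, lat]), metric="euclidean"))
    elif mode == "great_circle":
        lam = np.radians(lon)
        phi = np.radians(lat)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
        h = np.clip(h, 0.0, 1.0)
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2  # enforce exact symmetry against float noise
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return DistanceMatrix(d, labels=list(lonlat.index), kind="geographic")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    ``r`` is the rank (Spearman, default) or Pearson correlation of the
    condensed entries; ``p`` comes from jointly permuting rows and columns of
    ``d2``: p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for the one-tailed
    positive alternative, with |r| for ``two-sided``.
    """
    if d1.n != d2.n:
        raise ValidationError("distance matrices differ in size")
    if list(d1.labels) != list(d2.labels):
        raise ValidationError("distance matrix labels do not match")
    if d1.n < 4:
        raise ValidationError("Mantel test needs at least 4 objects")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method: {method!r}")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative: {alternative!r}")

    # Spearman = Pearson on ranks; a joint row/column permutation of d2
    # permutes its condensed entries, so ranking once up front is valid.
    m1 = squareform(rankdata(d1.condensed()), checks=False) if method == "spearman" else d1.data
    m2 = squareform(rankdata(d2.condensed()), checks=False) if method == "spearman" else d2.data

    v1 = squareform(m1, checks=False)
    v1 = v1 - v1.mean()
    n1 = np.sqrt((v1**2).sum())

    def corr(mat: np.ndarray) -> float:
        v2 = squareform(mat, checks=False)
        v2 = v2 - v2.mean()
        n2 = np.sqrt((v2**2).sum())
        if n1 == 0 or n2 == 0:
            raise ValidationError("constant distance matrix: correlation undefined")
        return float((v1 @ v2) / (n1 * n2))

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(d2.n)
        r_perm = corr(m2[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_perm >= r_obs - 1e-12
        else:
            hits += abs(r_perm) >= abs(r_obs) - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed,
                        alternative=alternative)
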