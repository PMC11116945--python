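"""Core domain types: community tables, incidence matrices, and subsetting.

The analysis operates on a samples x genera abundance table with per-sample
metadata (site, land cover, year, replicate, coordinates) and per-genus
trophic-group labels, plus a companion table of soil environmental variables.
All downstream null-model work runs on a pruned binary incidence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAND_COVERS = ("farmland", "grassland", "woodland")
TROPHIC_GROUPS = ("PF", "BF", "FF", "OP")  # plant parasites, bacterivores,
# fungivores, omnivores-predators
SCALES = ("local", "regional")

META_COLUMNS = ("site", "land_cover", "year", "replicate", "longitude", "latitude")
ENV_COLUMNS = ("SM", "ST", "pH", "STC", "STN", "STP")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


class DegenerateMatrixError(ValueError):
    """Raised when a matrix is empty, or too small for the requested analysis."""


@dataclass
class CommunityTable:
    """Samples x genera count matrix with sample and genus metadata.

    Parameters
    ----------
    counts : pd.DataFrame
        Non-negative integer counts; index = sample ids, columns = genus names.
    sample_meta : pd.DataFrame
        One row per sample (same index as ``counts``) with columns
        ``site, land_cover, year, replicate, longitude, latitude``.
    genus_meta : pd.DataFrame
        One row per genus (index = genus names) with a ``trophic_group``
        column taking values in ``{PF, BF, FF, OP}``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    genus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValidationError("counts rows and sample_meta rows do not match")
        if not self.counts.columns.equals(self.genus_meta.index):
            raise ValidationError("counts columns and genus_meta rows do not match")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"genus {self.counts.columns[j]!r}"
            )
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample_meta missing columns: {missing}")
        if "trophic_group" not in self.genus_meta.columns:
            raise ValidationError("genus_meta missing 'trophic_group' column")
        bad = set(self.genus_meta["trophic_group"]) - set(TROPHIC_GROUPS)
        if bad:
            raise ValidationError(f"unknown trophic groups: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genera(self) -> int:
        return self.counts.shape[1]


@dataclass
class EnvTable:
    """Per-sample soil environment: SM, ST, pH, STC, STN, STP."""

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        missing = [c for c in ENV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"environment table missing columns: {missing}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in environment table: {dupes}")

    def align_to(self, table: CommunityTable) -> "EnvTable":
        """Return rows matching ``table``'s samples; error on missing ids."""
        missing = table.counts.index.difference(self.data.index)
        if len(missing):
            raise ValidationError(
                f"samples absent from environment table: {missing.tolist()}"
            )
        return EnvTable(self.data.loc[table.counts.index])


@dataclass
class IncidenceMatrix:
    """Pruned binary site-by-genus matrix (rows = samples/sites)."""

    data: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValidationError("incidence matrix must be 2-dimensional")
        if not np.isin(self.data, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        if not self.row_labels:
            self.row_labels = list(range(self.data.shape[0]))
        if not self.col_labels:
            self.col_labels = list(range(self.data.shape[1]))
        if len(self.row_labels) != self.data.shape[0]:
            raise ValidationError("row_labels length mismatch")
        if len(self.col_labels) != self.data.shape[1]:
            raise ValidationError("col_labels length mismatch")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def fill(self) -> int:
        """Total number of presences."""
        return int(self.data.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.row_labels, columns=self.col_labels)


def to_incidence(
    table: CommunityTable | pd.DataFrame,
    threshold: int = 1,
    drop_singletons: bool = False,
) -> IncidenceMatrix:
    """Convert an abundance table to a pruned presence-absence matrix.

    A cell is a presence when its count is at least ``threshold`` (default 1).
    All-zero rows and columns are removed after thresholding; removed labels
    are recorded on the result. ``drop_singletons`` additionally removes
    genera present in exactly one sample (retained by default).

    Raises
    ------
    DegenerateMatrixError
        If no row or no column survives pruning.
    """
    if threshold < 1:
        raise ValidationError("threshold must be a positive integer")
    counts = table.counts if isinstance(table, CommunityTable) else table
    if counts.size == 0:
        raise DegenerateMatrixError("empty community table")
    binary = (counts.to_numpy() >= threshold).astype(np.int8)
    min_occurrences = 2 if drop_singletons else 1
    keep_cols = binary.sum(axis=0) >= min_occurrences
    binary = binary * keep_cols[None, :]
    keep_rows = binary.sum(axis=1) > 0
    keep_cols = binary.sum(axis=0) > 0
    if not keep_rows.any() or not keep_cols.any():
        raise DegenerateMatrixError("degenerate matrix: empty after pruning")
    return IncidenceMatrix(
        data=binary[np.ix_(keep_rows, keep_cols)],
        row_labels=list(counts.index[keep_rows]),
        col_labels=list(counts.columns[keep_cols]),
        dropped_rows=list(counts.index[~keep_rows]),
        dropped_cols=list(counts.columns[~keep_cols]),
    )


def subset(
    table: CommunityTable,
    land_cover: str,
    scale: str,
    site: str | None = None,
    year: int | None = None,
) -> CommunityTable:
    """Restrict a community table to one analysis unit.

    ``scale='regional'`` keeps all sites of one land cover; ``scale='local'``
    additionally requires ``site`` and keeps that site only. The sampling
    years are pooled unless ``year`` restricts to one. Genus columns are
    untouched (prune later via :func:`to_incidence`).
    """
    if land_cover not in set(table.sample_meta["land_cover"]):
        raise ValidationError(f"unknown land cover: {land_cover!r}")
    if scale not in SCALES:
        raise ValidationError(f"unknown scale: {scale!r}")
    mask = table.sample_meta["land_cover"] == land_cover
    if scale == "local":
        if site is None:
            raise ValidationError("site is required at the local scale")
        if site not in set(table.sample_meta["site"]):
            raise ValidationError(f"unknown site: {site!r}")
        mask &= table.sample_meta["site"] == site
    elif site is not None:
        raise ValidationError("site must be omitted at the regional scale")
    if year is not None:
        if year not in set(table.sample_meta["year"]):
            raise ValidationError(f"unknown sampling year: {year!r}")
        mask &= table.sample_meta["year"] == year
    return CommunityTable(
        counts=table.counts.loc[mask],
        sample_meta=table.sample_meta.loc[mask],
        genus_meta=table.genus_meta,
    )


def subset_trophic(table: CommunityTable, group: str) -> CommunityTable:
    """Keep only genera of one trophic group; sample rows unchanged.

    An empty result (no genera carry the group) raises
    :class:`DegenerateMatrixError` so callers can flag the unit as degenerate.
    """
    if group not in TROPHIC_GROUPS:
        raise ValidationError(f"unknown trophic group: {group!r}")
    keep = table.genus_meta["trophic_group"] == group
    if not keep.any():
        raise DegenerateMatrixError(f"degenerate: no genera in group {group}")
    return CommunityTable(
        counts=table.counts.loc[:, keep],
        sample_meta=table.sample_meta,
        genus_meta=table.genus_meta.loc[keep],
    )
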