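"""Delimited-text readers and writers for community, metadata and environment tables.

Interchange dialect: UTF-8 delimited text (comma by default, tab accepted),
"." decimal separator. The community table has sample_id as first column and
genus names as header; sample metadata and environment tables are keyed by
sample_id; the trophic map is a two-column table (genus_id, trophic_group).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import CommunityTable, EnvTable, META_COLUMNS, ValidationError


def _read(path, sep) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate ids {dupes}")
    return df


def read_community(
    community_path,
    meta_path,
    env_path,
    trophic_path,
    sep: str = ",",
) -> tuple[CommunityTable, EnvTable]:
    """Load and validate the four input tables.

    Raises descriptive errors for missing columns, duplicate or mismatched
    sample ids (with the offending ids named), and non-numeric or negative
    counts (with their row/column address).
    """
    counts = _read(community_path, sep)
    try:
        counts = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        for j, col in enumerate(counts.columns):
            bad = pd.to_numeric(counts[col], errors="coerce").isna()
            if bad.any():
                row = counts.index[bad.argmax()]
                raise ValidationError(
                    f"{community_path}: non-numeric count at sample {row!r}, "
                    f"genus {col!r}"
                ) from exc
        raise
    meta = _read(meta_path, sep)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{meta_path}: missing columns {missing}")
    trophic = _read(trophic_path, sep)
    if "trophic_group" not in trophic.columns:
        raise ValidationError(f"{trophic_path}: missing 'trophic_group' column")
    counts.columns.name = trophic.index.name  # genus axis name survives round-trips
    env = _read(env_path, sep)

    for name, df in (("metadata", meta), ("environment", env)):
        absent = counts.index.difference(df.index)
        if len(absent):
            rows = [int(counts.index.get_loc(s)) + 2 for s in absent]  # header = line 1
            raise ValidationError(
                f"samples absent from {name} table: {absent.tolist()} "
                f"(community file lines {rows})"
            )
    absent_genera = counts.columns.difference(trophic.index)
    if len(absent_genera):
        raise ValidationError(
            f"genera absent from trophic map: {absent_genera.tolist()}"
        )
    table = CommunityTable(
        counts=counts,
        sample_meta=meta.loc[counts.index],
        genus_meta=trophic.loc[counts.columns],
    )
    return table, EnvTable(env.loc[counts.index])


def write_community(
    table: CommunityTable,
    env: EnvTable,
    out_dir,
    sep: str = ",",
) -> dict:
    """Write the four tables under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": out / "community.csv",
        "metadata": out / "sample_metadata.csv",
        "environment": out / "environment.csv",
        "trophic": out / "trophic_groups.csv",
    }
    table.counts.to_csv(paths["community"], sep=sep)
    table.sample_meta.to_csv(paths["metadata"], sep=sep)
    env.data.to_csv(paths["environment"], sep=sep)
    table.genus_meta.to_csv(paths["trophic"], sep=sep)
    return paths
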