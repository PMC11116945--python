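"""Run configuration and the combined analysis driver.

:func:`run_all` walks every analysis unit (each land cover at each site at
the local scale, plus each land cover pooled regionally), and emits four
delimited-text reports: the EMS element/structure table, the Mantel table
(community dissimilarity vs. environmental and spatial distance), the
co-occurrence table (overall and per trophic group), and the variable
importance table for the regional site scores. A run log records seeds,
simulation counts, software version and every setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    CommunityTable,
    DegenerateMatrixError,
    EnvTable,
    LAND_COVERS,
    TROPHIC_GROUPS,
    ValidationError,
    subset,
    to_incidence,
)
from .cooccurrence import cooccurrence_analysis
from .distances import bray_curtis, euclidean_env, geographic_distance, mantel
from .ems import ems_pipeline
from .importance import importance_analysis
from .io import read_community
from .ordination import reciprocal_averaging


@dataclass
class RunConfig:
    """Settings for a full analysis run (YAML-loadable)."""

    community: str | None = None
    metadata: str | None = None
    environment: str | None = None
    trophic: str | None = None
    out_dir: str = "results"
    analyses: tuple = ("ems", "mantel", "cooccurrence", "importance")
    alpha: float = 0.05
    n_sims_ems: int = 1000
    n_sims_cooccurrence: int = 10_000
    n_perm_mantel: int = 9999
    n_trees: int = 500
    n_perms_importance: int = 100
    seed: int = 0
    abs_mode: str = "both_axes"
    geo_mode: str = "great_circle"
    threshold: int = 1
    sep: str = ","

    def __post_init__(self) -> None:
        for name in ("n_sims_ems", "n_sims_cooccurrence", "n_perm_mantel",
                     "n_trees", "n_perms_importance", "threshold"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        for name in ("community", "metadata", "environment", "trophic"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def load_tables(self) -> tuple[CommunityTable, EnvTable]:
        if any(getattr(self, n) is None
               for n in ("community", "metadata", "environment", "trophic")):
            raise ValidationError("input paths are not all set in the config")
        return read_community(self.community, self.metadata,
                              self.environment, self.trophic, sep=self.sep)


def _units(table: CommunityTable):
    """Yield (scale, land_cover, site) analysis units: regional first."""
    covers = [lc for lc in LAND_COVERS if lc in set(table.sample_meta["land_cover"])]
    sites = list(dict.fromkeys(table.sample_meta["site"]))
    for lc in covers:
        yield "regional", lc, None
    for lc in covers:
        for site in sites:
            yield "local", lc, site


def _unit_seed(base: int, *parts) -> int:
    """Stable per-unit seed derived from the run seed (below 2**31)."""
    import zlib

    key = tuple(zlib.crc32(repr(p).encode()) for p in parts)
    h = np.random.SeedSequence(entropy=base, spawn_key=key)
    return int(h.generate_state(1)[0] % (2**31))


def run_all(
    config: RunConfig,
    table: CommunityTable | None = None,
    env: EnvTable | None = None,
) -> dict:
    """Run every selected analysis over all units; write reports + log.

    ``table``/``env`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are read from the configured paths. Returns
    the report path map.
    """
    if table is None or env is None:
        table, env = config.load_tables()
    env = env.align_to(table)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log: list[str] = [
        f"nemameta {__version__}",
        f"seed={config.seed} alpha={config.alpha} abs_mode={config.abs_mode} "
        f"geo_mode={config.geo_mode} threshold={config.threshold}",
        f"n_sims_ems={config.n_sims_ems} n_sims_cooccurrence={config.n_sims_cooccurrence} "
        f"n_perm_mantel={config.n_perm_mantel} n_trees={config.n_trees} "
        f"n_perms_importance={config.n_perms_importance}",
    ]
    units = list(_units(table))

    if "ems" in config.analyses:
        rows = []
        for scale, lc, site in units:
            seed = _unit_seed(config.seed, "ems", scale, lc, site)
            res = ems_pipeline(
                table, scale, lc, site,
                n_sims=config.n_sims_ems, seed=seed,
                mode=config.abs_mode, alpha=config.alpha,
                threshold=config.threshold,
            )
            rows.append({
                "scale": scale, "land_cover": lc, "site": site or "",
                "abs_obs": res.coherence.abs_obs,
                "coh_p": round(res.coherence.p, 4),
                "coh_mean": round(res.coherence.null.mean, 2),
                "coh_sd": round(res.coherence.null.sd, 2),
                "coh_z": round(res.coherence.z, 2),
                "rep_obs": res.turnover.rep_obs,
                "tur_p": round(res.turnover.p, 4),
                "tur_mean": round(res.turnover.null.mean, 2),
                "tur_sd": round(res.turnover.null.sd, 2),
                "tur_z": round(res.turnover.z, 2),
                "morisita_i": round(res.boundary.morisita_i, 2),
                "bnd_p": round(res.boundary.p, 4),
                "label": res.label,
                "n_sims": config.n_sims_ems, "seed": seed,
                "warnings": ";".join(res.ordination.warnings),
            })
        df = pd.DataFrame(rows)
        paths["ems"] = out / "ems_report.csv"
        df.to_csv(paths["ems"], sep=config.sep, index=False)
        log.append(f"ems: {len(df)} analysis units")

    if "mantel" in config.analyses:
        rows = []
        for scale, lc, site in units:
            unit = subset(table, lc, scale, site)
            seed = _unit_seed(config.seed, "mantel", scale, lc, site)
            if unit.n_samples < 4:
                continue
            d_com = bray_curtis(unit.counts.loc[unit.counts.sum(axis=1) > 0])
            keep = d_com.labels
            d_env = euclidean_env(env.data.loc[keep])
            d_geo = geographic_distance(
                unit.sample_meta.loc[keep, ["longitude", "latitude"]],
                mode=config.geo_mode,
            )
            m_env = mantel(d_com, d_env, n_perm=config.n_perm_mantel, seed=seed)
            m_geo = mantel(d_com, d_geo, n_perm=config.n_perm_mantel, seed=seed + 1)
            rows.append({
                "scale": scale, "land_cover": lc, "site": site or "",
                "env_r": round(m_env.r, 2), "env_p": round(m_env.p, 4),
                "spa_r": round(m_geo.r, 2), "spa_p": round(m_geo.p, 4),
                "n_samples": len(keep), "n_perm": config.n_perm_mantel,
                "seed": seed,
            })
        df = pd.DataFrame(rows)
        paths["mantel"] = out / "mantel_report.csv"
        df.to_csv(paths["mantel"], sep=config.sep, index=False)
        log.append(f"mantel: {len(df)} analysis units")

    if "cooccurrence" in config.analyses:
        rows = []
        for scale, lc, site in units:
            unit = subset(table, lc, scale, site)
            for group in (None, *TROPHIC_GROUPS):
                seed = _unit_seed(config.seed, "cooc", scale, lc, site, group)
                res = cooccurrence_analysis(
                    unit, group=group, n_sims=config.n_sims_cooccurrence,
                    seed=seed, threshold=config.threshold,
                )
                rows.append({
                    "scale": scale, "land_cover": lc, "site": site or "",
                    "group": group or "all",
                    "c_obs": round(res.c_obs, 4) if not np.isnan(res.c_obs) else "",
                    "null_mean": round(res.null.mean, 4) if res.null else "",
                    "null_sd": round(res.null.sd, 4) if res.null else "",
                    "ses": round(res.ses, 2) if res.ses is not None else "",
                    "interpretation": res.interpretation,
                    "n_taxa": res.n_taxa,
                    "n_sims": config.n_sims_cooccurrence, "seed": seed,
                })
        df = pd.DataFrame(rows)
        paths["cooccurrence"] = out / "cooccurrence_report.csv"
        df.to_csv(paths["cooccurrence"], sep=config.sep, index=False)
        log.append(f"cooccurrence: {len(df)} unit x group rows")

    if "importance" in config.analyses:
        rows = []
        for lc in dict.fromkeys(table.sample_meta["land_cover"]):
            unit = subset(table, lc, "regional")
            try:
                incidence = to_incidence(unit, threshold=config.threshold)
                ordination = reciprocal_averaging(incidence)
            except DegenerateMatrixError:
                continue
            keep = ordination.ordered_matrix.row_labels  # pruned samples
            scores = pd.Series(
                ordination.site_scores, index=incidence.row_labels
            ).loc[keep]
            variables = pd.concat(
                [env.data.loc[keep],
                 unit.sample_meta.loc[keep, ["longitude", "latitude"]]],
                axis=1,
            )
            seed = _unit_seed(config.seed, "imp", lc)
            res = importance_analysis(
                scores.to_numpy(), variables,
                n_trees=config.n_trees, n_perms=config.n_perms_importance,
                seed=seed,
            )
            for _, rec in res.table.iterrows():
                rows.append({
                    "land_cover": lc, "variable": rec["variable"],
                    "importance": round(rec["importance"], 2),
                    "p": round(rec["p"], 4), "rank": int(rec["rank"]),
                    "signif": rec["signif"],
                    "n_trees": config.n_trees, "seed": seed,
                })
        df = pd.DataFrame(rows)
        paths["importance"] = out / "importance_report.csv"
        df.to_csv(paths["importance"], sep=config.sep, index=False)
        log.append(f"importance: {len(df)} variable rows")

    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(log) + "\n")
    return paths
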