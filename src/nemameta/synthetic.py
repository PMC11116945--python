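"""Synthetic metacommunities and a full study-design emulator.

Two layers:

* :func:`generate_metacommunity` builds a community with a known idealized
  structure (Clementsian compartments, independent Gleasonian ranges, nested
  subsets, checkerboard/segregated/aggregated pairs, evenly spaced ranges, or
  Bernoulli noise) along an explicit one-dimensional gradient, so every
  pipeline stage can be validated against a known truth.
* :func:`generate_study_design` emulates the survey layout the package is
  aimed at: 4 stations spanning ~10 degrees of latitude x 3 land covers x
  3 replicate plots x 2 sampling years = 72 samples, at most 100 identified
  individuals per sample, genera spread over the four trophic groups, and
  soil variables that track the latitudinal climate gradient.

Abundances are assigned per presence from a skewed (log-normal) abundance
model and multinomially thinned to the 100-individual identification cap,
so sample totals are always <= 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CommunityTable, EnvTable, TROPHIC_GROUPS, ValidationError

STRUCTURES = (
    "clementsian",
    "gleasonian",
    "nested",
    "checkerboard",
    "evenly_spaced",
    "random",
    "segregated_pairs",
    "aggregated_pairs",
)

# Study-site layout: name -> (longitude, latitude, MAT degC, MAP mm)
STUDY_SITES = {
    "Heihe": (127.45, 50.25, 2.0, 510.0),
    "Harbin": (126.583, 45.667, 5.5, 500.0),
    "Lishu": (124.617, 43.35, 5.8, 576.0),
    "Shenyang": (123.55, 40.8, 7.9, 700.0),
}
LAND_COVERS = ("farmland", "grassland", "woodland")
YEARS = (2019, 2021)
N_REPLICATES = 3
IDENTIFIED_PER_SAMPLE = 100


@dataclass
class SyntheticScenario:
    """Parameters of one structured metacommunity.

    ``gradient`` defaults to unit-spaced site positions 1..n_sites, so
    ``boundary_noise_sd`` is in units of inter-site spacing.
    """

    structure: str = "clementsian"
    n_sites: int = 24
    n_taxa: int = 30
    n_compartments: int = 3
    boundary_noise_sd: float = 0.5
    fill: float = 0.5
    n_pairs: int = 10
    gradient: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure: {self.structure!r}")
        if self.n_sites < 2 or self.n_taxa < 2:
            raise ValidationError("need at least 2 sites and 2 taxa")
        if self.structure == "clementsian" and self.n_compartments > self.n_taxa:
            raise ValidationError("more compartments than taxa")
        if not 0.0 < self.fill < 1.0 and self.structure == "random":
            raise ValidationError("fill must be in (0, 1)")
        if self.structure in ("checkerboard", "segregated_pairs", "aggregated_pairs"):
            if 2 * self.n_pairs > self.n_taxa:
                raise ValidationError("2 * n_pairs exceeds n_taxa")
        if self.gradient is None:
            self.gradient = np.arange(1, self.n_sites + 1, dtype=float)
        else:
            self.gradient = np.asarray(self.gradient, dtype=float)
            if self.gradient.size != self.n_sites:
                raise ValidationError("gradient length must equal n_sites")


def _range_incidence(grad: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Presence where the site position falls inside each taxon's range."""
    return ((grad[:, None] >= lo[None, :]) & (grad[:, None] <= hi[None, :])).astype(np.int8)


def _structure_incidence(s: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    n, t = s.n_sites, s.n_taxa
    grad = s.gradient
    lo_g, hi_g = grad.min() - 0.5, grad.max() + 0.5
    span = hi_g - lo_g

    if s.structure == "clementsian":
        edges = np.linspace(lo_g, hi_g, s.n_compartments + 1)
        comp = np.arange(t) % s.n_compartments  # taxa spread over compartments
        lo = edges[comp] + rng.normal(0, s.boundary_noise_sd, t)
        hi = edges[comp + 1] + rng.normal(0, s.boundary_noise_sd, t)
        return _range_incidence(grad, np.minimum(lo, hi), np.maximum(lo, hi))

    if s.structure == "gleasonian":
        # independent range centers with similar widths (~half the gradient):
        # idiosyncratic, non-coincident boundaries. Ranges lie wholly inside
        # the gradient and widths vary little, because truncated or strongly
        # heterogeneous ranges make the ordination stack range edges at the
        # matrix margins, which reads as spurious boundary clumping.
        width = rng.uniform(0.4 * span, 0.6 * span, t)
        center = rng.uniform(lo_g + width / 2, hi_g - width / 2)
        return _range_incidence(grad, center - width / 2, center + width / 2)

    if s.structure == "evenly_spaced":
        width = span / 3
        start = np.linspace(lo_g, hi_g - width, t)
        return _range_incidence(grad, start, start + width)

    if s.structure == "nested":
        order = np.argsort(np.argsort(grad))  # site richness follows gradient rank
        depth = rng.integers(1, n + 1, size=t).astype(float)
        depth += rng.normal(0, s.boundary_noise_sd, t)
        depth = np.clip(np.round(depth), 1, n)
        return (order[:, None] < depth[None, :]).astype(np.int8)

    if s.structure in ("checkerboard", "segregated_pairs"):
        out = np.zeros((n, t), dtype=np.int8)
        for p in range(s.n_pairs):
            a, b = 2 * p, 2 * p + 1
            sites = rng.permutation(n)
            half = n // 2
            out[sites[:half], a] = 1
            if s.structure == "checkerboard":
                out[sites[half:], b] = 1  # exact complement
            else:
                k = max(2, int(rng.binomial(n, 0.4)))
                out[sites[half:half + min(k, n - half)], b] = 1  # disjoint set
        # remaining taxa occupy random sites so the matrix stays full rank
        for j in range(2 * s.n_pairs, t):
            out[:, j] = rng.random(n) < 0.4
        return out

    if s.structure == "aggregated_pairs":
        # Aggregation that a fixed-margins null can register must be diffuse:
        # the total pairwise overlap is fully determined by the row sums, so
        # literally identical ("co-placed") columns starve every other pair
        # of overlap and push the community C-score UP, not down. Instead,
        # pair members share clearly more sites than chance (k^2/n + 0.3k)
        # while all remaining overlaps are homogenized toward their
        # expectation by a greedy draw - fewer checkerboard units than the
        # margins predict, i.e. community-wide aggregation.
        k = n // 2
        lam = k * k / n
        delta = 0.3 * k
        cols: list[np.ndarray] = []
        for j in range(t):
            partner = j - 1 if (j % 2 == 1 and j // 2 < s.n_pairs) else None
            best, best_score = None, np.inf
            for _ in range(300):
                cand = np.zeros(n, dtype=np.int8)
                cand[rng.choice(n, k, replace=False)] = 1
                score = 0.0
                for jj, col in enumerate(cols):
                    target = lam + delta if jj == partner else lam
                    score += (int((cand & col).sum()) - target) ** 2
                if score < best_score:
                    best, best_score = cand, score
            cols.append(best)
        return np.array(cols).T

    # random
    return (rng.random((n, t)) < s.fill).astype(np.int8)


def _abundances(
    incidence: np.ndarray,
    rng: np.random.Generator,
    total: int = IDENTIFIED_PER_SAMPLE,
) -> np.ndarray:
    """Skewed abundances per presence, thinned to <= ``total`` per sample.

    Per-taxon log-normal base abundances crossed with per-cell log-normal
    noise give a few dominant and many rare genera; each sample's presences
    then share ``total`` identified individuals (at least one each).
    """
    n, t = incidence.shape
    base = rng.lognormal(mean=0.0, sigma=1.0, size=t)
    counts = np.zeros((n, t), dtype=np.int64)
    for i in range(n):
        present = np.nonzero(incidence[i])[0]
        k = present.size
        if k == 0:
            continue
        w = base[present] * rng.lognormal(0.0, 0.5, k)
        w /= w.sum()
        if k >= total:
            chosen = rng.choice(present, size=total, replace=False, p=w)
            np.add.at(counts[i], chosen, 1)
        else:
            counts[i, present] = 1 + rng.multinomial(total - k, w)
    return counts


def generate_metacommunity(s: SyntheticScenario) -> CommunityTable:
    """Generate a structured community table (pure function of scenario + seed)."""
    rng = np.random.default_rng(s.seed)
    incidence = _structure_incidence(s, rng)
    counts = _abundances(incidence, rng)
    sample_ids = [f"s{i + 1:02d}" for i in range(s.n_sites)]
    genus_ids = [f"g{j + 1:02d}" for j in range(s.n_taxa)]
    sample_meta = pd.DataFrame(
        {
            "site": "S1",
            "land_cover": "grassland",
            "year": 2019,
            "replicate": np.arange(1, s.n_sites + 1),
            "longitude": 120.0,
            "latitude": 40.0 + s.gradient / 10.0,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    genus_meta = pd.DataFrame(
        {"trophic_group": [TROPHIC_GROUPS[j % 4] for j in range(s.n_taxa)]},
        index=pd.Index(genus_ids, name="genus_id"),
    )
    counts_df = pd.DataFrame(counts, index=sample_meta.index, columns=genus_meta.index)
    return CommunityTable(counts=counts_df, sample_meta=sample_meta, genus_meta=genus_meta)


# ---------------------------------------------------------------------------
# Full study-design emulator


def _default_genus_pool(rng: np.random.Generator, n_genera: int) -> pd.DataFrame:
    """Genus pool with realistic trophic-group proportions (BF-rich)."""
    weights = {"BF": 0.38, "PF": 0.31, "FF": 0.16, "OP": 0.15}
    groups: list[str] = []
    for g, w in weights.items():
        groups += [g] * max(1, round(w * n_genera))
    groups = groups[:n_genera]
    while len(groups) < n_genera:
        groups.append("BF")
    rng.shuffle(groups)
    ids = [f"Genus{j + 1:02d}" for j in range(n_genera)]
    return pd.DataFrame({"trophic_group": groups}, index=pd.Index(ids, name="genus_id"))


def generate_study_design(
    seed: int = 0, n_genera: int = 32
) -> tuple[CommunityTable, EnvTable]:
    """Emulate the full survey: 4 sites x 3 land covers x 3 plots x 2 years.

    Genus occupancy follows Gaussian niches along the latitudinal gradient
    with land-cover affinities; abundances honour the 100-individual
    identification cap. Soil variables are generated around site climate
    (MAT/MAP) means so they correlate with latitude, with plot-level noise.
    """
    rng = np.random.default_rng(seed)
    genus_meta = _default_genus_pool(rng, n_genera)

    lats = np.array([v[1] for v in STUDY_SITES.values()])
    lat_lo, lat_hi = lats.min() - 1, lats.max() + 1
    niche_center = rng.uniform(lat_lo, lat_hi, n_genera)
    niche_width = rng.uniform(2.0, 6.0, n_genera)  # degrees of latitude
    # land-cover affinity on logit scale, per genus
    lc_affinity = {lc: rng.normal(0.0, 0.8, n_genera) for lc in LAND_COVERS}

    rows_meta = []
    sample_ids = []
    incidence_rows = []
    env_rows = []
    for site, (lon, lat, mat, mapr) in STUDY_SITES.items():
        for lc in LAND_COVERS:
            for rep in range(1, N_REPLICATES + 1):
                # plot coordinates fixed across years
                plot_lon = lon + rng.normal(0, 0.01)
                plot_lat = lat + rng.normal(0, 0.01)
                for year in YEARS:
                    sid = f"{site}_{lc}_r{rep}_{year}"
                    sample_ids.append(sid)
                    rows_meta.append(
                        dict(site=site, land_cover=lc, year=year, replicate=rep,
                             longitude=plot_lon, latitude=plot_lat)
                    )
                    logit = (
                        1.2
                        - ((plot_lat - niche_center) / niche_width) ** 2
                        + lc_affinity[lc]
                        + rng.normal(0, 0.5, n_genera)
                    )
                    prob = 1.0 / (1.0 + np.exp(-logit))
                    incidence_rows.append((rng.random(n_genera) < prob).astype(np.int8))
                    env_rows.append(
                        dict(
                            SM=10.0 + 0.03 * mapr + rng.normal(0, 2.0),
                            ST=mat + 13.0 + rng.normal(0, 1.0),
                            pH=7.6 - 0.12 * (lat - 40.0) + rng.normal(0, 0.2),
                            STC=8.0 + 1.1 * (lat - 40.0) + rng.normal(0, 1.5),
                            STN=0.8 + 0.11 * (lat - 40.0) + rng.normal(0, 0.15),
                            STP=0.45 + 0.02 * (lat - 40.0) + rng.normal(0, 0.05),
                        )
                    )

    incidence = np.vstack(incidence_rows)
    counts = _abundances(incidence, rng)
    index = pd.Index(sample_ids, name="sample_id")
    table = CommunityTable(
        counts=pd.DataFrame(counts, index=index, columns=genus_meta.index),
        sample_meta=pd.DataFrame(rows_meta, index=index),
        genus_meta=genus_meta,
    )
    env = EnvTable(pd.DataFrame(env_rows, index=index).round(4))
    return table, env
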