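"""Elements of metacommunity structure on the RA-ordered incidence matrix.

Three elements are evaluated in sequence on the ordered matrix:

1. **Coherence** — the number of embedded absences (gaps strictly inside a
   genus's site range, and by default also inside a site's genus range).
   Fewer gaps than the null expects means species ranges respond coherently
   to a shared gradient; more gaps means checkerboard-like exclusion.
2. **Turnover** — after filling ranges, the number of opposing
   presence/absence pairs over all site pairs x genus pairs ("replacements").
   Significantly fewer replacements than null means nestedness; more means
   species substitution along the gradient.
3. **Boundary clumping** — Morisita's index of dispersion on the per-site
   counts of genus range boundaries, with a chi-squared test. I > 1 means
   range edges coincide (clumped, Clementsian-like); I < 1 means edges are
   hyper-dispersed (evenly spaced).

A decision tree over the three elements assigns one of the idealized
metacommunity structures (Random, Checkerboard, Clementsian, Gleasonian,
Evenly spaced, Nested with loss subtypes) or, when coherence is significant
but turnover is not, the corresponding quasi-structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CommunityTable, DegenerateMatrixError, IncidenceMatrix, subset, to_incidence
from .null_models import NullDistribution, z_and_p
from .ordination import OrdinationResult, reciprocal_averaging

ABS_MODES = ("both_axes", "columns_only")

# Structure labels
RANDOM = "Random"
CHECKERBOARD = "Checkerboard"
CLEMENTSIAN = "Clementsian"
GLEASONIAN = "Gleasonian"
EVENLY_SPACED = "Evenly spaced"
NESTED_CLUMPED = "Nested (clumped loss)"
NESTED_STOCHASTIC = "Nested (stochastic loss)"
NESTED_HYPERDISPERSED = "Nested (hyperdispersed loss)"


def quasi(label: str) -> str:
    return "Quasi-" + label[0].lower() + label[1:] if label.startswith("Nested") else "Quasi-" + label


@dataclass
class CoherenceResult:
    abs_obs: int
    null: NullDistribution
    z: float
    p: float


@dataclass
class TurnoverResult:
    rep_obs: int
    null: NullDistribution
    z: float
    p: float


@dataclass
class BoundaryResult:
    morisita_i: float
    chi2: float
    df: int
    p: float


@dataclass
class EMSResult:
    """Full pipeline output for one analysis unit."""

    ordination: OrdinationResult
    coherence: CoherenceResult
    turnover: TurnoverResult
    boundary: BoundaryResult
    label: str
    provenance: dict = field(default_factory=dict)


def embedded_absences(om: IncidenceMatrix, mode: str = "both_axes") -> int:
    """Count absences embedded strictly inside ranges of the ordered matrix.

    For every column (genus), zeros lying between its first and last presence
    in row order are embedded. ``both_axes`` (default) adds the analogous
    count along rows (gaps inside each site's genus range).
    """
    if mode not in ABS_MODES:
        raise ValueError(f"unknown mode: {mode!r}")
    total = _range_gaps(om.data)
    if mode == "both_axes":
        total += _range_gaps(om.data.T)
    return int(total)


def _range_gaps(data: np.ndarray) -> int:
    """Sum over columns of zeros between each column's first and last 1."""
    n, m = data.shape
    occupied = data.astype(bool)
    any_col = occupied.any(axis=0)
    first = np.argmax(occupied, axis=0)
    last = n - 1 - np.argmax(occupied[::-1], axis=0)
    span = np.where(any_col, last - first + 1, 0)
    return int((span - data.sum(axis=0)).sum())


def fill_ranges(data: np.ndarray) -> np.ndarray:
    """Set embedded absences inside each genus's site range to 1."""
    n, m = data.shape
    occupied = data.astype(bool)
    any_col = occupied.any(axis=0)
    first = np.argmax(occupied, axis=0)
    last = n - 1 - np.argmax(occupied[::-1], axis=0)
    rows = np.arange(n)[:, None]
    filled = ((rows >= first) & (rows <= last) & any_col).astype(np.int8)
    return filled


def replacements(om: IncidenceMatrix, fill: bool = True) -> int:
    """Count replacements (opposing presence/absence pairs) along the axis.

    Genus ranges are first made contiguous (``fill=True``, the standard
    convention); then for every unordered pair of sites and pair of genera,
    one replacement is counted when one genus occurs only at the first site
    while the other occurs only at the second.
    """
    data = fill_ranges(om.data) if fill else om.data
    # A[a, b] = number of genera present at site a but absent at site b
    x = data.astype(np.int64)
    a = x @ (1 - x).T
    return int((a * a.T).sum() // 2)


def morisita_boundary(om: IncidenceMatrix) -> BoundaryResult:
    """Morisita's index of boundary clumping with a chi-squared dispersion test.

    Each genus contributes two range boundaries (its first and its last
    occurrence in site order, both counted even when they coincide). With
    ``f_i`` boundaries at site i and ``F`` boundaries in total,
    ``I = n * sum f_i (f_i - 1) / (F (F - 1))``. The chi-squared statistic
    compares the boundary counts to a uniform expectation (df = n - 1); the
    reported p takes the upper tail when I >= 1 and the lower tail when
    I < 1, so both clumping and hyper-dispersion are detectable.
    """
    data = om.data
    n = data.shape[0]
    if n < 2:
        raise DegenerateMatrixError("boundary clumping needs at least 2 sites")
    occupied = data.astype(bool)
    any_col = occupied.any(axis=0)
    if not any_col.any():
        raise DegenerateMatrixError("no occupied genus in matrix")
    first = np.argmax(occupied, axis=0)[any_col]
    last = (data.shape[0] - 1 - np.argmax(occupied[::-1], axis=0))[any_col]
    f = np.bincount(first, minlength=n) + np.bincount(last, minlength=n)
    big_f = int(f.sum())
    if big_f < 2:
        raise DegenerateMatrixError("fewer than 2 range boundaries")
    morisita_i = n * float((f * (f - 1)).sum()) / (big_f * (big_f - 1))
    expected = big_f / n
    chi2 = float(((f - expected) ** 2 / expected).sum())
    df = n - 1
    if morisita_i >= 1.0:
        p = float(stats.chi2.sf(chi2, df))
    else:
        p = float(stats.chi2.cdf(chi2, df))
    return BoundaryResult(morisita_i=morisita_i, chi2=chi2, df=df, p=p)


def classify_structure(
    coh: CoherenceResult,
    tur: TurnoverResult,
    bnd: BoundaryResult,
    alpha: float = 0.05,
) -> str:
    """Assign the metacommunity structure label from the three elements."""
    return classify_from_stats(
        abs_obs=coh.abs_obs,
        abs_mean=coh.null.mean,
        coh_p=coh.p,
        rep_obs=tur.rep_obs,
        rep_mean=tur.null.mean,
        tur_p=tur.p,
        morisita_i=bnd.morisita_i,
        bnd_p=bnd.p,
        alpha=alpha,
    )


def classify_from_stats(
    abs_obs: float,
    abs_mean: float,
    coh_p: float,
    rep_obs: float,
    rep_mean: float,
    tur_p: float,
    morisita_i: float,
    bnd_p: float,
    alpha: float = 0.05,
) -> str:
    """Decision tree over printed or computed element statistics.

    (1) Non-significant coherence -> Random. (2) Significant negative
    coherence (more embedded absences than the null mean) -> Checkerboard.
    (3) Otherwise turnover decides: significantly fewer replacements than
    null -> Nested (boundary subtype: clumped / stochastic / hyperdispersed
    loss); significantly more -> Clementsian (I significantly > 1),
    Evenly spaced (I significantly < 1) or Gleasonian (I near 1);
    non-significant turnover yields the corresponding Quasi-structure, with
    the direction of the replacement count picking the branch.
    """
    if coh_p >= alpha:
        return RANDOM
    if abs_obs > abs_mean:
        return CHECKERBOARD
    # positive coherence: fewer embedded absences than expected
    if morisita_i > 1.0 and bnd_p < alpha:
        nested = NESTED_CLUMPED
        gradient = CLEMENTSIAN
    elif morisita_i < 1.0 and bnd_p < alpha:
        nested = NESTED_HYPERDISPERSED
        gradient = EVENLY_SPACED
    else:
        nested = NESTED_STOCHASTIC
        gradient = GLEASONIAN
    label = nested if rep_obs < rep_mean else gradient
    if tur_p >= alpha:
        return quasi(label)
    return label


def coherence_turnover_nulls(
    incidence: IncidenceMatrix,
    n_sims: int = 1000,
    seed: int = 0,
    mode: str = "both_axes",
    method: str = "row_fixed",
) -> tuple[CoherenceResult, TurnoverResult]:
    """Coherence and turnover against a shared set of null matrices.

    Every null matrix is re-ordinated before counting, exactly as the
    observed matrix is; both statistics are taken from the same simulated
    matrices for efficiency.
    """
    ord_obs = reciprocal_averaging(incidence)
    abs_obs = embedded_absences(ord_obs.ordered_matrix, mode)
    rep_obs = replacements(ord_obs.ordered_matrix)

    pair_values = np.empty((n_sims, 2))
    if method == "row_fixed":
        from .null_models import randomize_row_fixed

        children = np.random.SeedSequence(seed).spawn(n_sims)
        for i in range(n_sims):
            null_m = randomize_row_fixed(incidence, np.random.default_rng(children[i]))
            om = reciprocal_averaging(null_m).ordered_matrix
            pair_values[i] = (embedded_absences(om, mode), replacements(om))
    else:
        from .null_models import _swap_inplace

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        fill = max(incidence.fill, 1)
        data = incidence.data.copy()
        _swap_inplace(data, 10 * fill, rng)
        for i in range(n_sims):
            _swap_inplace(data, fill, rng)
            om = reciprocal_averaging(
                IncidenceMatrix(data.copy(), list(incidence.row_labels), list(incidence.col_labels))
            ).ordered_matrix
            pair_values[i] = (embedded_absences(om, mode), replacements(om))

    coh_null = NullDistribution(pair_values[:, 0], method=method, seed=seed)
    tur_null = NullDistribution(pair_values[:, 1], method=method, seed=seed)
    coh_z, coh_p = z_and_p(abs_obs, coh_null)
    tur_z, tur_p = z_and_p(rep_obs, tur_null)
    return (
        CoherenceResult(abs_obs=abs_obs, null=coh_null, z=coh_z, p=coh_p),
        TurnoverResult(rep_obs=rep_obs, null=tur_null, z=tur_z, p=tur_p),
    )


def ems_pipeline(
    table: CommunityTable,
    scale: str,
    land_cover: str,
    site: str | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    mode: str = "both_axes",
    alpha: float = 0.05,
    threshold: int = 1,
) -> EMSResult:
    """Subset -> incidence -> ordination -> elements -> structure label."""
    unit = subset(table, land_cover, scale, site)
    incidence = to_incidence(unit, threshold=threshold)
    if incidence.shape[0] < 2 or incidence.shape[1] < 2:
        raise DegenerateMatrixError(
            f"analysis unit too small after pruning: {incidence.shape}"
        )
    ordination = reciprocal_averaging(incidence)
    coh, tur = coherence_turnover_nulls(incidence, n_sims=n_sims, seed=seed, mode=mode)
    bnd = morisita_boundary(ordination.ordered_matrix)
    label = classify_structure(coh, tur, bnd, alpha=alpha)
    return EMSResult(
        ordination=ordination,
        coherence=coh,
        turnover=tur,
        boundary=bnd,
        label=label,
        provenance={
            "scale": scale,
            "land_cover": land_cover,
            "site": site,
            "n_sims": n_sims,
            "seed": seed,
            "mode": mode,
            "alpha": alpha,
            "threshold": threshold,
            "warnings": ordination.warnings,
        },
    )
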