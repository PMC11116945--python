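"""C-score / SES co-occurrence analysis under the fixed-fixed null.

For every unordered pair of genera, the number of "checkerboard units" is
cu = (Ri - S)(Rj - S), where Ri and Rj are the two genera's site totals and S
is the number of shared sites. The C-score is the mean of cu over all pairs;
higher values mean more segregated distributions. The standardized effect
size SES = (C_obs - mean(C_sim)) / sd(C_sim) is judged against +-2.0:
SES > 2 indicates non-random segregation (competition-like structure),
SES < -2 non-random aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CommunityTable,
    DegenerateMatrixError,
    IncidenceMatrix,
    subset_trophic,
    to_incidence,
)
from .null_models import DegenerateNullError, NullDistribution, null_distribution

SES_THRESHOLD = 2.0  # 95% of null SES values fall in (-2, 2)


@dataclass
class CScoreResult:
    c_obs: float
    null: NullDistribution | None
    ses: float | None
    n_taxa: int
    n_sites: int
    group: str | None = None
    degenerate: bool = False

    @property
    def interpretation(self) -> str:
        if self.ses is None:
            return "degenerate"
        if self.ses > SES_THRESHOLD:
            return "segregated"
        if self.ses < -SES_THRESHOLD:
            return "aggregated"
        return "random"


def c_score(m: IncidenceMatrix) -> float:
    """Mean checkerboard units over all unordered genus pairs."""
    data = m.data.astype(np.int64)
    n_taxa = data.shape[1]
    if n_taxa < 2:
        raise DegenerateMatrixError("C-score needs at least 2 genera")
    shared = data.T @ data  # S for every pair, genus totals on the diagonal
    totals = np.diag(shared)
    cu = (totals[:, None] - shared) * (totals[None, :] - shared)
    iu = np.triu_indices(n_taxa, k=1)
    return float(cu[iu].mean())


def ses(obs: float, null: NullDistribution) -> float:
    """Standardized effect size: SDs between observation and null mean."""
    if null.sd == 0.0:
        raise DegenerateNullError("degenerate null: zero standard deviation")
    return float((obs - null.mean) / null.sd)


def cooccurrence_analysis(
    table: CommunityTable,
    group: str | None = None,
    n_sims: int = 10_000,
    seed: int = 0,
    threshold: int = 1,
) -> CScoreResult:
    """C-score and SES for a community (optionally one trophic group).

    The null holds both site richness and genus incidence fixed
    (sequential-swap chain); ``n_sims`` simulated matrices feed the SES.
    A subset that is degenerate after pruning (fewer than 2 genera or
    2 sites) is flagged and gets no SES.
    """
    try:
        unit = subset_trophic(table, group) if group is not None else table
        incidence = to_incidence(unit, threshold=threshold)
        if incidence.shape[0] < 2 or incidence.shape[1] < 2:
            raise DegenerateMatrixError("subset too small after pruning")
        obs = c_score(incidence)
    except DegenerateMatrixError:
        return CScoreResult(
            c_obs=float("nan"), null=None, ses=None, n_taxa=0, n_sites=0,
            group=group, degenerate=True,
        )
    null = null_distribution(c_score, incidence, method="fixed_fixed",
                             n_sims=n_sims, seed=seed)
    if null.degenerate:
        return CScoreResult(
            c_obs=obs, null=null, ses=None,
            n_taxa=incidence.shape[1], n_sites=incidence.shape[0],
            group=group, degenerate=True,
        )
    return CScoreResult(
        c_obs=obs,
        null=null,
        ses=ses(obs, null),
        n_taxa=incidence.shape[1],
        n_sites=incidence.shape[0],
        group=group,
    )
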