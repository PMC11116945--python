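"""Reciprocal-averaging (correspondence analysis) ordering of incidence matrices.

Reciprocal averaging iterates weighted averaging between site scores and genus
scores; its fixed point is the first non-trivial correspondence-analysis axis.
Sites with similar genus lists, and genera with similar distributions, end up
adjacent once rows and columns are sorted by their scores. The ordered matrix
is the substrate for all metacommunity-structure element counts, and the site
scores double as the gradient response for the importance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import DegenerateMatrixError, IncidenceMatrix

_TOL = 1e-10
_MAX_ITER = 1000


@dataclass
class OrdinationResult:
    """First-axis RA scores and the matrix reordered by them.

    ``site_scores`` / ``genus_scores`` are in the input row/column order;
    ``row_order`` / ``column_order`` are the permutations that sort them
    (ties broken by original index). ``degenerate`` marks a flat gradient
    (e.g. an all-ones matrix); ``warnings`` carries non-fatal conditions
    such as a block-disconnected input.
    """

    site_scores: np.ndarray
    genus_scores: np.ndarray
    row_order: np.ndarray
    column_order: np.ndarray
    ordered_matrix: IncidenceMatrix
    degenerate: bool = False
    warnings: list = field(default_factory=list)


def _ra_scores(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Power-iterate the averaging operator; returns (site, genus, degenerate)."""
    n, m = data.shape
    r = data.sum(axis=1).astype(float)
    c = data.sum(axis=0).astype(float)
    total = r.sum()
    v = np.linspace(-1.0, 1.0, n)
    v -= r @ v / total
    norm = np.sqrt(r @ (v**2) / total)
    if norm < 1e-12:  # n == 1 style corner
        return np.zeros(n), np.zeros(m), True
    v /= norm
    converged = False
    for _ in range(_MAX_ITER):
        u = (data.T @ v) / c
        v_new = (data @ u) / r
        v_new -= r @ v_new / total  # project out the trivial constant axis
        norm = np.sqrt(r @ (v_new**2) / total)
        if norm < 1e-12:
            return np.zeros(n), np.zeros(m), True  # no gradient (rank-1 matrix)
        v_new /= norm
        if min(np.max(np.abs(v_new - v)), np.max(np.abs(v_new + v))) < _TOL:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        # nearly tied leading axes stall the averaging iteration; fall back
        # to the exact eigen-solution of the standardized matrix
        p = data / total
        rr, cc = r / total, c / total
        std = (p - np.outer(rr, cc)) / np.sqrt(np.outer(rr, cc))
        uu, sv, _ = np.linalg.svd(std)
        if sv.size == 0 or sv[0] < 1e-12:
            return np.zeros(n), np.zeros(m), True
        v = uu[:, 0] / np.sqrt(rr)
        v -= r @ v / total
        norm = np.sqrt(r @ (v**2) / total)
        if norm < 1e-12:
            return np.zeros(n), np.zeros(m), True
        v /= norm
    u = (data.T @ v) / c
    return v, u, False


def _components(data: np.ndarray) -> np.ndarray:
    """Connected components of the bipartite site-genus graph (row labels)."""
    n, m = data.shape
    rows, cols = np.nonzero(data)
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols + n)), shape=(n + m, n + m)
    )
    _, labels = connected_components(adj + adj.T, directed=False)
    return labels


def reciprocal_averaging(m: IncidenceMatrix) -> OrdinationResult:
    """Order an incidence matrix along the first reciprocal-averaging axis.

    The sign of the axis is fixed so that, in input order, the first row's
    score does not exceed the last row's; a reversal never changes any of the
    downstream count statistics. Block-disconnected matrices get a warning and
    are ordered component by component, larger components first.

    Raises
    ------
    DegenerateMatrixError
        For matrices with fewer than 2 rows or 2 columns.
    """
    data = m.data
    n_rows, n_cols = data.shape
    if n_rows < 2 or n_cols < 2:
        raise DegenerateMatrixError(
            f"ordination needs at least 2 rows and 2 columns, got {data.shape}"
        )
    warnings: list[str] = []
    labels = _components(data)
    row_comp = labels[:n_rows]
    col_comp = labels[n_rows:]
    comp_ids, comp_sizes = np.unique(labels, return_counts=True)

    if len(comp_ids) == 1:
        site, genus, degenerate = _ra_scores(data)
    else:
        warnings.append(
            f"disconnected incidence matrix ({len(comp_ids)} components); "
            "components ordered by size"
        )
        # Rank components by descending size, ties by smallest member index.
        order = sorted(
            comp_ids,
            key=lambda cid: (-comp_sizes[comp_ids == cid][0], np.argmax(labels == cid)),
        )
        site = np.zeros(n_rows)
        genus = np.zeros(n_cols)
        degenerate = True  # flips to False if any component has a gradient
        for k, cid in enumerate(order):
            rsel = row_comp == cid
            csel = col_comp == cid
            block = data[np.ix_(rsel, csel)]
            if block.shape[0] >= 2 and block.shape[1] >= 2:
                s, g, deg = _ra_scores(block)
                degenerate = degenerate and deg
            else:
                s = np.zeros(block.shape[0])
                g = np.zeros(block.shape[1])
            # squash into (0, 1) then offset so component k occupies (2k, 2k+1)
            span = max(np.ptp(s) if s.size else 0.0,
                       np.ptp(g) if g.size else 0.0, 1.0)
            site[rsel] = 2.0 * k + 0.5 + s / (2.0 * span)
            genus[csel] = 2.0 * k + 0.5 + g / (2.0 * span)

    if degenerate:
        warnings.append("flat scores: no gradient in the incidence matrix")
    # Sign convention: first row's score <= last row's score in input order.
    # (Skipped for disconnected inputs, where size orders the components.)
    if len(comp_ids) == 1 and site[0] > site[-1]:
        site = -site
        genus = -genus
    row_order = np.argsort(site, kind="stable")
    column_order = np.argsort(genus, kind="stable")
    ordered = IncidenceMatrix(
        data=data[np.ix_(row_order, column_order)],
        row_labels=[m.row_labels[i] for i in row_order],
        col_labels=[m.col_labels[j] for j in column_order],
    )
    return OrdinationResult(
        site_scores=site,
        genus_scores=genus,
        row_order=row_order,
        column_order=column_order,
        ordered_matrix=ordered,
        degenerate=degenerate,
        warnings=warnings,
    )
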