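from itertools import combinations

import numpy as np
import pytest

from nemameta import (
    DegenerateMatrixError,
    IncidenceMatrix,
    classify_from_stats,
    ems_pipeline,
    embedded_absences,
    morisita_boundary,
    replacements,
)
from nemameta.datasets import ems_survey_summary
from nemameta.ems import fill_ranges
from nemameta.synthetic import SyntheticScenario, generate_metacommunity

from conftest import make_table


def brute_embedded_absences(data: np.ndarray, mode: str) -> int:
    """Oracle: literal per-column (and per-row) gap count."""

    def gaps(mat):
        total = 0
        for col in mat.T:
            ones = np.nonzero(col)[0]
            if ones.size:
                total += int((col[ones[0] : ones[-1] + 1] == 0).sum())
        return total

    return gaps(data) + (gaps(data.T) if mode == "both_axes" else 0)


def brute_replacements(data: np.ndarray) -> int:
    """Oracle: enumerate all site pairs x genus pairs on the filled matrix."""
    filled = fill_ranges(data)
    count = 0
    for a, b in combinations(range(data.shape[0]), 2):
        for g1, g2 in combinations(range(data.shape[1]), 2):
            x = filled[a, g1], filled[b, g1], filled[a, g2], filled[b, g2]
            if (x == (1, 0, 0, 1)) or (x == (0, 1, 1, 0)):
                count += 1
    return count


class TestEmbeddedAbsences:
    def test_banded_matrix_has_none(self):
        data = np.fromfunction(lambda i, j: (abs(i - j) <= 1).astype(int), (6, 6), dtype=int)
        assert embedded_absences(IncidenceMatrix(data)) == 0

    def test_hand_counted_example(self):
        m = IncidenceMatrix([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
        assert embedded_absences(m, mode="columns_only") == 1
        assert embedded_absences(m, mode="both_axes") == 2

    def test_all_ones_has_none(self):
        assert embedded_absences(IncidenceMatrix(np.ones((4, 5), dtype=int))) == 0

    @pytest.mark.parametrize("mode", ["both_axes", "columns_only"])
    def test_matches_oracle_on_random_matrices(self, mode, rng):
        for _ in range(50):
            data = (rng.random((6, 6)) < 0.5).astype(int)
            m = IncidenceMatrix(data)
            assert embedded_absences(m, mode) == brute_embedded_absences(data, mode)


class TestReplacements:
    def test_nested_matrix_has_none(self):
        data = np.tril(np.ones((5, 5), dtype=int))
        assert replacements(IncidenceMatrix(data)) == 0

    def test_checkerboard_pair(self):
        assert replacements(IncidenceMatrix([[1, 0], [0, 1]])) == 1

    def test_partial_overlap_example(self):
        # g1 at sites {1,2}, g2 at {2,3}: only the 1-3 site pair opposes
        m = IncidenceMatrix([[1, 0], [1, 1], [0, 1]])
        assert replacements(m) == 1

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            data = (rng.random((6, 6)) < 0.5).astype(int)
            m = IncidenceMatrix(data)
            assert replacements(m) == brute_replacements(data)


class TestMorisitaBoundary:
    def test_all_boundaries_on_one_site_is_maximal(self):
        # two genera occupying only site 0 of four: all 4 boundaries coincide
        m = IncidenceMatrix([[1, 1], [0, 0], [0, 0], [0, 0]])
        res = morisita_boundary(m)
        assert res.morisita_i == pytest.approx(4.0)
        assert res.df == 3

    def test_one_boundary_per_site_is_zero(self):
        # two genera spanning sites 0-3 and 1-2: boundaries at 4 distinct sites
        m = IncidenceMatrix([[1, 0], [1, 1], [1, 1], [1, 0]])
        res = morisita_boundary(m)
        assert res.morisita_i == pytest.approx(0.0)

    def test_two_balanced_clumps_approach_one_from_below(self):
        # both sites hold half of the F boundaries:
        # I = 2 * 2 * (F/2)(F/2 - 1) / (F(F-1)) -> 1 from below as F grows
        n_genera = 40
        data = np.zeros((2, n_genera), dtype=int)
        data[0, : n_genera // 2] = 1  # 2 boundaries each at site 0
        data[1, n_genera // 2 :] = 1  # 2 boundaries each at site 1
        res = morisita_boundary(IncidenceMatrix(data))
        f = 2 * n_genera
        expected = 2 * 2 * (f / 2) * (f / 2 - 1) / (f * (f - 1))
        assert res.morisita_i == pytest.approx(expected)
        assert 0.9 < res.morisita_i < 1.0

    def test_degenerate_single_site(self):
        with pytest.raises(DegenerateMatrixError):
            morisita_boundary(IncidenceMatrix([[1, 1]]))


class TestClassifier:
    def test_reproduces_all_published_labels(self):
        """The decision tree reproduces the published structure label for
        every one of the 15 survey analysis units from its printed
        element statistics."""
        table = ems_survey_summary()
        for _, row in table.iterrows():
            label = classify_from_stats(
                row.abs_obs, row.coh_mean, row.coh_p,
                row.rep_obs, row.tur_mean, row.tur_p,
                row.morisita_i, row.bnd_p,
            )
            assert label == row.label, f"{row.site} {row.land_cover}"

    @pytest.mark.parametrize(
        "stats,expected",
        [
            # (abs, mean, p) (rep, mean, p) (I, p)
            ((40, 102.21, 0.00, 639, 507.69, 0.08, 1.28, 0.01), "Quasi-Clementsian"),
            ((38, 159.54, 0.00, 1602, 1241.29, 0.00, 1.15, 0.02), "Clementsian"),
            ((44, 162.95, 0.00, 1463, 1652.90, 0.19, 1.15, 0.01),
             "Quasi-nested (clumped loss)"),
            ((43, 190.65, 0.00, 1800, 1463.85, 0.00, 1.07, 0.10), "Gleasonian"),
            # non-significant coherence dominates everything else
            ((40, 102.21, 0.50, 639, 507.69, 0.00, 1.28, 0.01), "Random"),
            # more embedded absences than expected: checkerboard
            ((200, 102.21, 0.00, 639, 507.69, 0.00, 1.28, 0.01), "Checkerboard"),
            # significant negative turnover with I significantly below 1
            ((40, 102.21, 0.00, 400, 507.69, 0.01, 0.60, 0.01),
             "Nested (hyperdispersed loss)"),
            ((40, 102.21, 0.00, 400, 507.69, 0.01, 1.00, 0.50),
             "Nested (stochastic loss)"),
            # positive turnover, I significantly below 1: evenly spaced
            ((40, 102.21, 0.00, 700, 507.69, 0.01, 0.60, 0.01), "Evenly spaced"),
        ],
    )
    def test_decision_tree_branches(self, stats, expected):
        a, am, ap, r, rm, rp, i, bp = stats
        assert classify_from_stats(a, am, ap, r, rm, rp, i, bp) == expected


class TestPipeline:
    def test_nested_scenario_recovers_nestedness(self):
        table = generate_metacommunity(
            SyntheticScenario(structure="nested", n_sites=20, n_taxa=24, seed=5)
        )
        res = ems_pipeline(table, "local", "grassland", "S1", n_sims=100, seed=2)
        assert res.label.startswith(("Nested", "Quasi-nested"))

    def test_random_scenario_mostly_random(self):
        hits = 0
        for seed in range(8):
            table = generate_metacommunity(
                SyntheticScenario(structure="random", n_sites=16, n_taxa=20,
                                  fill=0.5, seed=seed)
            )
            res = ems_pipeline(table, "local", "grassland", "S1",
                               n_sims=80, seed=seed + 100)
            hits += res.label == "Random"
        assert hits >= 5

    def test_degenerate_single_genus_unit_rejected(self):
        table = make_table([[1], [1], [1]], groups=["BF"])
        with pytest.raises(DegenerateMatrixError):
            ems_pipeline(table, "local", "farmland", "S1", n_sims=10, seed=0)

    def test_provenance_recorded(self, study):
        table, _ = study
        res = ems_pipeline(table, "local", "woodland", "Lishu", n_sims=30, seed=9)
        assert res.provenance["seed"] == 9
        assert res.provenance["n_sims"] == 30
        assert res.provenance["mode"] == "both_axes"
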