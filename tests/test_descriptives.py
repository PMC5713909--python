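"""Weighted crosstabs, chi-square contrasts, published-table reproduction."""

from types import SimpleNamespace

import numpy as np
import pytest

from trostar import table1
from trostar.descriptives import (
    printed_pseudo_records,
    reproduce_printed_table,
    round_half_up,
    weighted_chisq,
    weighted_crosstab,
)


def _rec(cat, y, w, cov="sex"):
    return SimpleNamespace(samp_weight=w, outcome=y, **{cov: cat})


class TestWeightedCrosstab:
    def test_single_record_is_hundred_percent(self):
        tab = weighted_crosstab([_rec("boys", 1, 3.5)], "sex")
        assert tab.row_labels == ["boys"]
        assert tab.weighted_N[0, 0] == pytest.approx(3.5)
        assert tab.col_pct[0, 0] == pytest.approx(100.0)

    def test_constant_weights_match_unweighted_percentages(self, rng):
        recs = [
            _rec(rng.choice(["boys", "girls"]), int(rng.random() < 0.3), 2.5)
            for _ in range(400)
        ]
        tab = weighted_crosstab(recs, "sex")
        unw = 100.0 * tab.unweighted_n / tab.unweighted_n.sum(axis=0)
        np.testing.assert_allclose(tab.col_pct, unw, atol=1e-10)

    def test_column_percentages_sum_to_hundred(self):
        recs = printed_pseudo_records("ecigarette", "grade")
        tab = weighted_crosstab(recs, "grade")
        np.testing.assert_allclose(tab.col_pct.sum(axis=0), 100.0, atol=1e-9)
        # display convention keeps columns within rounding slack of 100
        assert np.all(np.abs(tab.display_pct().sum(axis=0) - 100.0) <= 0.2)

    def test_published_sex_cigarette_current_column(self):
        """Printed weighted counts 7159 / 7092 give 50.2% / 49.8%."""
        tab = weighted_crosstab(printed_pseudo_records("cigarette", "sex"), "sex")
        disp = tab.display_pct()
        assert disp[tab.row_labels.index("boys"), 0] == 50.2
        assert disp[tab.row_labels.index("girls"), 0] == 49.8

    def test_unknown_covariate_error_and_empty_column_nan(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            weighted_crosstab([_rec("boys", 1, 1.0)], "shoe_size")
        tab = weighted_crosstab(
            [_rec("boys", 1, 1.0), _rec("girls", 1, 1.0)], "sex"
        )
        assert np.all(np.isnan(tab.col_pct[:, 1]))  # no non-users observed
        with pytest.raises(ValueError, match="marginal|empty"):
            weighted_chisq(tab)


class TestWeightedChisq:
    def test_independent_table_gives_zero_statistic(self):
        recs = (
            [_rec("boys", 1, 2.0)] * 10 + [_rec("girls", 1, 2.0)] * 10
            + [_rec("boys", 0, 2.0)] * 30 + [_rec("girls", 0, 2.0)] * 30
        )
        stat, df, p = weighted_chisq(weighted_crosstab(recs, "sex"))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_matches_hand_computed_pearson_oracle(self):
        # rescaled 2x2 counts (10, 20; 20, 10): X^2 = 60*(10*10-20*20)^2/(30^4)
        recs = (
            [_rec("boys", 1, 1.0)] * 10 + [_rec("boys", 0, 1.0)] * 20
            + [_rec("girls", 1, 1.0)] * 20 + [_rec("girls", 0, 1.0)] * 10
        )
        stat, df, _ = weighted_chisq(weighted_crosstab(recs, "sex"))
        oracle = 60 * (10 * 10 - 20 * 20) ** 2 / 30**4
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert df == 1

    def test_invariant_to_uniform_weight_rescaling(self):
        base = (
            [_rec("boys", 1, 1.0)] * 13 + [_rec("boys", 0, 1.0)] * 20
            + [_rec("girls", 1, 1.0)] * 25 + [_rec("girls", 0, 1.0)] * 9
        )
        doubled = [SimpleNamespace(**{**r.__dict__, "samp_weight": 2.0}) for r in base]
        s1, _, _ = weighted_chisq(weighted_crosstab(base, "sex"))
        s2, _, _ = weighted_chisq(weighted_crosstab(doubled, "sex"))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_monotone_in_departure_from_independence(self):
        def stat_for(a):
            recs = (
                [_rec("boys", 1, 1.0)] * a + [_rec("boys", 0, 1.0)] * (30 - a)
                + [_rec("girls", 1, 1.0)] * (30 - a) + [_rec("girls", 0, 1.0)] * a
            )
            return weighted_chisq(weighted_crosstab(recs, "sex"))[0]

        stats_ = [stat_for(a) for a in (15, 12, 9, 6)]
        assert all(x < y for x, y in zip(stats_, stats_[1:]))


class TestPrintedTableReproduction:
    @pytest.mark.parametrize("outcome", table1.OUTCOMES)
    def test_consistent_cells_reproduce_exactly(self, outcome):
        for cov in table1.covariates(outcome):
            _, comparisons = reproduce_printed_table(outcome, cov)
            for cat, col, printed, recomputed, consistent in comparisons:
                if consistent:
                    assert recomputed == printed, (outcome, cov, cat, col)
                else:
                    assert recomputed != printed, (outcome, cov, cat, col)

    def test_unweighted_counts_match_printed_n(self):
        tab, _ = reproduce_printed_table("cigarette", "grade")
        by_cat = {c.category: c for c in table1.cells_for("cigarette", "grade")
                  if c.column == "current_user"}
        for i, lab in enumerate(tab.row_labels):
            assert tab.unweighted_n[i, 0] == by_cat[lab].n


def test_round_half_up_convention():
    assert round_half_up(50.25) == 50.3  # bankers' rounding would give 50.2
    assert round_half_up(50.24) == 50.2
    assert round_half_up(-1.05) == -1.1
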