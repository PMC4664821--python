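"""The statistical battery: paired t, Wilcoxon, 2x2 within-subject ANOVA,
normality-gated correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rtg.errors import MissingCellError, ParameterError
from rtg.stats import (
    excitability_behavior_correlation,
    paired_t,
    rm_anova_2x2,
    wilcoxon_signed_rank,
)


def anova_table(y, conditions=("real", "sham"), times=("pre", "post")):
    """y: (n_subjects, 2, 2) array -> long-format DataFrame."""
    rows = []
    for s in range(y.shape[0]):
        for i, c in enumerate(conditions):
            for j, t in enumerate(times):
                rows.append({"subject": f"S{s}", "condition": c, "time": t,
                             "value": y[s, i, j]})
    return pd.DataFrame(rows)


class TestPairedT:
    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_symmetric_differences_give_zero_t(self):
        rep = paired_t(np.array([1.0, 2.0]), np.array([0.0, 3.0]))  # d = {1, -1}
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_constant_shift_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ParameterError, match="zero variance"):
            paired_t(x, x + 3.0)

    def test_location_shift_invariance(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        a, b = paired_t(x, y), paired_t(x + 100.0, y + 100.0)
        assert a.statistic == pytest.approx(b.statistic)


class TestWilcoxon:
    def test_six_positive_pairs_exact_p(self):
        x = np.arange(1.0, 7.0)
        rep = wilcoxon_signed_rank(x + np.arange(1, 7) * 0.5, x)
        assert rep.p_value == pytest.approx(0.03125, abs=1e-12)
        assert rep.notes.startswith("exact")

    def test_antisymmetric_pair_gives_p_one(self):
        rep = wilcoxon_signed_rank(np.array([1.0, 2.0]), np.array([0.0, 3.0]))
        assert rep.p_value == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ParameterError):
            wilcoxon_signed_rank(x, x)

    def test_exact_p_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 13))
            d = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1.0, 1.0], size=n)
            x = np.zeros(n)
            rep = wilcoxon_signed_rank(x + d, x)
            ref = sps.wilcoxon(x + d, x, method="exact")
            assert rep.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_p_matches_full_enumeration_with_ties(self, rng):
        # independent oracle: explicit 2^n sign patterns via itertools
        d = np.array([1.0, 1.0, -2.0, 3.0, 3.0, 4.0, -1.0])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
        count = sum(
            (np.dot(signs, ranks) <= lo + 1e-9) + (np.dot(signs, ranks) >= hi - 1e-9)
            for signs in itertools.product([0, 1], repeat=len(d))
        )
        expected = min(1.0, count / 2.0 ** len(d))
        rep = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert rep.p_value == pytest.approx(expected, abs=1e-12)

    def test_z_statistic_matches_manual_computation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        n = len(d)
        mu = n * (n + 1) / 4
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z_manual = (w - mu - 0.5 * np.sign(w - mu)) / sigma
        rep = wilcoxon_signed_rank(x, y)
        assert rep.statistic == pytest.approx(z_manual, abs=1e-12)


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        y = np.full((6, 2, 2), 3.0)
        res = rm_anova_2x2(anova_table(y))
        for rep in res.values():
            assert rep.statistic == 0.0
            assert rep.p_value == 1.0

    def test_interaction_equals_squared_paired_t_on_difference_of_differences(self, rng):
        y = rng.normal(size=(9, 2, 2))
        res = rm_anova_2x2(anova_table(y))
        dd = (y[:, 0, 1] - y[:, 0, 0]) - (y[:, 1, 1] - y[:, 1, 0])
        t = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
        assert res["interaction"].statistic == pytest.approx(t**2, abs=1e-9)

    def test_matches_pingouin_two_way_rm_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(size=(7, 2, 2)) + rng.normal(size=(7, 1, 1))
        table = anova_table(y)
        mine = rm_anova_2x2(table)
        ref = pingouin.rm_anova(
            data=table, dv="value", within=["condition", "time"],
            subject="subject", detailed=True,
        ).set_index("Source")
        assert mine["condition"].statistic == pytest.approx(ref.loc["condition", "F"], rel=1e-8)
        assert mine["time"].statistic == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["condition * time", "F"], rel=1e-8
        )
        p_col = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert mine["interaction"].p_value == pytest.approx(
            ref.loc["condition * time", p_col], rel=1e-8
        )

    def test_location_shift_invariance(self, rng):
        y = rng.normal(size=(5, 2, 2))
        a = rm_anova_2x2(anova_table(y))
        b = rm_anova_2x2(anova_table(y + 50.0))
        for key in a:
            assert a[key].statistic == pytest.approx(b[key].statistic, abs=1e-8)

    def test_missing_cell_listed_in_error(self, rng):
        table = anova_table(rng.normal(size=(4, 2, 2)))
        table = table[~((table.subject == "S2") & (table.condition == "real")
                        & (table.time == "post"))]
        with pytest.raises(MissingCellError, match="S2"):
            rm_anova_2x2(table)

    def test_null_interaction_pvalues_uniform(self):
        from rtg.simulations import null_interaction_pvalues

        pvals = null_interaction_pvalues(500, seed=2024)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExcitabilityCorrelation:
    def test_linear_relation_selects_pearson(self, rng):
        x = rng.normal(size=12)
        rep = excitability_behavior_correlation(x, 2.0 * x)
        assert "pearson" in rep.test_name
        assert rep.statistic == pytest.approx(1.0)

    def test_monotone_nonlinear_relation_under_spearman(self, rng):
        x = rng.exponential(size=30) ** 3  # heavily skewed: fails normality
        rep = excitability_behavior_correlation(x, np.log(x + 1.0))
        assert "spearman" in rep.test_name
        assert rep.statistic == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ParameterError):
            excitability_behavior_correlation(np.ones(6), np.arange(6.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            excitability_behavior_correlation(np.arange(3.0), np.arange(3.0))
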