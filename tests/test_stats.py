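import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bifidopanel import cohort as coh
from bifidopanel import stats as bst
from bifidopanel.plsda import PLSDA

from conftest import exact_rank_sum_p


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, expected_p",
        [
            ([1, 2, 3], [4, 5, 6], 2 / 20),
            ([1, 2, 3, 4], [5, 6, 7, 8], 2 / 70),
            ([1, 3, 5], [2, 4, 6], 14 / 20),  # U=3, 2*P(U<=3) by enumeration
        ],
    )
    def test_exact_examples(self, x, y, expected_p):
        _, p = bst.rank_sum_test(x, y)
        assert math.isclose(p, expected_p, rel_tol=1e-12)
        assert math.isclose(exact_rank_sum_p(x, y), expected_p, rel_tol=1e-12)

    def test_identical_tied_samples_give_p_one(self):
        x = [1.0, 2.0, 2.0, 3.0] * 4
        assert bst.rank_sum_test(x, x)[1] == 1.0
        assert bst.rank_sum_test([5.0] * 6, [5.0] * 4)[1] == 1.0

    def test_symmetry_in_group_order(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(0.5, 1, size=9)
        assert math.isclose(
            bst.rank_sum_test(x, y)[1], bst.rank_sum_test(y, x)[1], rel_tol=1e-12
        )

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            bst.rank_sum_test([], [1, 2])

    def test_matches_enumeration_oracle_small_n(self):
        """Spot-check rank configurations up to combined n = 8 against the
        full-enumeration oracle (the exhaustive n <= 10 sweep runs with
        the acceptance checks)."""
        for n in range(2, 9):
            for nx in range(1, n):
                for xs_idx in itertools.combinations(range(n), nx):
                    ranks = np.arange(1.0, n + 1)
                    x = ranks[list(xs_idx)]
                    y = np.delete(ranks, list(xs_idx))
                    _, p = bst.rank_sum_test(x, y)
                    assert math.isclose(p, exact_rank_sum_p(x, y), rel_tol=1e-12), (
                        x, y,
                    )


@pytest.fixture(scope="module")
def metab_table():
    parts = coh.generate_participants(coh.default_study_design(), 55)
    metab = coh.generate_metabolites(parts, coh.default_effect_template(), 56)
    return metab.merge(parts[["id", "group"]], on="id")


class TestPairwise:
    def test_comparison_count(self, metab_table):
        out = bst.pairwise_group_tests(metab_table, list(coh.METABOLITES))
        assert len(out) == 36  # 3 unordered pairs x 12 analytes
        assert out["p_value"].between(0, 1).all()

    def test_constant_variable_gives_p_one(self, metab_table):
        t = metab_table.copy()
        t["flat"] = 3.14
        out = bst.pairwise_group_tests(t, ["flat"])
        assert (out["p_value"] == 1.0).all()

    def test_unknown_group_rejected(self, metab_table):
        with pytest.raises(ValueError, match="adults"):
            bst.pairwise_group_tests(metab_table, ["valine"], groups=["control", "adults"])

    def test_optional_fdr_column(self, metab_table):
        out = bst.pairwise_group_tests(metab_table, list(coh.METABOLITES), fdr=True)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        # the raw significance flag is untouched by the adjustment
        assert (out["significant"] == (out["p_value"] < 0.05)).all()


class TestChiSquare:
    def test_proportional_table(self):
        stat, p = bst.chi_square_independence([[10, 10], [20, 20]])
        assert stat == 0.0 and p == 1.0

    def test_study_sex_by_group_independent(self):
        stat, p = bst.chi_square_independence([[22, 25, 8], [17, 15, 10]])
        assert p > 0.05

    def test_perfect_association(self):
        stat, p = bst.chi_square_independence([[50, 0], [0, 50]])
        assert math.isclose(stat, 100.0)
        assert p < 1e-10

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            bst.chi_square_independence([[0, 0], [5, 5]])
        with pytest.raises(ValueError, match="non-negative"):
            bst.chi_square_independence([[1, -1], [2, 2]])


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert bst.spearman(x, np.exp(x))[0] == 1.0
        assert bst.spearman(x, -x)[0] == -1.0

    def test_hand_ranked_example(self):
        rho, _ = bst.spearman([1, 2, 3], [3, 1, 2])
        assert math.isclose(rho, -0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bst.spearman([1, 1, 1], [1, 2, 3])

    def test_equals_pearson_of_midranks(self, rng):
        x = rng.integers(0, 6, size=60).astype(float)  # heavy ties
        y = x * 0.5 + rng.normal(size=60)
        rho, _ = bst.spearman(x, y)
        pearson = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert math.isclose(rho, pearson, abs_tol=1e-12)


class TestCorrelationMatrix:
    def test_symmetry_unit_diagonal_and_duplicates(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        df["a2"] = df["a"]
        cm = bst.correlation_matrix(df, ["a", "b", "c", "a2"])
        assert np.allclose(cm.rho, cm.rho.T, equal_nan=True)
        assert (np.diag(cm.rho) == 1.0).all()
        assert cm.rho.loc["a", "a2"] == 1.0
        assert (cm.rho.abs() <= 1.0).all().all()

    def test_sparse_pairs_flagged_unavailable(self):
        df = pd.DataFrame({"a": [1, 2, np.nan, np.nan], "b": [np.nan, 1, 2, 3]})
        cm = bst.correlation_matrix(df, ["a", "b"])
        assert np.isnan(cm.rho.loc["a", "b"])
        assert np.isnan(cm.p.loc["a", "b"])

    def test_engineered_dependence_stands_out(self, rng):
        n = 80
        latent = rng.normal(size=n)
        df = pd.DataFrame({
            "infantis": latent + 0.3 * rng.normal(size=n),
            "valine": latent + 0.3 * rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        cm = bst.correlation_matrix(df, list(df.columns))
        off = cm.rho.where(~np.eye(4, dtype=bool)).abs()
        assert cm.rho.loc["infantis", "valine"] > off.stack().median()

    def test_long_form_round(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        cm = bst.correlation_matrix(df, ["a", "b"])
        long = cm.to_long()
        assert len(long) == 4
        assert math.isclose(
            long.set_index(["variable_a", "variable_b"]).loc[("a", "b"), "rho"],
            cm.rho.loc["a", "b"],
        )


class TestAutoscale:
    def test_hand_example_and_idempotence(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "w": [2.0, 4.0, 9.0]})
        scaled, means, scales = bst.autoscale(df)
        assert np.allclose(scaled["v"], [-1, 0, 1])
        assert (scales > 0).all()
        again, _, _ = bst.autoscale(scaled)
        assert np.allclose(again, scaled, atol=1e-12)
        assert np.allclose(scaled.mean(), 0, atol=1e-12)
        assert np.allclose(scaled.std(ddof=1), 1, atol=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            bst.autoscale(df)


class TestDemographics:
    def test_printed_count_percentages(self):
        rows = []
        for group, m, f in [("control", 22, 17), ("t1d", 25, 15), ("obese", 8, 10)]:
            for i in range(m + f):
                rows.append({
                    "id": f"{group}{i}", "group": group,
                    "sex": "M" if i < m else "F",
                    "age": 12.0, "bmi": 21.0, "hba1c": np.nan,
                })
        summary = bst.demographic_summary(pd.DataFrame(rows)).table.set_index("group")
        assert summary.loc["control", "male_pct"] == 56.4
        assert summary.loc["t1d", "male_pct"] == 62.5
        assert summary.loc["obese", "male_pct"] == 44.4

    def test_single_sex_group(self):
        df = pd.DataFrame({
            "id": ["a", "b"], "group": "g", "sex": ["M", "M"],
            "age": [10.0, 12.0], "bmi": [20.0, 22.0], "hba1c": [np.nan, np.nan],
        })
        s = bst.demographic_summary(df).table
        assert s.loc[0, "male_pct"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bst.demographic_summary(pd.DataFrame(columns=["group", "sex", "age", "bmi"]))


def test_lv_association_self_covariate(rng):
    X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
    labels = np.array(["g1"] * 20 + ["g2"] * 20)
    res = PLSDA(X, labels).fit()
    rho, p = bst.lv_association(res, res.x_scores.iloc[:, 0])
    assert rho == 1.0
    with pytest.raises(ValueError, match="length"):
        bst.lv_association(res, np.arange(7))
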