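import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from omicnet.correlation import (
    classify_concordance,
    concordance_table,
    group_mean_zscores,
    spearman_by_subgroup,
)

from conftest import make_matrix, make_metadata


def correlation_input(features, esr, groups=None, seed=0):
    """Matrix + metadata where one RA subgroup carries the given marker."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    groups = groups or ["ACPA_NEG"] * n
    meta = make_metadata(groups, seed=seed, esr=esr,
                         smoking=["NEVER_FORMER"] * n)
    data = make_matrix(features, sample_ids=meta.sample_ids)
    return data, meta


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [1, 4, 9, 16], 1.0),        # monotone map
            ([1, 2, 3, 4], [16, 9, 4, 1], -1.0),       # antitone map
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),         # 1 - 6*4/(4*15)
        ],
    )
    def test_known_rhos(self, x, y, expected):
        data, meta = correlation_input(np.array(x).reshape(-1, 1), y)
        res = spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",))
        assert res["rho"][0] == pytest.approx(expected)

    def test_matches_scipy_with_ties_and_missing_marker(self):
        rng = np.random.default_rng(3)
        n = 30
        feats = rng.integers(0, 5, size=(n, 4)).astype(float)  # heavy ties
        esr = rng.integers(0, 6, n).astype(float)
        esr[:5] = np.nan  # pairwise-complete handling
        data, meta = correlation_input(feats, esr)
        res = spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",))
        keep = ~np.isnan(esr)
        for j, fid in enumerate(data.feature_ids):
            rho, p = spearmanr(feats[keep, j], esr[keep])
            row = res[res["feature_id"] == fid].iloc[0]
            assert row["rho"] == pytest.approx(rho, abs=1e-12)
            assert row["p"] == pytest.approx(p, abs=1e-9)
            assert row["n_pairs"] == keep.sum()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(20, 2))
        esr = rng.gamma(2, 5, 20)
        data, meta = correlation_input(feats, esr)
        r1 = spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",))
        data2, meta2 = correlation_input(np.exp(feats), esr ** 3)
        r2 = spearman_by_subgroup(data2, meta2, "ESR", subgroups=("ACPA_NEG",))
        assert np.allclose(r1["rho"], r2["rho"])

    def test_constant_feature_flagged_not_raised(self):
        data, meta = correlation_input(np.ones((8, 1)), np.arange(8.0))
        res = spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",))
        assert res["degenerate"][0] and np.isnan(res["rho"][0])

    def test_too_few_marker_values_errors(self):
        data, meta = correlation_input(np.random.default_rng(0).normal(size=(6, 1)),
                                       [1.0, 2.0, 3.0] + [np.nan] * 3)
        with pytest.raises(ValueError, match="only 3"):
            spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",))

    def test_unknown_marker(self):
        data, meta = correlation_input(np.ones((5, 1)), np.arange(5.0))
        with pytest.raises(ValueError, match="marker"):
            spearman_by_subgroup(data, meta, "TNF")


def res_row(rho, p, feature="f", marker="ESR"):
    return pd.Series({"feature_id": feature, "marker": marker, "rho": rho, "p": p})


class TestConcordance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0.5, 0.01), (-0.1, 0.6), "A_specific_pos"),
            ((0.6, 0.01), (0.6, 0.01), "concordant_pos"),
            ((-0.6, 0.01), (-0.5, 0.02), "concordant_neg"),
            ((0.45, 0.01), (-0.45, 0.01), "opposite"),
            ((-0.1, 0.6), (-0.5, 0.04), "B_specific_neg"),
            ((0.2, 0.3), (0.1, 0.8), "none"),
        ],
    )
    def test_categories(self, a, b, expected):
        assert classify_concordance(res_row(*a), res_row(*b)) == expected

    def test_swap_symmetry(self):
        swap = {"A_specific_pos": "B_specific_pos",
                "A_specific_neg": "B_specific_neg",
                "B_specific_pos": "A_specific_pos",
                "B_specific_neg": "A_specific_neg"}
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = res_row(rng.uniform(-1, 1), rng.uniform(0, 1))
            b = res_row(rng.uniform(-1, 1), rng.uniform(0, 1))
            cat = classify_concordance(a, b)
            swapped = classify_concordance(b, a)
            assert swapped == swap.get(cat, cat)

    def test_mismatched_feature_errors(self):
        with pytest.raises(ValueError):
            classify_concordance(res_row(0.5, 0.01, feature="x"),
                                 res_row(0.5, 0.01, feature="y"))

    def test_concordance_table_shape(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(40, 3))
        groups = ["ACPA_NEG"] * 20 + ["ACPA_POS"] * 20
        data, meta = correlation_input(feats, rng.gamma(2, 6, 40), groups=groups)
        corr = spearman_by_subgroup(data, meta, "ESR")
        tab = concordance_table(corr)
        assert len(tab) == 3
        assert set(tab.columns) >= {"rho_A", "rho_B", "category"}


class TestGroupMeanZscores:
    def test_equally_spaced_means(self):
        vals = np.r_[np.full((4, 1), 1.0), np.full((4, 1), 2.0), np.full((4, 1), 3.0)]
        meta = make_metadata(["ACPA_NEG"] * 4 + ["ACPA_POS"] * 4 + ["CONTROL"] * 4)
        data = make_matrix(vals, sample_ids=meta.sample_ids)
        z = group_mean_zscores(data, meta)
        assert np.allclose(
            z.loc["F0", ["ACPA_NEG", "ACPA_POS", "CONTROL"]], [-1, 0, 1]
        )

    def test_degenerate_and_row_normalization(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 5))
        vals[:, 0] = 7.0  # equal group means
        meta = make_metadata(["ACPA_NEG"] * 4 + ["ACPA_POS"] * 4 + ["CONTROL"] * 4)
        data = make_matrix(vals, sample_ids=meta.sample_ids)
        z = group_mean_zscores(data, meta)
        gcols = ["ACPA_NEG", "ACPA_POS", "CONTROL"]
        assert (z.loc["F0", gcols] == 0).all() and z.loc["F0", "degenerate"]
        assert np.allclose(z[gcols].mean(axis=1), 0, atol=1e-12)


class TestExactPermutationP:
    def test_exact_matches_enumeration_oracle(self):
        from itertools import permutations

        from omicnet.correlation import spearman_exact_p

        rng = np.random.default_rng(7)
        for _ in range(3):
            x, y = rng.normal(size=(2, 6))
            ours = spearman_exact_p(x, y)
            obs = abs(spearmanr(x, y).statistic)
            count = total = 0
            for perm in permutations(y):
                total += 1
                count += abs(spearmanr(x, perm).statistic) >= obs - 1e-12
            assert ours == pytest.approx(count / total, abs=1e-10)

    def test_requires_small_n(self):
        from omicnet.correlation import spearman_exact_p

        with pytest.raises(ValueError, match="n < 10"):
            spearman_exact_p(np.arange(12), np.arange(12))

    def test_exact_method_through_subgroup_api(self):
        rng = np.random.default_rng(8)
        feats = rng.normal(size=(8, 2))
        data, meta = correlation_input(feats, rng.gamma(2, 5, 8))
        res = spearman_by_subgroup(data, meta, "ESR", subgroups=("ACPA_NEG",),
                                   p_method="exact")
        assert res["p"].between(0, 1).all()
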