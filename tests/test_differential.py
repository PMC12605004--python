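import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from omicnet.differential import (
    _ols_t_tests,
    cohens_d,
    differential_features,
    fit_adjusted_lm,
    subset_treatment_naive,
)
from omicnet.io import (
    SampleMetadata,
    merge_omics,
    preprocess_metabolites,
    preprocess_proteins,
)
from omicnet.simulate import SyntheticConfig, evenly_planted, generate_cohort

from conftest import make_matrix, make_metadata


class TestCohensD:
    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_scale_invariance(self, a, b, k):
        a, b = np.array(a), np.array(b)
        if a.var() + b.var() == 0:
            return
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, abs=1e-10)
        assert cohens_d(k * a, k * b) == pytest.approx(d, rel=1e-9)

    def test_degenerate_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1, 1], [2, 2])


class TestFitAdjustedLm:
    def test_perfect_group_separation(self):
        design = pd.DataFrame({"const": 1.0, "g": [0, 0, 0, 1, 1, 1.0]})
        y = design["g"].to_numpy()
        beta, p = fit_adjusted_lm(y, design, "g")
        assert beta == pytest.approx(1.0)
        assert p < 1e-12

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"const": 1.0, "g": rng.integers(0, 2, 30).astype(float),
             "age": rng.normal(50, 8, 30), "bmi": rng.normal(28, 5, 30)}
        )
        y = 0.4 * X["g"] + 0.02 * X["age"] + rng.normal(0, 1, 30)
        beta, p = fit_adjusted_lm(y.to_numpy(), X, "g")
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_matches_normal_equations_brute_force(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
        Y = rng.normal(size=(25, 4))
        beta, _, _ = _ols_t_tests(X, Y)
        brute = np.linalg.solve(X.T @ X, X.T @ Y).T
        assert np.allclose(beta, brute, atol=1e-8)

    def test_rank_deficient_names_columns(self):
        design = pd.DataFrame(
            {"const": 1.0, "g": [0, 1, 0, 1.0], "g2": [0, 2, 0, 2.0]}
        )
        with pytest.raises(ValueError, match="g2|g"):
            fit_adjusted_lm(np.ones(4), design, "g")

    def test_type_one_error_calibrated(self):
        # pure-noise features against a random binary phenotype
        rng = np.random.default_rng(6)
        n, reps = 2000, 1000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        Y = rng.normal(size=(n, reps))
        _, _, p = _ols_t_tests(X, Y)
        frac = (p[:, 1] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


@pytest.fixture(scope="module")
def prepared(small_cohort):
    (prot, met, meta, truth), cfg = small_cohort
    merged = merge_omics(preprocess_proteins(prot), preprocess_metabolites(met)[0])
    return merged, meta, truth


class TestDifferentialFeatures:

    def test_threshold_logic_and_directions(self, prepared):
        merged, meta, _ = prepared
        res = differential_features(merged, meta, "ACPA_NEG_vs_CTRL")
        strict = (res["p"] < 0.01) & (res["d"].abs() > 0.5)
        relaxed = (res["p"] < 0.05) & (res["d"].abs() > 0.5)
        assert (res["passes_strict"] == strict).all()
        assert (res["passes_relaxed"] == relaxed).all()
        assert (res["passes_strict"] <= res["passes_relaxed"]).all()
        assert (np.sign(res.loc[res["d"] != 0, "d"]) ==
                np.where(res.loc[res["d"] != 0, "direction"] == "up", 1, -1)).all()

    def test_planted_features_recovered(self, prepared):
        merged, meta, truth = prepared
        res = differential_features(merged, meta, "ACPA_NEG_vs_CTRL")
        planted_neg = [e.feature_id for e in truth.planted
                       if e.groups == ("ACPA_NEG",)]
        hits = set(res.loc[res["passes_strict"], "feature_id"])
        assert len(hits & set(planted_neg)) >= 0.8 * len(planted_neg)

    def test_confounded_effect_shrinks_when_adjusted(self):
        # feature driven purely by BMI, and BMI differs by group:
        # adjusting for BMI must shrink the phenotype coefficient
        rng = np.random.default_rng(8)
        n = 60
        groups = ["ACPA_NEG"] * 30 + ["CONTROL"] * 30
        bmi = np.r_[rng.normal(33, 4, 30), rng.normal(27, 4, 30)]
        meta = make_metadata(groups, seed=8, bmi=bmi,
                             smoking=["NEVER_FORMER"] * n)
        y = 0.3 * bmi + rng.normal(0, 1, n)
        data = make_matrix(y.reshape(-1, 1), sample_ids=meta.sample_ids,
                           feature_ids=["confounded"])
        adj = differential_features(data, meta, "ACPA_NEG_vs_CTRL",
                                    covariates=("bmi",))
        unadj = differential_features(data, meta, "ACPA_NEG_vs_CTRL",
                                      covariates=())
        assert abs(adj["beta"][0]) < abs(unadj["beta"][0])

    def test_too_few_samples_errors(self):
        meta = make_metadata(["ACPA_NEG"] * 2 + ["CONTROL"] * 5,
                             smoking=["NEVER_FORMER"] * 7)
        data = make_matrix(np.random.default_rng(0).normal(size=(7, 2)),
                           sample_ids=meta.sample_ids)
        with pytest.raises(ValueError, match="fewer than 3"):
            differential_features(data, meta, "ACPA_NEG_vs_CTRL")

    def test_unknown_comparison(self, prepared):
        merged, meta, _ = prepared
        with pytest.raises(ValueError, match="comparison"):
            differential_features(merged, meta, "RA_vs_RA")


class TestTreatmentNaive:
    def test_all_flags_false_returns_everyone(self):
        meta = make_metadata(["ACPA_NEG", "CONTROL"])
        assert subset_treatment_naive(meta) == meta.sample_ids

    def test_single_medication_excludes(self):
        meta = make_metadata(["ACPA_NEG", "ACPA_NEG", "CONTROL"],
                             med_prednisone=[True, False, False])
        assert subset_treatment_naive(meta) == ["S1", "S2"]

    def test_rerun_on_naive_subset_drops_constant_med_covariates(self, small_cohort):
        (prot, met, meta, _), _ = small_cohort
        merged = merge_omics(preprocess_proteins(prot),
                             preprocess_metabolites(met)[0])
        naive = subset_treatment_naive(meta)
        sub_meta = meta.subset(naive)
        sub = merged.with_values(merged.values.loc[naive])
        res = differential_features(sub, sub_meta, "ACPA_NEG_vs_CTRL")
        assert len(res) == len(merged.feature_ids)
        assert (res["n_used"] <= len(naive)).all()
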