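import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from omicnet.classify import (
    TaskSpec,
    compute_metrics,
    permute_labels,
    run_task,
    stratified_folds,
)
from omicnet.io import filter_by_missingness, scale_and_impute
from omicnet.simulate import SyntheticConfig, evenly_planted, generate_cohort

from conftest import make_metadata


class TestStratifiedFolds:
    def test_balanced_cohort_gives_equal_test_counts(self):
        meta = make_metadata(["ACPA_NEG"] * 40 + ["ACPA_POS"] * 40 + ["CONTROL"] * 40)
        folds = stratified_folds(meta, k=5, seed=0)
        for f in range(5):
            counts = meta.frame.loc[folds[folds == f].index, "group"].value_counts()
            assert (counts == 8).all()

    def test_deterministic(self):
        meta = make_metadata(["ACPA_NEG"] * 20 + ["CONTROL"] * 20)
        assert stratified_folds(meta, 5, seed=3).equals(
            stratified_folds(meta, 5, seed=3)
        )

    def test_remainder_spread(self):
        meta = make_metadata(["ACPA_NEG"] * 41 + ["ACPA_POS"] * 40 + ["CONTROL"] * 40)
        folds = stratified_folds(meta, k=5, seed=1)
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_k_larger_than_group_errors(self):
        meta = make_metadata(["ACPA_NEG"] * 3 + ["CONTROL"] * 40)
        with pytest.raises(ValueError, match="smallest group"):
            stratified_folds(meta, k=5)


class TestComputeMetrics:
    def test_confusion_panel_hand_example(self):
        # TP=7, FN=1, TN=6, FP=2
        y = [1] * 8 + [0] * 8
        s = [0.9] * 7 + [0.1] + [0.8] * 2 + [0.2] * 6
        m = compute_metrics(y, s)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (7, 1, 6, 2)
        assert m["sensitivity"] == pytest.approx(0.875)
        assert m["specificity"] == pytest.approx(0.75)
        assert m["ppv"] == pytest.approx(7 / 9)
        assert m["npv"] == pytest.approx(6 / 7)
        assert m["accuracy"] == pytest.approx(0.8125)
        assert m["mcc"] == pytest.approx(40 / np.sqrt(4032))
        assert m["f1"] == pytest.approx(14 / 17)

    def test_perfect_separation_auc_one(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["auc"] == 1.0

    def test_auc_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 5, 30) / 4  # heavy ties
            assert compute_metrics(y, s)["auc"] == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        s = rng.random(40)
        a1 = compute_metrics(y, s)["auc"]
        a2 = compute_metrics(y, s ** 3)["auc"]  # monotone on [0, 1]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_flagged(self):
        m = compute_metrics([1, 1, 1], [0.2, 0.6, 0.9])
        assert np.isnan(m["auc"])
        assert np.isnan(m["specificity"])  # no negatives: denominator zero


@pytest.fixture(scope="module")
def mini_cohort():
    """Small, fast cohort for classification harness tests."""
    cfg = SyntheticConfig(
        n_per_group=15, n_proteins=24, n_metabolites=8, n_factors=8,
        planted=evenly_planted(8, 1.5, 24, 8), seed=17,
    )
    prot, met, meta, truth = generate_cohort(cfg)
    met_ready = scale_and_impute(filter_by_missingness(met)[0])
    return prot, met_ready, meta, truth


class TestRunTask:
    def test_anova_selector_end_to_end(self, mini_cohort):
        prot, met, meta, _ = mini_cohort
        spec = TaskSpec(task="ACPA_NEG_vs_CTRL", modality="multi",
                        selector="anova_f", n_grid=(5, 10), rf_trees=60,
                        cv_seed=1, k_folds=3)
        res = run_task(prot, met, meta, spec)
        assert len(res.per_fold) == 3 * 2
        assert res.best_n in (5, 10)
        assert set(res.fold_features[0]["5"]) <= set(
            list(prot.feature_ids) + list(met.feature_ids)
        )
        assert np.isfinite(res.summary.loc["auc", "mean"])

    def test_selector_none_ignores_grid(self, mini_cohort):
        prot, met, meta, _ = mini_cohort
        spec = TaskSpec(selector="none", n_grid=(5, 10), rf_trees=40,
                        cv_seed=1, k_folds=3)
        with pytest.warns(UserWarning, match="ignores n_grid"):
            res = run_task(prot, met, meta, spec)
        assert res.per_fold["n"].unique().tolist() == ["all"]
        assert res.best_n is None

    def test_ra_vs_ctrl_pools_subgroups(self, mini_cohort):
        prot, met, meta, _ = mini_cohort
        spec = TaskSpec(task="RA_vs_CTRL", selector="anova_f", n_grid=(8,),
                        rf_trees=40, cv_seed=2, k_folds=3)
        res = run_task(prot, met, meta, spec)
        row = res.per_fold.iloc[0]
        # each test fold: 10 RA positives, 5 control negatives
        assert row["tp"] + row["fn"] == 10
        assert row["tn"] + row["fp"] == 5

    def test_paired_selectors_share_folds(self, mini_cohort):
        prot, met, meta, _ = mini_cohort
        folds = stratified_folds(meta, 3, seed=9)
        base = dict(n_grid=(6,), rf_trees=40, cv_seed=9, k_folds=3)
        r1 = run_task(prot, met, meta, TaskSpec(selector="anova_f", **base),
                      folds=folds)
        r2 = run_task(prot, met, meta, TaskSpec(selector="mutual_info", **base),
                      folds=folds)
        assert len(r1.per_fold) == len(r2.per_fold)

    def test_determinism(self, mini_cohort):
        prot, met, meta, _ = mini_cohort
        spec = TaskSpec(selector="anova_f", n_grid=(6,), rf_trees=40,
                        cv_seed=4, k_folds=3)
        a = run_task(prot, met, meta, spec)
        b = run_task(prot, met, meta, spec)
        assert a.per_fold.equals(b.per_fold)
        assert a.fold_model_hashes == b.fold_model_hashes

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            TaskSpec(task="RA_vs_RA")
        with pytest.raises(ValueError):
            TaskSpec(n_grid=(20, 10))


class TestNoLeakage:
    def test_test_fold_values_and_labels_do_not_affect_selection(self, mini_cohort):
        """Perturbing held-out rows (values or labels) must leave the selected
        features and the fitted forests of that fold bit-identical."""
        prot, met, meta, _ = mini_cohort
        folds = stratified_folds(meta, 3, seed=5)
        spec = TaskSpec(task="ACPA_NEG_vs_CTRL", selector="network_rwr",
                        n_grid=(5,), rf_trees=40, cv_seed=5, k_folds=3,
                        enet_kwargs={"n_cv": 5})
        ref = run_task(prot, met, meta, spec, folds=folds)

        test_ids = folds[folds == 0].index
        # corrupt the held-out rows' abundances
        rng = np.random.default_rng(0)
        prot2_vals = prot.values.copy()
        prot2_vals.loc[test_ids] = np.exp(
            rng.normal(7, 1, size=(len(test_ids), prot2_vals.shape[1]))
        )
        prot2 = prot.with_values(prot2_vals)
        met2_vals = met.values.copy()
        met2_vals.loc[test_ids] = rng.lognormal(0, 1, (len(test_ids),
                                                       met2_vals.shape[1]))
        met2 = met.with_values(met2_vals)
        # shuffle the held-out labels too (fold assignment held fixed)
        frame2 = meta.frame.copy()
        frame2.loc[test_ids, "group"] = rng.permutation(
            frame2.loc[test_ids, "group"].to_numpy()
        )
        from omicnet.io import SampleMetadata

        alt = run_task(prot2, met2, SampleMetadata(frame2), spec, folds=folds)
        assert alt.fold_features[0] == ref.fold_features[0]
        assert alt.fold_model_hashes[(0, "5")] == ref.fold_model_hashes[(0, "5")]


def test_permute_labels_preserves_counts(mini_cohort):
    _, _, meta, _ = mini_cohort
    perm = permute_labels(meta, seed=3)
    assert (perm.frame["group"].value_counts().sort_index()
            == meta.frame["group"].value_counts().sort_index()).all()
    assert not perm.frame["group"].equals(meta.frame["group"])
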