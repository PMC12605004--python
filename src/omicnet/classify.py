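"""Leakage-free cross-validated classification of RA phenotypes.

Five stratified folds partition the cohort so every test fold holds the same
number of samples per study group. Inside each fold, feature selection —
elastic-net network inference on the training rows, phenotype-seeded random
walk with restart, top-N cut — as well as random-forest training happen on the
training split only; the held-out rows never enter network inference,
standardization statistics, or ranking. Baseline selectors (none, ANOVA
F-test, mutual information) run on the identical folds so comparisons are
paired. Metrics follow the usual confusion-matrix panel plus rank-based AUC;
reported values are taken at the subnetwork size with the highest mean test
AUC, which is a post-hoc choice (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif, mutual_info_classif

from .diffusion import rwr, top_n_features
from .io import (
    GROUPS,
    OmicsMatrix,
    SampleMetadata,
    SmokingMode,
    encode_design,
    log_transform,
    merge_omics,
)
from .network import infer_network

TASKS = {
    "ACPA_NEG_vs_CTRL": (("ACPA_NEG",), "CONTROL"),
    "ACPA_POS_vs_CTRL": (("ACPA_POS",), "CONTROL"),
    "RA_vs_CTRL": (("ACPA_NEG", "ACPA_POS"), "CONTROL"),
}
MODALITIES = ("multi", "proteomic", "metabolomic")
SELECTORS = ("network_rwr", "none", "anova_f", "mutual_info")


@dataclass(frozen=True)
class TaskSpec:
    task: str = "ACPA_NEG_vs_CTRL"
    modality: str = "multi"
    selector: str = "network_rwr"
    n_grid: tuple = (10, 20, 30, 40, 50, 75, 100, 150, 200, None)  # None = all
    rf_trees: int = 500
    rf_max_features: str | float = "sqrt"
    rf_seed: int = 0
    cv_seed: int = 0
    k_folds: int = 5
    enet_kwargs: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        sizes = [n for n in self.n_grid if n is not None]
        if sizes != sorted(sizes):
            raise ValueError("n_grid must be ascending")


@dataclass
class CVResult:
    """Per-fold metrics, per-fold selections, and the best-N summary."""

    spec: TaskSpec
    per_fold: pd.DataFrame  # rows: fold x N with the metric panel
    fold_features: dict  # fold -> {n_label: tuple of selected feature ids}
    fold_model_hashes: dict  # (fold, n_label) -> joblib hash of the fitted RF
    best_n: object  # N with highest mean AUC (None = all features)

    @property
    def summary(self) -> pd.DataFrame:
        """Mean ± SD of every metric at the best N (NaN-denominator folds are
        excluded from that metric's average, per the NPV/PPV convention)."""
        at_best = self.per_fold[self.per_fold["n"].eq(_n_label(self.best_n))]
        metrics = [c for c in at_best.columns if c not in ("fold", "n")]
        return pd.DataFrame({
            "mean": at_best[metrics].mean(skipna=True),
            "sd": at_best[metrics].std(skipna=True, ddof=1),
        })

    def mean_auc(self, n=None) -> float:
        label = _n_label(self.best_n if n is None else n)
        return float(self.per_fold.loc[self.per_fold["n"].eq(label), "auc"].mean())


def _n_label(n) -> str:
    return "all" if n is None else str(int(n))


def stratified_folds(meta: SampleMetadata, k: int = 5, seed: int = 0) -> pd.Series:
    """Deterministic fold assignment with equal per-group test counts.

    Each group is shuffled and dealt round-robin, so with 40/40/40 and k=5
    every fold's test set is 8+8+8; remainders differ across folds by at most
    one sample per group.
    """
    sizes = meta.frame["group"].value_counts()
    if k > sizes.min():
        raise ValueError(f"k={k} exceeds the smallest group size ({sizes.min()})")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=meta.frame.index, dtype=int)
    for g in GROUPS:
        members = np.array(meta.group_members(g))
        if len(members) == 0:
            continue
        rng.shuffle(members)
        assignment.loc[members] = np.arange(len(members)) % k
    return assignment


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict:
    """Confusion panel at a score threshold plus rank-based AUC.

    AUC is the Mann–Whitney statistic (average ranks give tied scores 0.5
    credit); it is NaN when only one class is present. Ratio metrics with a
    zero denominator are NaN so they drop out of fold averaging.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    pos, neg = int(y.sum()), int((1 - y).sum())
    if pos == 0 or neg == 0:
        auc = np.nan
    else:
        ranks = rankdata(s)
        auc = (ranks[y == 1].sum() - pos * (pos + 1) / 2) / (pos * neg)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else np.nan
    return {
        "auc": float(auc) if not np.isnan(auc) else np.nan,
        "accuracy": (tp + tn) / len(y),
        "sensitivity": sens, "specificity": spec,
        "ppv": ppv, "npv": npv, "f1": f1, "mcc": mcc,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def prepare_features(
    prot: OmicsMatrix | None,
    met: OmicsMatrix | None,
    modality: str,
    log_proteins: bool = True,
) -> OmicsMatrix:
    """Assemble the modality's feature block (proteins natural-logged)."""
    if modality == "proteomic":
        return log_transform(prot) if log_proteins else prot
    if modality == "metabolomic":
        return met
    return merge_omics(log_transform(prot) if log_proteins else prot, met)


def _rank_features_network(
    data: OmicsMatrix, meta: SampleMetadata, train_ids, spec: TaskSpec, fold: int
) -> list[str]:
    train_meta = meta.subset(train_ids)
    design = encode_design(
        train_meta,
        include={"sex", "age", "bmi", "smoking", "meds", "phenotype"},
        smoking_mode=SmokingMode.UNKNOWN_LEVEL,
    )
    design = design.loc[:, design.nunique() > 1]  # drop constant indicators
    train_block = OmicsMatrix(data.values.loc[list(train_ids)], data.feature_info)
    net = infer_network(
        train_block, design, seed=spec.cv_seed + fold, **spec.enet_kwargs
    )
    seeds = [n for n in net.nodes if n.startswith("group_")]
    ranking = rwr(net, seeds)
    sub = top_n_features(net, ranking, len(data.feature_ids))
    return sub.nodes  # all feature nodes, relevance-ordered


def _rank_features_filter(
    data: OmicsMatrix, y: np.ndarray, train_rows: pd.Index, selector: str, seed: int
) -> list[str]:
    X = data.values.loc[train_rows].to_numpy(dtype=float)
    if selector == "anova_f":
        score, _ = f_classif(X, y)
    else:
        score = mutual_info_classif(X, y, random_state=seed)
    score = np.nan_to_num(score, nan=-np.inf)
    order = np.lexsort((np.array(data.feature_ids), -score))
    return [data.feature_ids[i] for i in order]


def run_task(
    prot: OmicsMatrix | None,
    met: OmicsMatrix | None,
    meta: SampleMetadata,
    spec: TaskSpec,
    log_proteins: bool = True,
    folds: pd.Series | None = None,
) -> CVResult:
    """Run one classification task through the full per-fold pipeline.

    Network inference and RWR ranking use all training-fold samples (their
    one-hot phenotype labels included); the classifier is then trained on the
    task's training rows and scored on the task's held-out rows, positives
    being the RA (sub)group(s). A precomputed ``folds`` assignment may be
    passed to pair runs (selector comparisons, permutation controls).
    """
    data = prepare_features(prot, met, spec.modality, log_proteins)
    if data.n_missing:
        raise ValueError("impute missing values before classification")
    pos_groups, neg_group = TASKS[spec.task]
    if folds is None:
        folds = stratified_folds(meta, spec.k_folds, spec.cv_seed)

    n_grid = list(spec.n_grid)
    if spec.selector == "none":
        if len(n_grid) > 1 or n_grid[0] is not None:
            import warnings

            warnings.warn("selector 'none' ignores n_grid; using all features")
        n_grid = [None]

    rows, fold_features, fold_hashes = [], {}, {}
    for fold in range(spec.k_folds):
        test_ids = folds.index[folds == fold]
        train_ids = folds.index[folds != fold]
        task_groups = set(pos_groups) | {neg_group}
        in_task = meta.frame["group"].isin(task_groups)
        train_rows = train_ids[in_task.loc[train_ids]]
        test_rows = test_ids[in_task.loc[test_ids]]
        y_train = meta.frame.loc[train_rows, "group"].isin(pos_groups).to_numpy(int)
        y_test = meta.frame.loc[test_rows, "group"].isin(pos_groups).to_numpy(int)

        if spec.selector == "network_rwr":
            order = _rank_features_network(data, meta, train_ids, spec, fold)
        elif spec.selector == "none":
            order = list(data.feature_ids)
        else:
            order = _rank_features_filter(
                data, y_train, train_rows, spec.selector, spec.cv_seed + fold
            )

        fold_features[fold] = {}
        for n in n_grid:
            feats = order if n is None else order[: min(n, len(order))]
            label = _n_label(n)
            fold_features[fold][label] = tuple(feats)
            rf = RandomForestClassifier(
                n_estimators=spec.rf_trees,
                max_features=spec.rf_max_features,
                random_state=spec.rf_seed + fold,
            )
            rf.fit(data.values.loc[train_rows, feats].to_numpy(), y_train)
            fold_hashes[(fold, label)] = joblib.hash(rf)
            prob = rf.predict_proba(data.values.loc[test_rows, feats].to_numpy())
            scores = prob[:, list(rf.classes_).index(1)]
            rows.append({"fold": fold, "n": label,
                         **compute_metrics(y_test, scores)})

    per_fold = pd.DataFrame(rows)
    mean_auc = per_fold.groupby("n")["auc"].mean()
    # highest mean AUC; ties go to the smaller subnetwork
    best_label = min(
        mean_auc.index,
        key=lambda lb: (-mean_auc[lb], np.inf if lb == "all" else int(lb)),
    )
    best_n = None if best_label == "all" else int(best_label)
    return CVResult(spec, per_fold, fold_features, fold_hashes, best_n)


def permute_labels(meta: SampleMetadata, seed: int) -> SampleMetadata:
    """Shuffle group labels across samples (permutation-null control)."""
    rng = np.random.default_rng(seed)
    frame = meta.frame.copy()
    frame["group"] = rng.permutation(frame["group"].to_numpy())
    return SampleMetadata(frame)
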