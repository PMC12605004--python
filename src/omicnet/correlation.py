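"""Subgroup-stratified Spearman correlation with clinical markers.

Features are correlated with ESR, CRP or DAS28-CRP separately inside each RA
subgroup, on pairwise-complete observations with average ranks for ties and a
two-sided t-approximation p-value. A concordance classifier compares one
feature's correlation across the two subgroups (concordant / subgroup-specific
/ opposite), which is the logic behind subgroup-specific correlation claims.
Group-mean Z-scores summarize each feature's mean abundance profile across the
three study groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, OmicsMatrix, SampleMetadata

RA_SUBGROUPS = ("ACPA_NEG", "ACPA_POS")
MARKER_NAMES = {"ESR": "esr", "CRP": "crp", "DAS28CRP": "das28crp"}


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p-value for Spearman rho (n < 10 only).

    Enumerates all rank permutations; p is the fraction with |rho| at least
    the observed value. Useful where the t approximation is unreliable.
    """
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n >= 10:
        raise ValueError("exact permutation p is supported for n < 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()

    def rho_of(r):
        r = np.asarray(r, dtype=float)
        rc = r - r.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (rc ** 2).sum())
        return np.dot(rx_c, rc) / denom if denom > 0 else np.nan

    obs = abs(rho_of(ry))
    if np.isnan(obs):
        return np.nan
    count = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(rho_of(perm)) >= obs - 1e-12:
            count += 1
    return count / total


def spearman_by_subgroup(
    data: OmicsMatrix,
    meta: SampleMetadata,
    marker: str,
    subgroups=RA_SUBGROUPS,
    min_pairs: int = 4,
    p_method: str = "asymptotic",
) -> pd.DataFrame:
    """Spearman rho of every feature with one clinical marker, per subgroup.

    Rows with a missing marker value are dropped (pairwise-complete); constant
    features or a constant marker yield an undefined rho flagged in the
    ``degenerate`` column rather than an exception. ``p_method="exact"``
    switches to the permutation p-value, available only below 10 pairs.
    """
    if p_method not in ("asymptotic", "exact"):
        raise ValueError("p_method must be 'asymptotic' or 'exact'")
    if marker not in MARKER_NAMES:
        raise ValueError(f"marker must be one of {sorted(MARKER_NAMES)}")
    col = MARKER_NAMES[marker]
    out = []
    for sg in subgroups:
        members = meta.frame[meta.frame["group"] == sg]
        m = members[col].astype(float)
        keep = m.notna()
        n = int(keep.sum())
        if n < min_pairs:
            raise ValueError(
                f"marker {marker} present for only {n} samples in {sg} "
                f"(need >= {min_pairs})"
            )
        mv = m[keep].to_numpy()
        fv = data.values.loc[m.index[keep]].to_numpy(dtype=float)
        marker_const = np.ptp(mv) == 0
        rm = _rank(mv.reshape(-1, 1))[:, 0]
        rf = _rank(fv)
        rm_c = rm - rm.mean()
        rf_c = rf - rf.mean(axis=0)
        denom = np.sqrt((rm_c ** 2).sum() * (rf_c ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rf_c * rm_c[:, None]).sum(axis=0) / denom
        feat_const = np.ptp(fv, axis=0) == 0
        degenerate = feat_const | marker_const
        rho = np.where(degenerate, np.nan, rho)
        if p_method == "exact":
            if n >= 10:
                raise ValueError("exact permutation p requires fewer than 10 pairs")
            p = np.array([
                spearman_exact_p(fv[:, j], mv) if not degenerate[j] else np.nan
                for j in range(fv.shape[1])
            ])
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * stats.t.sf(np.abs(t), n - 2)
            p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
        out.append(pd.DataFrame({
            "feature_id": data.feature_ids,
            "marker": marker,
            "subgroup": sg,
            "rho": rho,
            "p": np.where(degenerate, np.nan, p),
            "n_pairs": n,
            "degenerate": degenerate,
        }))
    return pd.concat(out, ignore_index=True)


CONCORDANCE_CATEGORIES = (
    "concordant_pos", "concordant_neg",
    "A_specific_pos", "A_specific_neg",
    "B_specific_pos", "B_specific_neg",
    "opposite", "none",
)


def classify_concordance(
    resA: pd.Series, resB: pd.Series, rho_thr: float = 0.4, alpha: float = 0.05
) -> str:
    """Compare one feature-marker correlation across two subgroups.

    A subgroup "passes" when |rho| > rho_thr and p < alpha. Both pass with the
    same sign: concordant; both significant with opposite signs: opposite; one
    passes while the other is non-significant (p >= alpha): subgroup-specific.
    """
    if resA["feature_id"] != resB["feature_id"] or resA["marker"] != resB["marker"]:
        raise ValueError("concordance requires the same feature and marker")
    rA, pA = float(resA["rho"]), float(resA["p"])
    rB, pB = float(resB["rho"]), float(resB["p"])
    if np.isnan(rA) or np.isnan(rB):
        return "none"
    passA = abs(rA) > rho_thr and pA < alpha
    passB = abs(rB) > rho_thr and pB < alpha
    sigA, sigB = pA < alpha, pB < alpha
    if sigA and sigB and np.sign(rA) != np.sign(rB) and (passA or passB):
        return "opposite"
    if passA and passB and np.sign(rA) == np.sign(rB):
        return "concordant_pos" if rA > 0 else "concordant_neg"
    if passA and not sigB:
        return "A_specific_pos" if rA > 0 else "A_specific_neg"
    if passB and not sigA:
        return "B_specific_pos" if rB > 0 else "B_specific_neg"
    return "none"


def concordance_table(
    corr: pd.DataFrame, subgroup_a: str = "ACPA_NEG", subgroup_b: str = "ACPA_POS",
    rho_thr: float = 0.4, alpha: float = 0.05,
) -> pd.DataFrame:
    """Wide per-feature table pairing rho across two subgroups + category."""
    a = corr[corr["subgroup"] == subgroup_a].set_index("feature_id", drop=False)
    b = corr[corr["subgroup"] == subgroup_b].set_index("feature_id", drop=False)
    rows = []
    for fid in a.index:
        ra, rb = a.loc[fid], b.loc[fid]
        rows.append({
            "feature_id": fid,
            "marker": ra["marker"],
            "rho_A": ra["rho"], "p_A": ra["p"],
            "rho_B": rb["rho"], "p_B": rb["p"],
            "category": classify_concordance(ra, rb, rho_thr, alpha),
        })
    return pd.DataFrame(rows)


def group_mean_zscores(data: OmicsMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Z-score of each feature's group means across the study groups.

    For each feature the three group means are standardized to mean 0, SD 1
    (sample SD across the group axis). Features whose group means are all
    equal get zeros and are flagged via the ``degenerate`` column.
    """
    groups = [g for g in GROUPS if (meta.frame["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    means = pd.DataFrame(
        {g: data.values.loc[meta.group_members(g)].mean(axis=0) for g in groups}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    degenerate = sd == 0
    z = (means.sub(mu, axis=0)).div(sd.where(~degenerate, 1.0), axis=0)
    z.loc[degenerate, :] = 0.0
    z["degenerate"] = degenerate
    z.index.name = "feature_id"
    return z
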