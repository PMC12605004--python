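"""Cohort characteristics table with exact categorical tests.

Categorical variables are compared across study groups with Fisher's exact
test (the Freeman–Halton enumeration generalizes it beyond 2×2); continuous
variables use the Kruskal–Wallis rank test. Continuous summaries report
mean ± SD, [Q1, Q3] under the linear-interpolation (type-7) quantile
convention, and min–max; Unknown smoking history is reported as its own row
but excluded from the test.
"""

from __future__ import annotations

from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MED_FLAGS, SampleMetadata

_REL_TOL = 1e-7  # observed-probability comparison tolerance (float safety)


def _log_table_prob(table: np.ndarray, row_sums, col_sums, total) -> float:
    lp = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    lp -= lgamma(total + 1)
    lp -= sum(lgamma(x + 1) for x in table.ravel())
    return lp


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)

    def fill(i: int, j: int, row_left, col_left):
        if i == r - 1:
            # last row forced by column margins
            if all(cl >= 0 for cl in col_left):
                table[r - 1] = col_left
                yield table
            return
        if j == c - 1:
            v = row_left[i]
            if 0 <= v <= col_left[j]:
                table[i, j] = v
                new_col = list(col_left)
                new_col[j] -= v
                new_row = list(row_left)
                new_row[i] = 0
                yield from fill(i + 1, 0, new_row, new_col)
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            table[i, j] = v
            new_col = list(col_left)
            new_col[j] -= v
            new_row = list(row_left)
            new_row[i] -= v
            yield from fill(i, j + 1, new_row, new_col)

    yield from fill(0, 0, list(row_sums), list(col_sums))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r×c contingency table.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed table's (the common
    "exact" two-sided convention). For r=c=2 this reduces to the classical
    test; larger tables use the Freeman–Halton generalization by full
    enumeration.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(t.sum())
    if total == 0:
        raise ValueError("empty table")
    if total > 10_000:
        raise ValueError(
            "table total exceeds the enumeration bound (10,000); "
            "use a Monte-Carlo test instead"
        )
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return 1.0
    lp_obs = _log_table_prob(t, row_sums, col_sums, total)
    cutoff = lp_obs + np.log1p(_REL_TOL)
    p = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(cand, row_sums, col_sums, total)
        if lp <= cutoff:
            p += np.exp(lp)
    return float(min(p, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, bool]:
    """Kruskal–Wallis H with tie correction; chi-square p on k-1 df.

    Returns (H, p, degenerate). All values identical across all groups is a
    degenerate case reported as H=0, p=1 with the flag set.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, True
    h, p = stats.kruskal(*groups)
    return float(h), float(p), False


_CONTINUOUS = ("age", "bmi", "esr", "crp", "das28crp")


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    # type-7 linear interpolation (numpy default)
    return float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75))


def _continuous_row(meta: SampleMetadata, var: str, groups: list[str]) -> dict:
    cells, test_groups = {}, []
    for g in groups:
        vals = meta.frame.loc[meta.frame["group"] == g, var].astype(float)
        known = vals.dropna().to_numpy()
        if len(known) == 0:
            cells[g] = "N/A"
            continue
        q1, q3 = _quartiles(known)
        cells[g] = (
            f"{known.mean():.1f} ± {known.std(ddof=1):.1f} "
            f"[{q1:.1f}, {q3:.1f}] {known.min():.1f}–{known.max():.1f} "
            f"(unknown: {int(vals.isna().sum())})"
        )
        if len(known) >= 2:
            test_groups.append(known)
    p = kruskal_wallis(test_groups)[1] if len(test_groups) >= 2 else np.nan
    return {"variable": var, **cells, "p": p, "test": "kruskal_wallis"}


def _categorical_row(
    meta: SampleMetadata, var: str, groups: list[str], exclude_levels=("UNKNOWN",)
) -> dict:
    f = meta.frame
    counts = pd.crosstab(f[var].astype(str), f["group"]).reindex(columns=groups,
                                                                 fill_value=0)
    cells = {
        g: "; ".join(
            f"{lev}: {counts.loc[lev, g]} "
            f"({100 * counts.loc[lev, g] / counts[g].sum():.0f}%)"
            for lev in counts.index
        )
        for g in groups
    }
    tested = counts.drop(index=[l for l in exclude_levels if l in counts.index])
    tested = tested.loc[tested.sum(axis=1) > 0, tested.sum(axis=0) > 0]
    if tested.shape[0] >= 2 and tested.shape[1] >= 2:
        p = fisher_exact(tested.to_numpy().T)
    else:
        p = np.nan
    return {"variable": var, **cells, "p": p, "test": "fisher_exact"}


def cohort_table(meta: SampleMetadata) -> pd.DataFrame:
    """Per-variable group summaries with the appropriate exact test."""
    groups = [g for g in ("ACPA_NEG", "ACPA_POS", "CONTROL")
              if (meta.frame["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = [_categorical_row(meta, "sex", groups)]
    rows.append(_continuous_row(meta, "age", groups))
    rows.append(_continuous_row(meta, "bmi", groups))
    rows.append(_categorical_row(meta, "smoking", groups))
    for var in ("esr", "crp", "das28crp"):
        rows.append(_continuous_row(meta, var, groups))
    f = meta.frame
    for flag in MED_FLAGS:
        ra = f[f["group"] != "CONTROL"]
        tab = pd.crosstab(ra[flag], ra["group"])
        cells = {
            g: f"{int(f.loc[f['group'] == g, flag].sum())} "
               f"({100 * f.loc[f['group'] == g, flag].mean():.0f}%)"
            for g in groups
        }
        if tab.shape == (2, 2):
            p = fisher_exact(tab.to_numpy().T)
        else:
            p = np.nan
        rows.append({"variable": flag, **cells, "p": p, "test": "fisher_exact"})
    return pd.DataFrame(rows)


def to_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown(index=False)
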