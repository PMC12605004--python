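"""One-tailed Fisher-exact (hypergeometric) set enrichment.

Tests whether a hit set over-represents each annotation term relative to a
declared feature universe. Two tail conventions are supported: the standard
one-tailed Fisher P(X >= k), and the conservative EASE-style variant
P(X >= k-1) used by DAVID, which discounts single-feature support. Both
p-values are always reported; ``mode`` picks which one drives the enriched
call. No multiple-testing correction gates the call (a BH column is emitted
for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .differential import _bh_qvalues


@dataclass(frozen=True)
class AnnotationCollection:
    """term_id -> member feature set, with optional term metadata."""

    terms: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)
    levels: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationCollection":
        terms: dict[str, set[str]] = {}
        for term, feature in pairs:
            terms.setdefault(str(term), set()).add(str(feature))
        return cls({t: frozenset(m) for t, m in terms.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationCollection":
        """Two-column TSV: term_id <tab> feature_id."""
        f = pd.read_csv(path, sep="\t", header=None, names=["term", "feature"],
                        dtype=str, comment="#")
        return cls.from_pairs(f.itertuples(index=False))

    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationCollection":
        terms, names = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            term, desc, *members = line.rstrip("\n").split("\t")
            terms[term] = frozenset(members)
            names[term] = desc
        return cls(terms, names)

    def restricted_to(self, universe: frozenset[str] | set[str]) -> "AnnotationCollection":
        """Intersect every term with the universe; drop emptied terms."""
        kept = {t: frozenset(m & set(universe)) for t, m in self.terms.items()}
        kept = {t: m for t, m in kept.items() if m}
        return AnnotationCollection(kept, self.names, self.levels)


def fisher_enrichment(
    hits: Iterable[str],
    universe: Iterable[str],
    ann: AnnotationCollection,
    mode: str = "standard",
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each annotation term.

    standard: p = P(X >= k); ease: p = P(X >= max(k-1, 0)), with
    X ~ Hypergeom(N=|universe|, K=|term|, n=|hits|). A term is enriched when
    the selected p-value is below ``alpha`` and the overlap k >= min_overlap.
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"mode must be standard or ease, got {mode!r}")
    hits = frozenset(map(str, hits))
    universe = frozenset(map(str, universe))
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)}")
    ann = ann.restricted_to(universe)
    N, n = len(universe), len(hits)
    rows = []
    for term in sorted(ann.terms):
        members = ann.terms[term]
        K = len(members)
        k = len(members & hits)
        p_std = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        p_ease = float(hypergeom.sf(max(k - 1, 0) - 1, N, K, n))
        rows.append({
            "term_id": term,
            "name": ann.names.get(term, term),
            "k": k, "K": K, "n": n, "N": N,
            "p_standard": min(p_std, 1.0),
            "p_ease": min(p_ease, 1.0),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    sel = out["p_standard"] if mode == "standard" else out["p_ease"]
    out["p"] = sel
    out["q"] = _bh_qvalues(sel.to_numpy())
    out["enriched"] = (sel < alpha) & (out["k"] >= min_overlap)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
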