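"""Random walk with restart over the multi-omic network.

The walker iterates p_{t+1} = (1-r) A' p_t + r p0 on the column-normalized
binary adjacency A' (every undirected edge walked both ways), restarting with
probability r at the seed distribution p0 — here uniform over the one-hot
phenotype nodes. Iteration stops when the L1 change falls below a tolerance;
the stationary vector assigns each node a relevance score (steady-state visit
probability) measuring proximity to the phenotype. Mass that reaches a
zero-degree (dangling) column is redirected to the seed distribution, which
keeps the scores a probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MultiOmicNetwork

FEATURE_KINDS = frozenset({"protein", "metabolite"})


def column_normalize(
    network: MultiOmicNetwork,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Column-stochastic transition matrix of the unweighted graph.

    Returns (A', node order, dangling mask). Columns of zero-degree nodes are
    all-zero and flagged dangling; callers decide where their mass goes.
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("empty graph")
    import networkx as nx

    A = nx.to_numpy_array(network.graph, nodelist=nodes, weight=None)
    deg = A.sum(axis=0)
    dangling = deg == 0
    cols = np.where(dangling, 1.0, deg)
    return A / cols, nodes, dangling


@dataclass
class RelevanceRanking:
    """Node relevance scores from RWR, with convergence diagnostics."""

    scores: pd.Series  # node -> steady-state probability, descending
    seeds: tuple[str, ...]
    restart: float
    iterations: int
    residual: float

    def top(self, n: int) -> pd.Series:
        return self.scores.head(n)


def rwr(
    network: MultiOmicNetwork,
    seeds,
    r: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> RelevanceRanking:
    """Random walk with restart from ``seeds`` (uniform initial mass).

    Stops when the L1 difference between successive probability vectors drops
    below ``tol``; raises if that never happens within ``max_iter`` steps.
    """
    seeds = tuple(sorted(set(seeds)))
    if not seeds:
        raise ValueError("empty seed set")
    if not 0 < r <= 1:
        raise ValueError(f"restart rate must be in (0, 1], got {r}")
    A, nodes, dangling = column_normalize(network)
    index = {n: i for i, n in enumerate(nodes)}
    missing = [s for s in seeds if s not in index]
    if missing:
        raise ValueError(f"seed nodes not in graph: {missing}")

    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
    p = p0.copy()
    for it in range(1, max_iter + 1):
        lost = p[dangling].sum()  # mass on dangling nodes restarts
        p_next = (1 - r) * (A @ p + lost * p0) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            scores = pd.Series(p, index=nodes).sort_values(
                ascending=False, kind="stable"
            )
            # deterministic tie order: by node id within equal scores
            scores = scores.iloc[
                np.lexsort((np.array(scores.index), -scores.to_numpy()))
            ]
            return RelevanceRanking(scores, seeds, r, it, residual)
    raise RuntimeError(
        f"RWR did not converge in {max_iter} iterations (residual {residual:.3g})"
    )


def rwr_closed_form(network: MultiOmicNetwork, seeds, r: float = 0.5) -> pd.Series:
    """Direct linear solve p = r (I - (1-r)A')^-1 p0 (no dangling handling).

    Reference route for graphs without zero-degree nodes.
    """
    A, nodes, dangling = column_normalize(network)
    if dangling.any():
        bad = [n for n, d in zip(nodes, dangling) if d]
        raise ValueError(f"closed form requires no dangling nodes: {bad}")
    index = {n: i for i, n in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in set(seeds)]] = 1.0 / len(set(seeds))
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * A, p0)
    return pd.Series(p, index=nodes)


@dataclass
class Subnetwork:
    """Top-N feature nodes by relevance plus their induced parent edges."""

    nodes: list[str]
    scores: pd.Series
    graph: "object"  # networkx subgraph view copy

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def top_n_features(
    network: MultiOmicNetwork,
    ranking: RelevanceRanking,
    n: int,
    include_kinds=FEATURE_KINDS,
) -> Subnetwork:
    """Top-N biomolecule nodes by relevance score, with induced subgraph.

    Phenotype and covariate nodes are removed before the cut. Ties are broken
    lexicographically by node ID. Requesting more nodes than available returns
    all of them with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [
        node for node in ranking.scores.index
        if network.node_kind(node) in include_kinds
    ]
    if n > len(eligible):
        import warnings

        warnings.warn(
            f"requested top {n} but only {len(eligible)} feature nodes exist"
        )
        n = len(eligible)
    chosen = eligible[:n]
    sub = network.graph.subgraph(chosen).copy()
    return Subnetwork(chosen, ranking.scores.loc[chosen], sub)
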