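"""Immune-parameter rank-correlation network with nesting-aware pruning.

Flow-cytometry gating makes some parameter pairs arithmetically
dependent (e.g. CD4% and CD8% of the same parent gate); for each
declared complementary pair only the first-listed member enters the
analysis.  Pairwise Spearman correlations over the pooled longitudinal
samples become network edges when |rho| >= 0.3 and p < 0.008; parameters
with no passing edge drop out of the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import spearman_rho_p

__all__ = [
    "CorrelationResult",
    "prune_nested",
    "pooled_spearman",
    "all_pairwise_correlations",
    "build_network",
]

RHO_THRESHOLD = 0.3
P_THRESHOLD = 0.008


@dataclass(frozen=True)
class CorrelationResult:
    parameter_a: str
    parameter_b: str
    rho: float
    p: float
    n: int

    def passes(
        self, rho_threshold: float = RHO_THRESHOLD, p_threshold: float = P_THRESHOLD
    ) -> bool:
        return (
            np.isfinite(self.rho)
            and abs(self.rho) >= rho_threshold
            and self.p < p_threshold
        )


def prune_nested(
    parameters,
    nested_pairs,
) -> list[str]:
    """Drop the second member of each declared gating-dependent pair.

    ``nested_pairs`` is an iterable of (kept, dropped) parameter pairs —
    e.g. (CD4% of alpha-beta T, CD8% of alpha-beta T) keeps CD4.  The
    relation must be acyclic: a parameter that is dropped in one pair
    cannot be the keeper of another that in turn drops the first keeper.
    Deterministic: output preserves the input parameter order.
    """
    parameters = list(parameters)
    keep_of: dict[str, str] = {}
    for kept, dropped in nested_pairs:
        if kept == dropped:
            raise ValueError(f"parameter {kept!r} declared nested with itself")
        keep_of[dropped] = kept
    # cycle check on the dropped -> kept mapping
    for start in keep_of:
        seen = {start}
        node = keep_of[start]
        while node in keep_of:
            node = keep_of[node]
            if node in seen:
                raise ValueError("cycle in nesting map")
            seen.add(node)
    dropped_set = set(keep_of)
    return [p for p in parameters if p not in dropped_set]


def pooled_spearman(x, y, parameter_a: str = "x", parameter_b: str = "y") -> CorrelationResult:
    """Spearman rho over pooled samples, mid-rank ties, pairwise-complete.

    Exact permutation p at n <= 10, t approximation above.  A constant
    vector gives a missing (NaN) result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least five complete pairs")
    rho, p = spearman_rho_p(x, y)
    a, b = sorted([parameter_a, parameter_b])
    if a != parameter_a:
        # stored undirected with lexical order; rho is symmetric
        parameter_a, parameter_b = a, b
    return CorrelationResult(parameter_a, parameter_b, rho, p, len(x))


def all_pairwise_correlations(
    data: pd.DataFrame, parameters=None
) -> list[CorrelationResult]:
    """Pooled Spearman for every unordered parameter pair."""
    params = list(parameters) if parameters is not None else list(data.columns)
    out = []
    for a, b in combinations(params, 2):
        out.append(pooled_spearman(data[a], data[b], a, b))
    return out


def build_network(
    edges: list[CorrelationResult],
    rho_threshold: float = RHO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    lineage: dict[str, str] | None = None,
) -> nx.Graph:
    """Graph of passing correlations.

    Nodes are parameters with at least one edge at |rho| >= rho_threshold
    and p < p_threshold (isolated parameters are lost from the network);
    node degree is the number of retained relationships; an optional
    lineage mapping is carried as a node attribute.
    """
    g = nx.Graph()
    for e in edges:
        if e.passes(rho_threshold, p_threshold):
            g.add_edge(e.parameter_a, e.parameter_b, rho=e.rho, p=e.p, n=e.n)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
        if lineage:
            g.nodes[node]["lineage"] = lineage.get(node, "")
    return g


def edges_table(edges: list[CorrelationResult],
                rho_threshold: float = RHO_THRESHOLD,
                p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter_a": [e.parameter_a for e in edges],
            "parameter_b": [e.parameter_b for e in edges],
            "rho": [e.rho for e in edges],
            "p": [e.p for e in edges],
            "n": [e.n for e in edges],
            "passes": [e.passes(rho_threshold, p_threshold) for e in edges],
        }
    )
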