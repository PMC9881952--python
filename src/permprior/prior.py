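"""The edge prior: probability of edge existence due to node degree.

The edge prior for a node pair is the fraction of degree-preserving
permutations of the network in which that pair is connected — the
binomial maximum-likelihood estimate of an edge-existence probability
that, by construction, carries no information about the network's true
edges beyond its degree sequence.

Degree-grouping is always applied: in a degree-preserving permutation,
the indicator of an edge between a pair with source degree u and target
degree v has the same distribution for every pair with degrees (u, v),
so all such pairs are pooled. This multiplies the effective number of
permutations per pair by the size of its degree group and makes the
estimate exactly constant within groups.

Two comparator predictors are provided: a closed-form analytical
approximation of the prior, and the degree product u·v scaled into
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netcore import Network, degrees
from .permute import SwapParams, permutation_ensemble

__all__ = [
    "PriorTable",
    "candidate_pairs",
    "edge_prior",
    "approximate_prior",
    "approximate_prior_table",
    "scaled_degree_product",
]


@dataclass(frozen=True)
class PriorTable:
    """Per-pair edge probabilities over the full candidate pair universe.

    ``table`` has columns (source, target, u, v, prior); ``kind`` is one
    of "permutation", "approximation", "scaled_degree_product".
    """

    table: pd.DataFrame
    kind: str
    m: int
    n_permutations: int | None = None

    def scores(self) -> np.ndarray:
        return self.table["prior"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def candidate_pairs(network: Network) -> tuple[np.ndarray, np.ndarray]:
    """All node pairs that could carry an edge in this network kind.

    bipartite: all source × target pairs; directed: all ordered pairs
    with i ≠ j (plus loops (i, i) when allowed); undirected: unordered
    pairs i < j (plus loops when allowed). This matches exactly the set
    of edges a degree-preserving permutation can produce.
    """
    if network.bipartite:
        I, J = np.meshgrid(
            np.arange(network.n_source), np.arange(network.n_target), indexing="ij"
        )
        return I.ravel(), J.ravel()
    n = network.n_source
    if network.directed:
        I, J = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        I, J = I.ravel(), J.ravel()
        if not network.allow_loops:
            keep = I != J
            I, J = I[keep], J[keep]
        return I, J
    k = 0 if network.allow_loops else 1
    I, J = np.triu_indices(n, k=k)
    return I.astype(np.int64), J.astype(np.int64)


def _degree_keys(
    network: Network, I: np.ndarray, J: np.ndarray, deg
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode each pair's (u, v) degree pair as a scalar grouping key.

    For undirected networks the pair is unordered, so (u, v) is sorted.
    Returns (keys, u, v) with u, v the per-pair degrees as reported.
    """
    u = deg.source_degree[I]
    v = deg.target_degree[J]
    if network.directed or network.bipartite:
        lo, hi = u, v
    else:
        lo = np.minimum(u, v)
        hi = np.maximum(u, v)
    base = int(max(deg.source_degree.max(initial=0), deg.target_degree.max(initial=0))) + 1
    return lo * base + hi, u, v


def edge_prior(
    network: Network,
    n_permutations: int = 100,
    params: SwapParams | None = None,
) -> PriorTable:
    """Permutation-estimated, degree-grouped edge prior for every pair.

    For each degree pair (u, v), the prior is the total number of edges
    observed among candidate pairs with those degrees, summed over all
    permuted networks, divided by (group size × n_permutations). Every
    candidate pair receives its degree group's value, so the estimate is
    exactly constant within groups and the priors sum to m over the
    whole universe.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    params = params or SwapParams()
    deg = degrees(network)
    I, J = candidate_pairs(network)
    keys, u, v = _degree_keys(network, I, J, deg)
    n_keys = int(keys.max(initial=0)) + 1
    sizes = np.bincount(keys, minlength=n_keys)

    counts = np.zeros(n_keys)
    for permuted, _ in permutation_ensemble(network, n_permutations, params):
        arr = permuted.edge_array()
        ekeys, _, _ = _degree_keys(network, arr[:, 0], arr[:, 1], deg)
        counts += np.bincount(ekeys, minlength=n_keys)

    with np.errstate(invalid="ignore", divide="ignore"):
        group_prior = np.where(sizes > 0, counts / (sizes * n_permutations), 0.0)
    table = pd.DataFrame(
        {"source": I, "target": J, "u": u, "v": v, "prior": group_prior[keys]}
    )
    return PriorTable(table, "permutation", network.m, n_permutations)


def approximate_prior(u, v, m):
    """Closed-form approximation of the edge prior for degrees (u, v).

    P = u·v / sqrt((u·v)^2 + (m − u − v + 1)^2), where m is the total
    edge count. Always in [0, 1]; equals 0 when u·v = 0; tends to u·v/m
    when u·v ≪ m and to 1 as u·v grows. The approximation is accurate
    for sparse networks (many nodes, fewer edges) and degrades on tiny
    dense graphs, where edge occupancies are strongly dependent.
    Accepts scalars or arrays.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(u_arr < 0) or np.any(v_arr < 0):
        raise ValueError("degrees must be nonnegative")
    uv = u_arr * v_arr
    rest = m - u_arr - v_arr + 1.0
    denom = np.sqrt(uv**2 + rest**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(uv == 0, 0.0, uv / np.where(denom == 0, 1.0, denom))
    if np.isscalar(u) and np.isscalar(v):
        return float(p)
    return p


def approximate_prior_table(network: Network) -> PriorTable:
    """Analytical approximation evaluated over the full pair universe."""
    deg = degrees(network)
    I, J = candidate_pairs(network)
    _, u, v = _degree_keys(network, I, J, deg)
    p = approximate_prior(u, v, max(network.m, 1))
    table = pd.DataFrame({"source": I, "target": J, "u": u, "v": v, "prior": p})
    return PriorTable(table, "approximation", network.m)


def scaled_degree_product(network: Network) -> PriorTable:
    """Degree product u·v scaled into [0, 1] by its maximum over all pairs."""
    if network.m < 1:
        raise ValueError("network must have at least one edge")
    deg = degrees(network)
    I, J = candidate_pairs(network)
    _, u, v = _degree_keys(network, I, J, deg)
    uv = (u * v).astype(float)
    top = uv.max(initial=0.0)
    if top == 0:
        raise ValueError("all candidate pairs have zero degree product")
    table = pd.DataFrame(
        {"source": I, "target": J, "u": u, "v": v, "prior": uv / top}
    )
    return PriorTable(table, "scaled_degree_product", network.m)
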