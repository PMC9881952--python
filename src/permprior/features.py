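"""Classical edge-prediction features on undirected unipartite networks.

Five features spanning the spectrum from purely degree-based to
neighborhood- and propagation-based:

* preferential attachment — product of endpoint degrees (a pure function
  of degree, so it is invariant under degree-preserving permutation);
* Jaccard coefficient — |N(i) ∩ N(j)| / |N(i) ∪ N(j)|;
* Adamic/Adar — Σ over common neighbors w of 1 / ln(deg w);
* resource allocation — Σ over common neighbors w of 1 / deg w;
* random walk with restart (RWR) — stationary visiting probability of a
  restarting random walk, symmetrized over the two endpoints.

All features return a tidy DataFrame with one row per requested
(pair, feature), in pair order, columns (source, target, feature, score).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .netcore import Network, degrees

__all__ = [
    "UnsupportedStructureError",
    "ConvergenceError",
    "preferential_attachment",
    "neighborhood_indices",
    "random_walk_with_restart",
    "compute_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "preferential_attachment",
    "jaccard",
    "adamic_adar",
    "resource_allocation",
    "rwr",
)


class UnsupportedStructureError(ValueError):
    """Raised when a feature is requested on a network kind it is not defined for."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver fails to reach tolerance."""


def _check_undirected(network: Network) -> None:
    if network.directed or network.bipartite:
        raise UnsupportedStructureError(
            "edge-prediction features are defined for undirected unipartite "
            "networks only"
        )


def _as_pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (source, target) pairs")
    return arr[:, 0], arr[:, 1]


def _neighbor_sets(network: Network) -> list[set]:
    nbrs: list[set] = [set() for _ in range(network.n_source)]
    for i, j in network.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    return nbrs


def preferential_attachment(network: Network, pairs) -> pd.DataFrame:
    """Product of the two endpoint degrees for each pair."""
    _check_undirected(network)
    I, J = _as_pair_arrays(pairs)
    deg = degrees(network).source_degree
    score = (deg[I] * deg[J]).astype(float)
    return pd.DataFrame(
        {"source": I, "target": J, "feature": "preferential_attachment", "score": score}
    )


def neighborhood_indices(
    network: Network,
    pairs,
    which=("jaccard", "adamic_adar", "resource_allocation"),
) -> pd.DataFrame:
    """Common-neighbor indices: Jaccard, Adamic/Adar, resource allocation.

    Jaccard of a pair with an empty neighborhood union is 0 (no
    neighborhood evidence). A common neighbor of degree 1 is impossible
    on a simple graph; if one is ever encountered (ln 1 = 0 would
    divide), an error is raised rather than returning infinity.
    """
    _check_undirected(network)
    which = tuple(which)
    unknown = set(which) - {"jaccard", "adamic_adar", "resource_allocation"}
    if unknown:
        raise ValueError(f"unknown neighborhood indices: {sorted(unknown)}")
    I, J = _as_pair_arrays(pairs)
    nbrs = _neighbor_sets(network)
    deg = degrees(network).source_degree

    frames = {name: np.zeros(len(I)) for name in which}
    for t in range(len(I)):
        ni = nbrs[I[t]]
        nj = nbrs[J[t]]
        common = ni & nj
        if "jaccard" in frames:
            union = len(ni | nj)
            frames["jaccard"][t] = len(common) / union if union else 0.0
        if common:
            if "adamic_adar" in frames:
                logs = np.log(deg[list(common)])
                if np.any(logs == 0):
                    raise ValueError(
                        "common neighbor of degree 1 encountered (ln 1 = 0)"
                    )
                frames["adamic_adar"][t] = float(np.sum(1.0 / logs))
            if "resource_allocation" in frames:
                frames["resource_allocation"][t] = float(
                    np.sum(1.0 / deg[list(common)])
                )
    out = [
        pd.DataFrame({"source": I, "target": J, "feature": name, "score": frames[name]})
        for name in which
    ]
    return pd.concat(out, ignore_index=True)


def _rwr_matrix(
    network: Network, sources: np.ndarray, restart: float, tol: float, max_iter: int
) -> np.ndarray:
    """Stationary RWR distributions, one column per source node.

    Solves p = restart·e_s + (1 − restart)·W·p by fixed-point iteration,
    with W the column-stochastic uniform-neighbor transition matrix.
    Mass at dangling (degree-0) nodes is redirected to the restart node,
    so each column sums to 1 at the fixed point.
    """
    n = network.n_source
    A = np.zeros((n, n))
    for i, j in network.edges:
        A[i, j] = 1.0
        A[j, i] = 1.0
    col_sums = A.sum(axis=0)
    nonzero = col_sums > 0
    W = np.zeros_like(A)
    W[:, nonzero] = A[:, nonzero] / col_sums[nonzero]
    dangling = ~nonzero

    s = len(sources)
    P = np.zeros((n, s))
    P[sources, np.arange(s)] = 1.0
    for _ in range(max_iter):
        dm = P[dangling, :].sum(axis=0) if dangling.any() else np.zeros(s)
        Q = (1.0 - restart) * (W @ P)
        Q[sources, np.arange(s)] += restart + (1.0 - restart) * dm
        resid = np.abs(Q - P).sum(axis=0).max()
        P = Q
        if resid < tol:
            return P
    raise ConvergenceError(
        f"random walk with restart did not converge in {max_iter} iterations "
        f"(L1 residual {resid:.3e} >= tol {tol:.3e})"
    )


def random_walk_with_restart(
    network: Network,
    pairs,
    restart: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """Symmetrized RWR score (p_s(t) + p_t(s)) / 2 for each pair."""
    _check_undirected(network)
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart must be in (0, 1]")
    I, J = _as_pair_arrays(pairs)
    sources = np.unique(np.concatenate([I, J]))
    col_of = {int(s): k for k, s in enumerate(sources)}
    P = _rwr_matrix(network, sources, restart, tol, max_iter)
    score = np.array(
        [0.5 * (P[J[t], col_of[int(I[t])]] + P[I[t], col_of[int(J[t])]])
         for t in range(len(I))]
    )
    return pd.DataFrame({"source": I, "target": J, "feature": "rwr", "score": score})


def compute_features(
    network: Network,
    pairs,
    features=FEATURE_NAMES,
    restart: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """Compute any subset of the five features; rows grouped by feature."""
    features = tuple(features)
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    out = []
    if "preferential_attachment" in features:
        out.append(preferential_attachment(network, pairs))
    hood = [f for f in features if f in ("jaccard", "adamic_adar", "resource_allocation")]
    if hood:
        out.append(neighborhood_indices(network, pairs, which=hood))
    if "rwr" in features:
        out.append(
            random_walk_with_restart(
                network, pairs, restart=restart, tol=tol, max_iter=max_iter
            )
        )
    return pd.concat(out, ignore_index=True)
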