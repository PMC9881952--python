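"""Generalized XSwap: degree-preserving randomization of networks.

The sampler repeatedly draws two existing edges (a, b) and (c, d) at
random and proposes to exchange their targets, yielding (a, d) and
(c, b). A proposal is performed only if it keeps the network valid —
no duplicate edges, no self-loops or antiparallel pairs unless allowed,
no creation of excluded pairs — and actually changes the edge set.
Every node keeps its exact source and target degree throughout, so the
long-run distribution ranges over networks sharing the input's degree
sequence.

Undirected edges are re-oriented uniformly at random each time they are
sampled: an unordered edge {a, b} enters the swap rule as (a, b) or
(b, a) with probability 1/2 each. Without this, one of the two
target-exchange variants of an undirected swap would be unreachable and
the chain would not be ergodic over the degree-sequence graph space.

Every permutation returns full accounting of attempts, performed swaps,
and the reason each invalid proposal was rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .netcore import Network

__all__ = [
    "SwapParams",
    "PermutationStats",
    "EdgeIndex",
    "is_valid_swap",
    "xswap",
    "permutation_ensemble",
    "edge_retention",
]

_CHUNK = 1 << 16

_REJECTION_REASONS = ("duplicate", "loop", "antiparallel", "excluded", "noop")


@dataclass(frozen=True)
class SwapParams:
    """Parameters of a permutation run.

    ``allow_loops`` / ``allow_antiparallel`` default to ``None``, meaning
    "inherit the network's own flags"; setting them overrides what the
    permuted network may contain. ``multiplier`` is the number of swap
    attempts per edge (total attempts = ceil(multiplier * m)).
    ``excluded_pairs`` are node pairs that are shielded from permutation:
    they are never created by a swap, and if such a pair is an existing
    edge it is never selected for swapping, so it persists untouched.
    """

    multiplier: float = 10.0
    seed: int = 0
    allow_loops: bool | None = None
    allow_antiparallel: bool | None = None
    excluded_pairs: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be positive")
        object.__setattr__(self, "excluded_pairs", frozenset(self.excluded_pairs))


@dataclass
class PermutationStats:
    """Accounting of swap attempts: attempts = performed + Σ rejections."""

    attempts: int = 0
    performed: int = 0
    rejected_duplicate: int = 0
    rejected_loop: int = 0
    rejected_antiparallel: int = 0
    rejected_excluded: int = 0
    rejected_noop: int = 0

    @property
    def rejected_total(self) -> int:
        return (
            self.rejected_duplicate
            + self.rejected_loop
            + self.rejected_antiparallel
            + self.rejected_excluded
            + self.rejected_noop
        )

    def as_dict(self) -> dict:
        return {
            "attempts": self.attempts,
            "performed": self.performed,
            "rejected_duplicate": self.rejected_duplicate,
            "rejected_loop": self.rejected_loop,
            "rejected_antiparallel": self.rejected_antiparallel,
            "rejected_excluded": self.rejected_excluded,
            "rejected_noop": self.rejected_noop,
        }


class EdgeIndex:
    """Edge-membership index with expected constant-time queries.

    Two backends trade memory for speed over the (n_source × n_target)
    pair space: ``"hash"`` stores packed integers in a set (memory ∝ m),
    ``"dense"`` a boolean matrix over the full pair space (memory ∝
    n_source·n_target, faster per query for dense networks). ``"auto"``
    picks dense when the pair space has at most 2**22 cells.
    """

    def __init__(self, network: Network, backend: str = "auto"):
        self.n_target = network.n_target
        cells = network.n_source * network.n_target
        if backend == "auto":
            backend = "dense" if cells <= (1 << 22) else "hash"
        self.backend = backend
        if backend == "dense":
            self._bits = np.zeros(cells, dtype=bool)
            self._set = None
        elif backend == "hash":
            self._bits = None
            self._set = set()
        else:
            raise ValueError(f"unknown backend {backend!r}")
        for i, j in network.edges:
            self.add(i, j)

    def _pack(self, i: int, j: int) -> int:
        return i * self.n_target + j

    def add(self, i: int, j: int) -> None:
        if self._bits is not None:
            self._bits[self._pack(i, j)] = True
        else:
            self._set.add(self._pack(i, j))

    def discard(self, i: int, j: int) -> None:
        if self._bits is not None:
            self._bits[self._pack(i, j)] = False
        else:
            self._set.discard(self._pack(i, j))

    def __contains__(self, edge) -> bool:
        i, j = edge
        if self._bits is not None:
            return bool(self._bits[self._pack(i, j)])
        return self._pack(i, j) in self._set


def _resolved_flags(network: Network, params: SwapParams) -> tuple[bool, bool]:
    allow_loops = (
        network.allow_loops if params.allow_loops is None else params.allow_loops
    )
    allow_anti = (
        network.allow_antiparallel
        if params.allow_antiparallel is None
        else params.allow_antiparallel
    )
    if network.bipartite:
        allow_loops = allow_anti = False
    return allow_loops, allow_anti


def _classify(
    a: int,
    b: int,
    c: int,
    d: int,
    e1c: tuple,
    e2c: tuple,
    index,
    undirected: bool,
    directed: bool,
    bipartite: bool,
    allow_loops: bool,
    allow_antiparallel: bool,
    excluded: frozenset,
) -> str | None:
    """Rejection reason for the proposed swap, or None if valid.

    The proposal replaces edges (a,b), (c,d) by (a,d), (c,b). e1c/e2c
    are the canonical stored forms of the two selected edges.
    """
    if undirected:
        n1 = (a, d) if a <= d else (d, a)
        n2 = (c, b) if c <= b else (b, c)
    else:
        n1 = (a, d)
        n2 = (c, b)
    if (n1 == e1c and n2 == e2c) or (n1 == e2c and n2 == e1c):
        return "noop"
    if not bipartite and not allow_loops and (a == d or c == b):
        return "loop"
    if directed and not allow_antiparallel:
        for x, y in (n1, n2):
            if x != y:
                rev = (y, x)
                if rev != e1c and rev != e2c and rev in index:
                    return "antiparallel"
        # two loops swapped into a mutual pair: (a,d) and (d,a)
        if n1 != n2 and n1[0] != n1[1] and n1 == (n2[1], n2[0]):
            return "antiparallel"
    if n1 == n2:
        return "duplicate"
    for nc in (n1, n2):
        if nc != e1c and nc != e2c and nc in index:
            return "duplicate"
    if excluded and (n1 in excluded or n2 in excluded):
        return "excluded"
    return None


def is_valid_swap(
    edge1: tuple, edge2: tuple, network: Network, params: SwapParams | None = None
) -> tuple[bool, str | None]:
    """Classify the swap replacing edge1=(a,b), edge2=(c,d) by (a,d), (c,b).

    For undirected networks the edges may be given in either orientation
    (the orientation determines which variant of the swap is proposed).
    Returns ``(True, None)`` for a valid swap, else ``(False, reason)``
    with reason in {"duplicate", "loop", "antiparallel", "excluded",
    "noop"}. Raises if either edge is not present in the network.
    """
    params = params or SwapParams()
    a, b = edge1
    c, d = edge2
    e1c = network.canonical(a, b)
    e2c = network.canonical(c, d)
    for edge, canon in ((edge1, e1c), (edge2, e2c)):
        if canon not in network.edges:
            raise ValueError(f"edge {edge} not present in the network")
    if e1c == e2c:
        return False, "noop"
    allow_loops, allow_anti = _resolved_flags(network, params)
    excluded = frozenset(network.canonical(*p) for p in params.excluded_pairs)
    index = EdgeIndex(network, backend="hash")
    undirected = not network.directed and not network.bipartite
    reason = _classify(
        a, b, c, d, e1c, e2c, index,
        undirected, network.directed, network.bipartite,
        allow_loops, allow_anti, excluded,
    )
    return (reason is None), reason


def _run_xswap(
    network: Network,
    params: SwapParams,
    checkpoints: tuple[int, ...] = (),
) -> tuple[Network, PermutationStats, dict[int, float]]:
    """Run one XSwap trajectory, recording edge retention at checkpoints.

    Checkpoints are attempt counts at which the fraction of original
    edges still present is recorded (attempt 0 = the unpermuted input).
    """
    allow_loops, allow_anti = _resolved_flags(network, params)
    undirected = not network.directed and not network.bipartite
    m = network.m
    attempts_total = math.ceil(params.multiplier * m)
    stats = PermutationStats()
    excluded = frozenset(network.canonical(*p) for p in params.excluded_pairs)

    edge_list = [tuple(e) for e in sorted(network.edges)]
    index = EdgeIndex(network)
    original = set(edge_list)
    overlap = m

    retention: dict[int, float] = {}
    cp_iter = iter(sorted(set(checkpoints)))
    next_cp = next(cp_iter, None)
    if next_cp == 0:
        retention[0] = 1.0
        next_cp = next(cp_iter, None)

    rng = np.random.default_rng(params.seed)
    counters = {r: 0 for r in _REJECTION_REASONS}
    done = 0
    while done < attempts_total:
        k = min(_CHUNK, attempts_total - done)
        idx = rng.integers(0, m, size=(k, 2)) if m else np.empty((k, 2), int)
        flips = rng.integers(0, 2, size=(k, 2)).astype(bool) if undirected else None
        for t in range(k):
            i1 = idx[t, 0]
            i2 = idx[t, 1]
            if i1 == i2:
                counters["noop"] += 1
            else:
                e1 = edge_list[i1]
                e2 = edge_list[i2]
                if e1 in excluded or e2 in excluded:
                    counters["excluded"] += 1
                else:
                    a, b = e1
                    c, d = e2
                    if undirected:
                        if flips[t, 0]:
                            a, b = b, a
                        if flips[t, 1]:
                            c, d = d, c
                    reason = _classify(
                        a, b, c, d, e1, e2, index,
                        undirected, network.directed, network.bipartite,
                        allow_loops, allow_anti, excluded,
                    )
                    if reason is None:
                        n1 = (a, d) if (not undirected or a <= d) else (d, a)
                        n2 = (c, b) if (not undirected or c <= b) else (b, c)
                        index.discard(*e1)
                        index.discard(*e2)
                        index.add(*n1)
                        index.add(*n2)
                        edge_list[i1] = n1
                        edge_list[i2] = n2
                        overlap -= (e1 in original) + (e2 in original)
                        overlap += (n1 in original) + (n2 in original)
                        stats.performed += 1
                    else:
                        counters[reason] += 1
            done_now = done + t + 1
            if next_cp is not None and done_now == next_cp:
                retention[next_cp] = overlap / m if m else 1.0
                next_cp = next(cp_iter, None)
        done += k

    stats.attempts = attempts_total
    stats.rejected_duplicate = counters["duplicate"]
    stats.rejected_loop = counters["loop"]
    stats.rejected_antiparallel = counters["antiparallel"]
    stats.rejected_excluded = counters["excluded"]
    stats.rejected_noop = counters["noop"]

    permuted = Network(
        frozenset(edge_list),
        network.n_source,
        network.n_target,
        network.directed,
        network.bipartite,
        network.allow_loops or allow_loops,
        network.allow_antiparallel or allow_anti,
    )
    return permuted, stats, retention


def xswap(
    network: Network, params: SwapParams | None = None
) -> tuple[Network, PermutationStats]:
    """Degree-preserving permutation of a network.

    Performs ``ceil(multiplier * m)`` swap attempts starting from a copy
    of the input (the input is never mutated). The permuted network has
    the identical node universe, edge count, and per-node source/target
    degrees. Reproducible for a fixed ``params.seed``. With fewer than
    two edges no swap has a partner, so the output equals the input with
    all attempts rejected.
    """
    params = params or SwapParams()
    permuted, stats, _ = _run_xswap(network, params)
    return permuted, stats


def permutation_ensemble(
    network: Network, n_permutations: int, params: SwapParams | None = None
) -> Iterator[tuple[Network, PermutationStats]]:
    """Stream of independent permutations, each starting from the input.

    Permutation ``i`` uses seed ``params.seed + i``, so the stream is
    deterministic and individual members can be regenerated in isolation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    params = params or SwapParams()
    for i in range(n_permutations):
        yield xswap(network, replace(params, seed=params.seed + i))


def edge_retention(
    network: Network,
    multipliers,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean fraction of original edges retained vs swap-attempt budget.

    For each repetition one trajectory is run to the largest multiplier
    and the retained fraction is recorded when each multiplier's attempt
    budget (ceil(multiplier * m)) is reached; repetitions use seeds
    ``seed + rep``. Sharing the trajectory across multipliers acts as a
    common-random-numbers scheme, so the retention curve is compared at
    matched randomness. Returns a DataFrame with columns ``multiplier``,
    ``retention`` (mean over repetitions), and ``std`` (sample standard
    deviation over repetitions, for Monte-Carlo error bars).
    """
    multipliers = list(multipliers)
    if any(x < 0 for x in multipliers):
        raise ValueError("multipliers must be nonnegative")
    if sorted(multipliers) != multipliers:
        raise ValueError("multipliers must be increasing")
    m = network.m
    checkpoints = tuple(math.ceil(x * m) for x in multipliers)
    max_mult = max(multipliers) if multipliers else 0.0
    values = np.zeros((n_reps, len(multipliers)))
    for rep in range(n_reps):
        params = SwapParams(multiplier=max_mult, seed=seed + rep)
        _, _, retention = _run_xswap(network, params, checkpoints=checkpoints)
        values[rep] = [retention[cp] for cp in checkpoints]
    return pd.DataFrame(
        {
            "multiplier": multipliers,
            "retention": values.mean(axis=0),
            "std": values.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(len(multipliers)),
        }
    )
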