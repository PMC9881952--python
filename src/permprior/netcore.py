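"""Core graph data model: immutable unweighted networks, node-label maps,
degree indexing, edge-list I/O, and uniform edge subsampling.

Networks are index-based: nodes are contiguous integers within each node
class. String labels live in a separate :class:`NodeLabelMap` so that the
permutation and scoring machinery can operate on plain integer pairs.

Three structural kinds are supported:

* undirected unipartite — each edge is an unordered pair, stored
  canonically with the smaller index first;
* directed unipartite — edges are ordered (source, target) pairs over a
  single node class; antiparallel pairs (i→j and j→i) are permitted only
  when the network allows them;
* bipartite — source and target indices refer to two disjoint node
  classes, each indexed from zero, so self-loops and antiparallel edges
  are structurally impossible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Network",
    "NodeLabelMap",
    "DegreeIndex",
    "read_edge_list",
    "write_edge_list",
    "read_label_map",
    "write_label_map",
    "degrees",
    "subsample_edges",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class Network:
    """An immutable unweighted network over integer node indices.

    Parameters
    ----------
    edges
        Set of ``(source, target)`` index pairs. Undirected edges must be
        canonical (smaller index first); the constructor validates this.
    n_source, n_target
        Size of the source / target node class. Equal for unipartite
        networks (one shared class).
    directed, bipartite
        Structural kind flags. ``bipartite`` implies ``directed=False``
        because the orientation of a bipartite edge is structural.
    allow_loops, allow_antiparallel
        Whether self-loops (i, i) and antiparallel directed pairs may
        exist. Both must be False for bipartite networks, where they are
        structurally impossible.
    """

    edges: frozenset
    n_source: int
    n_target: int
    directed: bool = False
    bipartite: bool = False
    allow_loops: bool = False
    allow_antiparallel: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", frozenset((int(i), int(j)) for i, j in self.edges)
        )
        if self.bipartite:
            if self.directed:
                raise ValueError(
                    "bipartite edges are structurally oriented; use directed=False"
                )
            if self.allow_loops or self.allow_antiparallel:
                raise ValueError(
                    "loops/antiparallel edges are structurally impossible "
                    "in bipartite networks"
                )
        elif self.n_source != self.n_target:
            raise ValueError("unipartite networks require n_source == n_target")
        undirected = not self.directed and not self.bipartite
        for i, j in self.edges:
            if not (0 <= i < self.n_source and 0 <= j < self.n_target):
                raise ValueError(f"edge ({i}, {j}) outside the node universe")
            if undirected and i > j:
                raise ValueError(
                    f"undirected edge ({i}, {j}) must be stored as (min, max)"
                )
            if i == j and not self.bipartite and not self.allow_loops:
                raise ValueError(f"self-loop ({i}, {i}) present but loops disallowed")
        if self.directed and not self.allow_antiparallel:
            for i, j in self.edges:
                if i != j and (j, i) in self.edges:
                    raise ValueError(
                        f"antiparallel pair ({i},{j})/({j},{i}) present "
                        "but antiparallel edges disallowed"
                    )

    # ------------------------------------------------------------------
    @property
    def m(self) -> int:
        """Total number of edges."""
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return self.n_source + self.n_target if self.bipartite else self.n_source

    def canonical(self, i: int, j: int) -> Edge:
        """Canonical storage form of the pair (i, j) for this network kind."""
        if self.directed or self.bipartite or i <= j:
            return (i, j)
        return (j, i)

    def has_edge(self, i: int, j: int) -> bool:
        return self.canonical(i, j) in self.edges

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) int64 array in deterministic sorted order."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def replace_edges(self, edges) -> "Network":
        """A network with the same universe and flags but different edges."""
        return Network(
            frozenset(edges),
            self.n_source,
            self.n_target,
            self.directed,
            self.bipartite,
            self.allow_loops,
            self.allow_antiparallel,
        )


@dataclass(frozen=True)
class NodeLabelMap:
    """Bijection between string labels and contiguous integer indices.

    ``target_labels is None`` means the network is unipartite and both
    columns share ``source_labels``.
    """

    source_labels: tuple
    target_labels: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_labels", tuple(self.source_labels))
        if self.target_labels is not None:
            object.__setattr__(self, "target_labels", tuple(self.target_labels))
        for labels in (self.source_labels, self.target_labels):
            if labels is not None and len(set(labels)) != len(labels):
                raise ValueError("node labels must be unique within a class")
        object.__setattr__(
            self, "_src_idx", {lab: i for i, lab in enumerate(self.source_labels)}
        )
        tgt = self.target_labels if self.target_labels is not None else self.source_labels
        object.__setattr__(self, "_tgt_idx", {lab: i for i, lab in enumerate(tgt)})

    @property
    def effective_target_labels(self) -> tuple:
        return self.target_labels if self.target_labels is not None else self.source_labels

    def source_index(self, label: str) -> int:
        return self._src_idx[label]

    def target_index(self, label: str) -> int:
        return self._tgt_idx[label]

    def source_label(self, index: int) -> str:
        return self.source_labels[index]

    def target_label(self, index: int) -> str:
        return self.effective_target_labels[index]


@dataclass(frozen=True)
class DegreeIndex:
    """Per-node source degree u_i, target degree v_j, and edge count m.

    For undirected networks ``source_degree is target_degree`` (one shared
    degree vector, in which a self-loop contributes 2 when loops are
    allowed) and the degree sum is 2m; for directed and bipartite networks
    the source (out) and target (in) degree vectors each sum to m.
    """

    source_degree: np.ndarray
    target_degree: np.ndarray
    m: int


def degrees(network: Network) -> DegreeIndex:
    """Exact integer degrees of every node in the network."""
    arr = network.edge_array()
    if network.directed or network.bipartite:
        src = np.bincount(arr[:, 0], minlength=network.n_source)
        tgt = np.bincount(arr[:, 1], minlength=network.n_target)
    else:
        # concatenating both endpoints makes a loop count twice, as required
        endpoints = np.concatenate([arr[:, 0], arr[:, 1]])
        src = tgt = np.bincount(endpoints, minlength=network.n_source)
    return DegreeIndex(src.astype(np.int64), tgt.astype(np.int64), network.m)


# ----------------------------------------------------------------------
# Edge-list I/O
# ----------------------------------------------------------------------


def _parse_line(line: str, lineno: int) -> tuple[str, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 2:
        fields = line.split()
    if len(fields) != 2:
        raise ValueError(f"line {lineno}: expected two tab-separated columns")
    return fields[0], fields[1]


def read_edge_list(
    path,
    directed: bool = False,
    bipartite: bool = False,
    allow_loops: bool = False,
    allow_antiparallel: bool = False,
    labels: NodeLabelMap | None = None,
) -> tuple[Network, NodeLabelMap]:
    """Read a two-column TSV edge list (``#`` lines are comments).

    Labels are mapped to contiguous indices in first-appearance order
    (per node class for bipartite input), unless an existing ``labels``
    map is supplied, in which case its indices are used — this is how a
    written network (including any zero-degree nodes) is reproduced
    index-exactly.

    Raises ``ValueError`` naming the offending line for duplicate edges
    (after canonicalization), disallowed self-loops, and disallowed
    antiparallel pairs.
    """
    path = Path(path)
    undirected = not directed and not bipartite

    if labels is not None:
        src_idx = {lab: i for i, lab in enumerate(labels.source_labels)}
        tgt_idx = {lab: i for i, lab in enumerate(labels.effective_target_labels)}
        frozen_maps = True
    else:
        src_idx = {}
        tgt_idx = src_idx if not bipartite else {}
        frozen_maps = False

    def index_of(table: dict, label: str, lineno: int) -> int:
        if label in table:
            return table[label]
        if frozen_maps:
            raise ValueError(f"line {lineno}: label {label!r} not in supplied label map")
        table[label] = len(table)
        return table[label]

    edges: set[Edge] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            s_lab, t_lab = _parse_line(line, lineno)
            i = index_of(src_idx, s_lab, lineno)
            j = index_of(tgt_idx, t_lab, lineno)
            if undirected and i > j:
                i, j = j, i
            if i == j and not bipartite and not allow_loops:
                raise ValueError(
                    f"line {lineno}: self-loop {s_lab!r} but allow_loops is false"
                )
            if (
                directed
                and not allow_antiparallel
                and i != j
                and (j, i) in edges
            ):
                raise ValueError(
                    f"line {lineno}: antiparallel edge {s_lab!r}\t{t_lab!r} "
                    "but allow_antiparallel is false"
                )
            if (i, j) in edges:
                raise ValueError(
                    f"line {lineno}: duplicate edge {s_lab!r}\t{t_lab!r} "
                    "after canonicalization"
                )
            edges.add((i, j))

    if labels is None:
        source_labels = tuple(src_idx)
        if bipartite:
            labels = NodeLabelMap(source_labels, tuple(tgt_idx))
        else:
            labels = NodeLabelMap(source_labels)
    n_source = len(labels.source_labels)
    n_target = len(labels.effective_target_labels)
    network = Network(
        frozenset(edges),
        n_source,
        n_target,
        directed=directed,
        bipartite=bipartite,
        allow_loops=allow_loops,
        allow_antiparallel=allow_antiparallel,
    )
    return network, labels


def write_edge_list(network: Network, labels: NodeLabelMap, path) -> None:
    """Write a network as a two-column TSV edge list with a ``#`` header.

    Edges are written in sorted index order so output is deterministic.
    Writing the :class:`NodeLabelMap` sidecar (:func:`write_label_map`)
    alongside allows an index-exact round trip through
    :func:`read_edge_list`.
    """
    n_src_lab = len(labels.source_labels)
    n_tgt_lab = len(labels.effective_target_labels)
    if n_src_lab < network.n_source or n_tgt_lab < network.n_target:
        raise ValueError("label map does not cover all node indices")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\n")
        if network.bipartite:
            fh.write("# bipartite: source and target columns are distinct node classes\n")
        for i, j in sorted(network.edges):
            fh.write(f"{labels.source_label(i)}\t{labels.target_label(j)}\n")


def write_label_map(labels: NodeLabelMap, path) -> None:
    """Write a NodeLabelMap as a JSON sidecar."""
    payload = {"source_labels": list(labels.source_labels)}
    if labels.target_labels is not None:
        payload["target_labels"] = list(labels.target_labels)
    Path(path).write_text(json.dumps(payload, indent=0) + "\n")


def read_label_map(path) -> NodeLabelMap:
    payload = json.loads(Path(path).read_text())
    target = payload.get("target_labels")
    return NodeLabelMap(
        tuple(payload["source_labels"]),
        tuple(target) if target is not None else None,
    )


# ----------------------------------------------------------------------
# Subsampling
# ----------------------------------------------------------------------


def subsample_edges(
    network: Network, fraction: float, seed: int
) -> tuple[Network, frozenset]:
    """Uniformly sample ``round(fraction * m)`` edges without replacement.

    Returns the sampled network (same node universe, so zero-degree nodes
    are retained) and the held-out complement edge set. Deterministic for
    a fixed seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    arr = network.edge_array()
    k = int(round(fraction * network.m))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(network.m, size=k, replace=False)
    mask = np.zeros(network.m, dtype=bool)
    mask[chosen] = True
    sampled = frozenset(map(tuple, arr[mask]))
    heldout = frozenset(map(tuple, arr[~mask]))
    return network.replace_edges(sampled), heldout
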