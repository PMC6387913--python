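"""Robust consensus networks from leave-one-fold-out structure learning.

The protocol: randomly partition the samples into ten folds; learn one
"fundamental" network on each nine-fold subset (ten networks in total); keep
an edge in the final network only when the corresponding skeleton pair occurs
in at least seven of the ten fundamental networks; orient each kept pair by
the majority direction; annotate with the correlation sign computed on the
full dataset.

Edge identity for the stability count is the *skeleton* pair (either
direction counts): score-equivalent DAGs can flip edge directions between
folds, so counting directed edges would undercount stable dependencies. The
strict directed count is also recorded per edge for the alternative reading.
Consensus cycles — possible because majority orientations of different pairs
need not be jointly acyclic — are resolved by re-orienting the
lowest-stability edge on each cycle (or dropping it if re-orienting still
cycles), with every such repair flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlation import CorrelationMatrix
from .matrix import ModificationMatrix
from .structure import DAGStructure, LearnConfig, hill_climb


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each sample to one of k folds, sizes differing by <= 1."""

    n_samples: int
    assignments: tuple[int, ...]
    seed: int
    k: int = 10

    def __post_init__(self) -> None:
        if len(self.assignments) != self.n_samples:
            raise ValueError("one fold index required per sample")
        counts = np.bincount(self.assignments, minlength=self.k)
        if len(set(self.assignments)) != self.k:
            raise ValueError(f"expected exactly {self.k} non-empty folds")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    def holdout_mask(self, fold: int) -> np.ndarray:
        """Boolean mask selecting the samples *outside* the given fold."""
        return np.asarray(self.assignments) != fold


@dataclass(frozen=True)
class ConsensusEdge:
    parent: str
    child: str
    stability_count: int              # skeleton count over the networks
    correlation_sign: str             # "+", "-", or "undefined"
    correlation_value: float | None = None
    directed_counts: tuple[int, int] = (0, 0)  # (parent->child, child->parent)
    direction_tie: bool = False
    cycle_repaired: bool = False

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.parent, self.child))


@dataclass
class ConsensusNetwork:
    """Final stability-filtered network with signed, counted edges."""

    nodes: list[str]
    edges: list[ConsensusEdge]
    threshold: int = 7
    n_networks: int = 10
    dropped_cycle_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for e in self.edges:
            if e.parent not in declared or e.child not in declared:
                raise ValueError(f"edge endpoint not declared: {e}")
        if not self.to_dag().is_acyclic():  # pragma: no cover - DAGStructure raises first
            raise ValueError("consensus network contains a cycle")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(e.pair for e in self.edges)

    def to_dag(self) -> DAGStructure:
        return DAGStructure(self.nodes, {(e.parent, e.child) for e in self.edges})

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return g


def make_folds(n_samples: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded uniform random partition into k folds of near-equal size."""
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    perm = rng.permutation(n_samples)
    assignments = np.empty(n_samples, dtype=int)
    assignments[perm] = np.arange(n_samples) % k
    return FoldPlan(n_samples=n_samples, assignments=tuple(int(a) for a in assignments),
                    seed=seed, k=k)


def learn_fundamental_networks(data: ModificationMatrix, folds: FoldPlan,
                               config: LearnConfig | None = None,
                               ) -> list[DAGStructure]:
    """One hill-climbed network per leave-one-fold-out dataset, in fold order."""
    if folds.n_samples != data.n_samples:
        raise ValueError("fold plan does not match the data")
    config = config or LearnConfig()
    networks = []
    for fold in range(folds.k):
        subset = data.subset_rows(folds.holdout_mask(fold))
        networks.append(hill_climb(subset, config))
    return networks


def build_consensus(networks: list[DAGStructure], threshold: int = 7,
                    cm: CorrelationMatrix | None = None) -> ConsensusNetwork:
    """Stability-filter a list of fundamental networks into one DAG.

    A skeleton pair is retained when it appears (in either direction) in at
    least ``threshold`` networks; its direction is the majority direction
    among the networks that contain it, with ties going to the
    lexicographically smaller node as parent (flagged). Correlation signs are
    looked up in ``cm`` (computed on the full dataset) when provided.
    """
    if not networks:
        raise ValueError("need at least one network")
    if not 1 <= threshold <= len(networks):
        raise ValueError(
            f"threshold {threshold} outside 1..{len(networks)}")
    node_set = set(networks[0].nodes)
    for net in networks[1:]:
        if set(net.nodes) != node_set:
            raise ValueError("all networks must share the same node set")
    nodes = list(networks[0].nodes)

    directed: dict[tuple[str, str], int] = {}
    for net in networks:
        for edge in net.edges:
            directed[edge] = directed.get(edge, 0) + 1

    pairs: dict[frozenset[str], tuple[int, int, str, str]] = {}
    for (u, v), cnt in directed.items():
        key = frozenset((u, v))
        if key in pairs:
            continue
        a, b = sorted(key)
        ab = directed.get((a, b), 0)
        ba = directed.get((b, a), 0)
        pairs[key] = (ab, ba, a, b)

    edges: list[ConsensusEdge] = []
    for ab, ba, a, b in sorted(pairs.values(), key=lambda t: (t[2], t[3])):
        skeleton_count = ab + ba
        if skeleton_count < threshold:
            continue
        tie = ab == ba
        parent, child = (a, b) if ab >= ba else (b, a)
        sign, value = "undefined", None
        if cm is not None and a in cm.mark_names and b in cm.mark_names:
            sign = cm.sign(a, b)
            v = cm.get(a, b)
            value = None if np.isnan(v) else float(v)
        edges.append(ConsensusEdge(
            parent=parent, child=child, stability_count=skeleton_count,
            correlation_sign=sign, correlation_value=value,
            directed_counts=(directed.get((parent, child), 0),
                             directed.get((child, parent), 0)),
            direction_tie=tie))

    edges, dropped = _resolve_cycles(nodes, edges)
    return ConsensusNetwork(nodes=nodes, edges=edges, threshold=threshold,
                            n_networks=len(networks),
                            dropped_cycle_edges=dropped)


def consensus_protocol(data: ModificationMatrix,
                       config: LearnConfig | None = None,
                       threshold: int = 7, k: int = 10, seed: int = 0,
                       n_rounds: int = 1,
                       cm: CorrelationMatrix | None = None,
                       ) -> tuple[ConsensusNetwork, list[DAGStructure], list[FoldPlan]]:
    """Full protocol: folds -> fundamental networks -> consensus.

    With ``n_rounds > 1`` the k-fold split is repeated with fresh seeds and
    the stability filter applies the same retention fraction (threshold / k)
    to the pooled ``n_rounds * k`` networks — the alternative reading of the
    repeated-cross-validation protocol. Correlation signs always come from
    the full dataset.
    """
    from .correlation import correlation_matrix
    config = config or LearnConfig()
    if cm is None:
        cm = correlation_matrix(data)
    networks: list[DAGStructure] = []
    plans: list[FoldPlan] = []
    for r in range(n_rounds):
        plan = make_folds(data.n_samples, k=k, seed=seed + 7919 * r)
        plans.append(plan)
        networks.extend(learn_fundamental_networks(data, plan, config))
    pooled_threshold = threshold if n_rounds == 1 else \
        int(np.ceil(threshold / k * len(networks)))
    net = build_consensus(networks, threshold=pooled_threshold, cm=cm)
    return net, networks, plans


def _resolve_cycles(nodes: list[str], edges: list[ConsensusEdge],
                    ) -> tuple[list[ConsensusEdge], list[tuple[str, str]]]:
    """Repair directed cycles: re-orient the weakest edge, else drop it."""
    edges = list(edges)
    dropped: list[tuple[str, str]] = []
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from((e.parent, e.child) for e in edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        cycle_edges = {(u, v) for u, v, *_ in cycle}
        on_cycle = [e for e in edges if (e.parent, e.child) in cycle_edges]
        weakest = min(on_cycle,
                      key=lambda e: (e.stability_count, e.parent, e.child))
        edges.remove(weakest)
        # flipping child->parent cycles again iff a parent ~> child path
        # survives without the original edge
        g.remove_edge(weakest.parent, weakest.child)
        if not nx.has_path(g, weakest.parent, weakest.child):
            flipped = ConsensusEdge(
                parent=weakest.child, child=weakest.parent,
                stability_count=weakest.stability_count,
                correlation_sign=weakest.correlation_sign,
                correlation_value=weakest.correlation_value,
                directed_counts=tuple(reversed(weakest.directed_counts)),
                direction_tie=weakest.direction_tie, cycle_repaired=True)
            edges.append(flipped)
        else:
            dropped.append((weakest.parent, weakest.child))
    return edges, dropped
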