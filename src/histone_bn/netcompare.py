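"""Post-analysis of consensus networks.

Three questions about a final network (or a pair of them):

* which *combinatorial patterns* does it contain — operationalised as
  connected components of the undirected skeleton with at least two marks
  (on the real CD4+ T-cell matrices the excluded-exon network is reported
  to have 19 edges / 10 patterns and the included-exon network 21 edges /
  13 patterns; those shapes depend on the original data and learner and are
  documented expectations, not package constants);
* which marks sit *directly adjacent* to a splicing-outcome node, when the
  network was learned over a matrix with an appended binary
  included/excluded column;
* how two networks *differ*, at the skeleton level, including sign agreement
  on shared edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .consensus import ConsensusNetwork


@dataclass
class PatternReport:
    """Connected-component decomposition of a consensus skeleton."""

    n_edges: int
    patterns: list[frozenset[str]]        # components with >= 2 marks
    singleton_nodes: frozenset[str]

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)


@dataclass
class NetworkDiff:
    """Skeleton-level set difference between two consensus networks."""

    edges_only_in_a: frozenset[frozenset[str]]
    edges_only_in_b: frozenset[frozenset[str]]
    shared_edges: frozenset[frozenset[str]]
    sign_agreement: dict[frozenset[str], bool] = field(default_factory=dict)


def find_patterns(network: ConsensusNetwork) -> PatternReport:
    """Combinatorial patterns = components (>= 2 marks) of the skeleton.

    Direction-blind by construction; isolated marks are listed separately.
    """
    g = network.to_undirected()
    patterns = []
    singletons = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            patterns.append(frozenset(comp))
        else:
            singletons.update(comp)
    patterns.sort(key=lambda c: (-len(c), min(c)))
    return PatternReport(n_edges=network.n_edges, patterns=patterns,
                         singleton_nodes=frozenset(singletons))


def direct_marks(network: ConsensusNetwork, outcome: str) -> list[str]:
    """Marks adjacent (as parent or child) to the outcome node, sorted.

    The outcome node is the binary splicing indicator appended to the matrix
    before learning; its graph neighbours are the marks with a direct
    dependence on the splicing event in the learned network.
    """
    if outcome not in network.nodes:
        raise ValueError(f"outcome node {outcome!r} not in the network")
    adjacent = set()
    for e in network.edges:
        if e.parent == outcome:
            adjacent.add(e.child)
        elif e.child == outcome:
            adjacent.add(e.parent)
    return sorted(adjacent)


def diff_networks(a: ConsensusNetwork, b: ConsensusNetwork) -> NetworkDiff:
    """Skeleton set difference plus per-shared-edge sign agreement."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("networks must share the same node set")
    skel_a = a.skeleton()
    skel_b = b.skeleton()
    shared = skel_a & skel_b
    signs_a = {e.pair: e.correlation_sign for e in a.edges}
    signs_b = {e.pair: e.correlation_sign for e in b.edges}
    agreement = {pair: signs_a[pair] == signs_b[pair] for pair in shared}
    return NetworkDiff(edges_only_in_a=frozenset(skel_a - skel_b),
                       edges_only_in_b=frozenset(skel_b - skel_a),
                       shared_edges=frozenset(shared),
                       sign_agreement=agreement)
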