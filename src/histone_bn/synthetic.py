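"""Synthetic binary datasets with known (planted) dependency structure.

Two generators:

* :func:`build_planted_dag` + :func:`forward_sample` — a random DAG with
  noisy-OR-like CPTs (a child turns on with probability ``effect_strength``
  when at least one parent is on, ``1 - effect_strength`` otherwise), used to
  benchmark structure recovery with a known answer key.
* :func:`histone_preset` — a 38-column dataset named after the real histone
  marks that reproduces the qualitative correlation geography of CD4+ T-cell
  exons: a positively co-occurring cluster seeded by H2BK5me1, one mark
  (H3K9me3) anticorrelated with most others via a shared latent activity
  state, and a ~0.3 background presence rate.

One integer seed controls two derived streams (DAG topology vs. sampling), so
tests can vary the data while holding the structure fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import MARK_CATALOG
from .matrix import ModificationMatrix, Region, SplicingClass
from .structure import DAGStructure

_STRUCTURE_STREAM = 0
_SAMPLING_STREAM = 1


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, which]))


@dataclass(frozen=True)
class CPTSet:
    """Conditional probability tables for every node of a binary DAG.

    ``parents[node]`` is the ordered parent list; ``tables[node]`` maps each
    parent-value tuple (over {0,1}, in parent order) to P(node = 1).
    """

    parents: dict[str, tuple[str, ...]]
    tables: dict[str, dict[tuple[int, ...], float]]

    def __post_init__(self) -> None:
        if set(self.parents) != set(self.tables):
            raise ValueError("parents and tables must cover the same nodes")
        for node, pa in self.parents.items():
            table = self.tables[node]
            if len(table) != 2 ** len(pa):
                raise ValueError(
                    f"{node}: table has {len(table)} entries, expected "
                    f"{2 ** len(pa)} for {len(pa)} parents")
            for combo, prob in table.items():
                if len(combo) != len(pa) or not all(v in (0, 1) for v in combo):
                    raise ValueError(f"{node}: bad parent combination {combo}")
                if not 0.0 <= prob <= 1.0:
                    raise ValueError(f"{node}: probability {prob} outside [0,1]")


@dataclass(frozen=True)
class PlantedScenario:
    """A DAG, its CPTs, and the sampling plan — the answer key travels along."""

    dag: DAGStructure
    cpts: CPTSet
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        missing = set(self.dag.nodes) - set(self.cpts.parents)
        if missing:
            raise ValueError(f"nodes without CPTs: {sorted(missing)}")


def _noisy_or_table(n_parents: int, effect_strength: float,
                    ) -> dict[tuple[int, ...], float]:
    table = {}
    for combo in np.ndindex(*([2] * n_parents)):
        on = any(combo)
        table[tuple(int(v) for v in combo)] = (
            effect_strength if on else 1.0 - effect_strength)
    return table


def max_feasible_edges(n_nodes: int, max_parents: int) -> int:
    """Largest edge count a DAG on ``n_nodes`` admits under an in-degree cap."""
    return sum(min(i, max_parents) for i in range(n_nodes))


def build_planted_dag(n_nodes: int, n_edges: int, max_parents: int,
                      effect_strength: float, seed: int,
                      n_samples: int = 10_000,
                      node_names: list[str] | None = None) -> PlantedScenario:
    """Random DAG with exactly ``n_edges`` edges and noisy-OR-like CPTs.

    Roots have P(on) = 0.5; a child is on with probability
    ``effect_strength`` when at least one parent is on, else
    ``1 - effect_strength``. Deterministic given ``seed``.
    """
    if not 0.5 < effect_strength <= 1.0:
        raise ValueError("effect_strength must be in (0.5, 1]")
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    cap = max_feasible_edges(n_nodes, max_parents)
    if n_edges < 0 or n_edges > cap:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_nodes} nodes with "
            f"max_parents={max_parents} (at most {cap})")
    if node_names is None:
        width = max(2, len(str(n_nodes - 1)))
        node_names = [f"M{i:0{width}d}" for i in range(n_nodes)]
    elif len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")

    rng = _stream(seed, _STRUCTURE_STREAM)
    order = rng.permutation(n_nodes)  # topological order of node indices
    pos = np.empty(n_nodes, dtype=int)
    pos[order] = np.arange(n_nodes)
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes)
             if pos[i] < pos[j]]
    rng.shuffle(pairs)
    # greedy pick under the per-child cap: a partition matroid, so greedy
    # always reaches any feasible edge count
    indeg = np.zeros(n_nodes, dtype=int)
    chosen: list[tuple[int, int]] = []
    for u, v in pairs:
        if len(chosen) == n_edges:
            break
        if indeg[v] < max_parents:
            indeg[v] += 1
            chosen.append((u, v))

    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, dict[tuple[int, ...], float]] = {}
    parent_idx: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for u, v in chosen:
        parent_idx[v].append(u)
    for i, name in enumerate(node_names):
        pa = tuple(node_names[u] for u in sorted(parent_idx[i]))
        parents[name] = pa
        tables[name] = ({(): 0.5} if not pa
                        else _noisy_or_table(len(pa), effect_strength))
    dag = DAGStructure(node_names,
                       {(node_names[u], node_names[v]) for u, v in chosen})
    return PlantedScenario(dag=dag, cpts=CPTSet(parents, tables),
                           n_samples=n_samples, seed=seed)


def forward_sample(scenario: PlantedScenario) -> ModificationMatrix:
    """Draw ``n_samples`` rows by ancestral sampling in topological order.

    Column order follows ``scenario.dag.nodes``; reproducible given the
    scenario's seed (sampling uses its own derived stream, independent of the
    topology stream).
    """
    rng = _stream(scenario.seed, _SAMPLING_STREAM)
    n = scenario.n_samples
    names = list(scenario.dag.nodes)
    col = {m: j for j, m in enumerate(names)}
    values = np.zeros((n, len(names)), dtype=np.uint8)
    for node in scenario.dag.topological_order():
        pa = scenario.cpts.parents[node]
        table = scenario.cpts.tables[node]
        if not pa:
            p = np.full(n, table[()])
        else:
            idx = np.zeros(n, dtype=np.int64)
            for parent in pa:
                idx = (idx << 1) | values[:, col[parent]]
            lookup = np.empty(2 ** len(pa))
            for combo, prob in table.items():
                key = 0
                for v in combo:
                    key = (key << 1) | v
                lookup[key] = prob
            p = lookup[idx]
        values[:, col[node]] = rng.random(n) < p
    ids = [f"synth_{i:06d}" for i in range(n)]
    return ModificationMatrix(ids, names, values,
                              region=Region.EXON,
                              splicing_class=SplicingClass.MIXED,
                              warn_on_zero_rows=False)


def outcome_scenario(n_samples: int, seed: int, n_parents: int = 3,
                     effect_strength: float = 0.9,
                     outcome_name: str = "SPLICING_OUTCOME",
                     ) -> PlantedScenario:
    """Marks plus a binary outcome planted as a noisy-OR child of some marks.

    The 38 catalog marks are independent Bernoulli(0.3); the outcome node is
    on with probability ``effect_strength`` when at least one of its
    ``n_parents`` randomly chosen mark parents is on. The scenario's DAG is
    the answer key for outcome-adjacency recovery.
    """
    if not 1 <= n_parents <= 4:
        raise ValueError("n_parents must be in 1..4")
    names = list(MARK_CATALOG.names)
    rng = _stream(seed, _STRUCTURE_STREAM)
    chosen = sorted(str(m) for m in rng.choice(names, size=n_parents,
                                               replace=False))
    parents: dict[str, tuple[str, ...]] = {m: () for m in names}
    tables: dict[str, dict[tuple[int, ...], float]] = {
        m: {(): 0.3} for m in names}
    parents[outcome_name] = tuple(chosen)
    tables[outcome_name] = _noisy_or_table(n_parents, effect_strength)
    dag = DAGStructure(names + [outcome_name],
                       {(m, outcome_name) for m in chosen})
    return PlantedScenario(dag=dag, cpts=CPTSet(parents, tables),
                           n_samples=n_samples, seed=seed)


# histone-like preset ---------------------------------------------------------

#: marks turned on by H2BK5me1 in the co-occurrence cluster
H2BK5ME1_CLUSTER = ("H3K4me1", "H3K4me2", "H3K79me1", "H3K9me1",
                    "H4K20me1", "H4K91ac")
#: the repressive mark that anticorrelates with nearly everything else
ANTICORRELATED_MARK = "H3K9me3"
_LATENT = "LATENT_ACTIVITY"


def histone_preset(n_samples: int, seed: int) -> ModificationMatrix:
    """A 38-mark dataset mimicking the CD4+ T-cell correlation structure.

    A hidden binary "activity" state drives 31 marks up when on (giving the
    broad positive correlation block) and drives H3K9me3 down (giving its
    negative row). H2BK5me1 additionally switches its six cluster partners on
    with effect strength 0.85. Background presence is ~0.3 per mark. The
    latent state is sampled but not returned as a column.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    names = list(MARK_CATALOG.names)
    nodes = [_LATENT] + names
    parents: dict[str, tuple[str, ...]] = {_LATENT: ()}
    tables: dict[str, dict[tuple[int, ...], float]] = {_LATENT: {(): 0.5}}
    edges: set[tuple[str, str]] = set()
    for mark in names:
        if mark == ANTICORRELATED_MARK:
            parents[mark] = (_LATENT,)
            tables[mark] = {(1,): 0.12, (0,): 0.55}  # repressed when active
            edges.add((_LATENT, mark))
        elif mark in H2BK5ME1_CLUSTER:
            parents[mark] = ("H2BK5me1",)
            tables[mark] = {(1,): 0.85, (0,): 0.15}
            edges.add(("H2BK5me1", mark))
        else:
            # activity-coupled background, marginal ~= 0.3 at P(latent)=0.5
            parents[mark] = (_LATENT,)
            tables[mark] = {(1,): 0.45, (0,): 0.15}
            edges.add((_LATENT, mark))
    dag = DAGStructure(nodes, edges)
    scenario = PlantedScenario(dag=dag, cpts=CPTSet(parents, tables),
                               n_samples=n_samples, seed=seed)
    sampled = forward_sample(scenario)
    keep = [j for j, m in enumerate(sampled.mark_names) if m != _LATENT]
    return ModificationMatrix(
        [f"exon_{i:06d}" for i in range(n_samples)],
        [sampled.mark_names[j] for j in keep],
        sampled.values[:, keep],
        region=Region.EXON, splicing_class=SplicingClass.MIXED,
        warn_on_zero_rows=False)
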