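#!/usr/bin/env python
"""Consensus Bayesian networks per dataset.

For each planted-class dataset: 10 leave-one-fold-out hill climbs, the
>=7-of-10 stability filter with correlation-sign annotation, and the
combinatorial-pattern report. Prints skeleton precision/recall against the
planted answer key.
"""

import json
from pathlib import Path

from histone_bn.consensus import consensus_protocol
from histone_bn.io import read_modification_matrix, write_network
from histone_bn.netcompare import find_patterns

SEED = 1
DATA = Path("results/data")
OUT = Path("results/networks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tsv in sorted(DATA.glob("*_exon.matrix.tsv")):
        label = tsv.name.replace(".matrix.tsv", "")
        matrix = read_modification_matrix(tsv)
        net, fundamentals, _ = consensus_protocol(matrix, threshold=7,
                                                  seed=SEED)
        write_network(net, OUT / f"{label}.consensus.graphml")
        write_network(net, OUT / f"{label}.consensus.sif", format="sif")
        report = find_patterns(net)
        (OUT / f"{label}.patterns.json").write_text(json.dumps({
            "n_edges": report.n_edges,
            "n_patterns": report.n_patterns,
            "patterns": [sorted(p) for p in report.patterns],
            "singletons": sorted(report.singleton_nodes)}, indent=1))
        line = (f"{label}: {net.n_edges} consensus edges, "
                f"{report.n_patterns} patterns")
        key_path = DATA / f"{label}.answer_key.json"
        if key_path.exists():
            key = json.loads(key_path.read_text())
            truth = {frozenset(e) for e in key["edges"]}
            est = net.skeleton()
            tp = len(truth & est)
            line += (f"; skeleton precision "
                     f"{tp / len(est) if est else 1.0:.2f}, "
                     f"recall {tp / len(truth):.2f}")
        print(line)


if __name__ == "__main__":
    main()
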