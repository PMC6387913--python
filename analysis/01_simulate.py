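#!/usr/bin/env python
"""Generate the synthetic study datasets.

Since the original CD4+ T-cell matrices live in a third-party supplement,
the analysis runs on synthetic stand-ins with a known answer key: one
planted-DAG dataset per splicing class (38 marks, 20 edges, effect 0.9,
n=10^4 — different structures for "included" and "excluded", mimicking the
claim that the two classes carry different mark dependencies) plus the
histone-like preset that reproduces the qualitative correlation geography
(H2BK5me1 cluster, H3K9me3 anticorrelation).

Writes results/data/<label>.matrix.tsv with .answer_key.json sidecars.
"""

import json
from pathlib import Path

from histone_bn.io import write_modification_matrix
from histone_bn.synthetic import build_planted_dag, forward_sample, histone_preset

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(["excluded_exon", "included_exon"]):
        scenario = build_planted_dag(38, 20, 3, 0.9, seed=SEED + i,
                                     n_samples=10_000)
        matrix = forward_sample(scenario)
        write_modification_matrix(matrix, OUT / f"{label}.matrix.tsv")
        key = {"nodes": list(scenario.dag.nodes),
               "edges": sorted(map(list, scenario.dag.edges)),
               "seed": SEED + i}
        (OUT / f"{label}.answer_key.json").write_text(
            json.dumps(key, indent=1, sort_keys=True))
        print(f"{label}: {matrix.n_samples} x {matrix.n_marks}, "
              f"{scenario.dag.n_edges} planted edges")

    preset = histone_preset(10_000, seed=SEED)
    write_modification_matrix(preset, OUT / "histone_preset.matrix.tsv")
    print(f"histone_preset: {preset.n_samples} x {preset.n_marks} "
          f"(catalog marks, latent-activity model)")


if __name__ == "__main__":
    main()
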