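#!/usr/bin/env python
"""Included-vs-excluded network comparison and the outcome-node analysis.

Diffs the two consensus skeletons (class-specific edges mirror the claim
that included and excluded exons carry distinct mark dependency structure),
then learns one consensus over the class-combined matrix with an appended
binary splicing-outcome column and reports the marks directly adjacent to
the outcome node.
"""

import json
from pathlib import Path

import numpy as np

from histone_bn.consensus import consensus_protocol
from histone_bn.io import read_modification_matrix, read_network
from histone_bn.matrix import ModificationMatrix
from histone_bn.netcompare import diff_networks, direct_marks

SEED = 1
DATA = Path("results/data")
NETS = Path("results/networks")
OUT = Path("results/comparison")
OUTCOME = "SPLICING_OUTCOME"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inc = read_network(NETS / "included_exon.consensus.graphml")
    exc = read_network(NETS / "excluded_exon.consensus.graphml")
    diff = diff_networks(inc, exc)
    (OUT / "diff_exon.json").write_text(json.dumps({
        "only_included": sorted(sorted(e) for e in diff.edges_only_in_a),
        "only_excluded": sorted(sorted(e) for e in diff.edges_only_in_b),
        "shared": sorted(sorted(e) for e in diff.shared_edges)}, indent=1))
    print(f"included-only edges: {len(diff.edges_only_in_a)}, "
          f"excluded-only: {len(diff.edges_only_in_b)}, "
          f"shared: {len(diff.shared_edges)}")

    a = read_modification_matrix(DATA / "included_exon.matrix.tsv")
    b = read_modification_matrix(DATA / "excluded_exon.matrix.tsv")
    combined = ModificationMatrix(
        list(a.sample_ids) + [s + "_x" for s in b.sample_ids],
        list(a.mark_names), np.vstack([a.values, b.values]),
        warn_on_zero_rows=False)
    outcome = np.concatenate([np.ones(a.n_samples, dtype=np.uint8),
                              np.zeros(b.n_samples, dtype=np.uint8)])
    combined = combined.with_column(OUTCOME, outcome)
    net, _, _ = consensus_protocol(combined, threshold=7, seed=SEED)
    marks = direct_marks(net, OUTCOME)
    (OUT / "outcome_exon.json").write_text(json.dumps(
        {"outcome_node": OUTCOME, "direct_marks": marks}, indent=1))
    print(f"marks directly adjacent to the splicing outcome: {marks}")


if __name__ == "__main__":
    main()
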