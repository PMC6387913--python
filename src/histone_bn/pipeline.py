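"""One-command orchestration of the full analysis.

For each labelled dataset (either the six real matrices — two splicing
classes by three regions — or synthetic stand-ins) the pipeline computes the
correlation matrix and heatmap, the ten fundamental networks, the consensus
network, and the pattern report; then it diffs the consensus networks of
matched regions between splicing classes and, when both classes of a region
are present, learns an extra consensus over the class-combined matrix with an
appended binary splicing-outcome node and reports the outcome-adjacent marks.

Everything is seeded from one master seed through per-stage derived streams,
and the run manifest records the config, its hash, and a checksum for every
output file, so a rerun with the same config is verifiable byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus import ConsensusNetwork, consensus_protocol
from .correlation import correlation_matrix, heatmap_export
from .io import read_modification_matrix, write_modification_matrix, write_network
from .matrix import ModificationMatrix, Region, SplicingClass
from .netcompare import diff_networks, direct_marks, find_patterns
from .structure import LearnConfig
from .synthetic import build_planted_dag, forward_sample, histone_preset

STUDY_LABELS = tuple(
    f"{cls}_{region}"
    for cls in ("included", "excluded")
    for region in ("exon", "preceding_intron", "succeeding_intron"))

OUTCOME_NODE = "SPLICING_OUTCOME"


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    In ``real`` mode ``inputs`` maps each of the six labels
    ``{included,excluded}_{exon,preceding_intron,succeeding_intron}`` to a
    TSV matrix path. In ``synthetic`` mode matrices are generated: one
    planted-DAG scenario per label (default two labels standing in for the
    two splicing classes of the exon region), or the histone preset.
    """

    output_dir: str | Path = "results/run"
    seed: int = 0
    mode: str = "synthetic"                      # "synthetic" | "real"
    inputs: dict[str, str] = field(default_factory=dict)
    learn: LearnConfig = field(default_factory=LearnConfig)
    threshold: int = 7
    k_folds: int = 10
    n_rounds: int = 1
    heatmaps: bool = True
    outcome_analysis: bool = True
    synthetic: dict = field(default_factory=lambda: {
        "generator": "planted",        # "planted" | "preset"
        "labels": ["excluded_exon", "included_exon"],
        "n_samples": 10_000,
        "n_nodes": 38,
        "n_edges": 20,
        "max_parents": 3,
        "effect_strength": 0.9,
    })

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "learn" in raw and isinstance(raw["learn"], dict):
            raw["learn"] = LearnConfig(**raw["learn"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


def _derived_seed(master: int, *tags: int) -> int:
    ss = np.random.SeedSequence([master, *tags])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _label_region(label: str) -> str:
    for region in ("preceding_intron", "succeeding_intron", "exon"):
        if label.endswith(region):
            return region
    return "exon"


def _label_class(label: str) -> str:
    return "included" if label.startswith("included") else \
        "excluded" if label.startswith("excluded") else "mixed"


def _load_inputs(config: RunConfig, outdir: Path, state) -> dict[str, ModificationMatrix]:
    datasets: dict[str, ModificationMatrix] = {}
    if config.mode == "real":
        missing = [lab for lab in STUDY_LABELS if lab not in config.inputs]
        if missing:
            raise FileNotFoundError(
                f"real-data mode requires all six matrices; missing labels: {missing}")
        unreadable = [lab for lab in STUDY_LABELS
                      if not Path(config.inputs[lab]).is_file()]
        if unreadable:
            raise FileNotFoundError(
                f"input file(s) not found for labels: {unreadable}")
        for lab in STUDY_LABELS:
            datasets[lab] = read_modification_matrix(
                config.inputs[lab], region=_label_region(lab),
                splicing_class=_label_class(lab))
            state(f"loaded:{lab}")
    elif config.mode == "synthetic":
        params = config.synthetic
        labels = list(params.get("labels", ["excluded_exon", "included_exon"]))
        for i, lab in enumerate(sorted(labels)):
            seed_i = _derived_seed(config.seed, 10, i)
            if params.get("generator", "planted") == "preset":
                m = histone_preset(int(params.get("n_samples", 10_000)), seed_i)
            else:
                scenario = build_planted_dag(
                    int(params.get("n_nodes", 38)), int(params.get("n_edges", 20)),
                    int(params.get("max_parents", 3)),
                    float(params.get("effect_strength", 0.9)),
                    seed=seed_i, n_samples=int(params.get("n_samples", 10_000)))
                m = forward_sample(scenario)
                key = {"nodes": list(scenario.dag.nodes),
                       "edges": sorted(map(list, scenario.dag.edges)),
                       "seed": seed_i}
                with (outdir / f"{lab}.answer_key.json").open("w") as fh:
                    json.dump(key, fh, indent=1, sort_keys=True)
            m = ModificationMatrix(m.sample_ids, list(m.mark_names), m.values,
                                   region=_label_region(lab),
                                   splicing_class=_label_class(lab),
                                   warn_on_zero_rows=False)
            write_modification_matrix(m, outdir / f"{lab}.matrix.tsv")
            datasets[lab] = m
            state(f"generated:{lab}")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return datasets


def _consensus_report(net: ConsensusNetwork, plans, config: RunConfig) -> dict:
    return {
        "threshold": net.threshold,
        "n_networks": net.n_networks,
        "n_edges": net.n_edges,
        "edges": [{
            "parent": e.parent, "child": e.child,
            "skeleton_count": e.stability_count,
            "directed_counts": list(e.directed_counts),
            "correlation_sign": e.correlation_sign,
            "correlation_value": e.correlation_value,
            "direction_tie": e.direction_tie,
            "cycle_repaired": e.cycle_repaired,
        } for e in sorted(net.edges, key=lambda e: (e.parent, e.child))],
        "dropped_cycle_edges": sorted(map(list, net.dropped_cycle_edges)),
        "fold_plans": [{"k": p.k, "seed": p.seed,
                        "assignments": list(p.assignments)} for p in plans],
        "learn_config": dataclasses.asdict(config.learn),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state_log = outdir / "state.log"
    state_log.write_text("", encoding="utf-8")

    def state(msg: str) -> None:
        with state_log.open("a", encoding="utf-8") as fh:
            fh.write(msg + "\n")

    datasets = _load_inputs(config, outdir, state)

    consensus: dict[str, ConsensusNetwork] = {}
    for i, (lab, matrix) in enumerate(sorted(datasets.items())):
        cm = correlation_matrix(matrix)
        cm.to_tsv(outdir / f"{lab}.correlation.tsv")
        if config.heatmaps:
            heatmap_export(cm, outdir / f"{lab}.heatmap.png",
                           order="hierarchical")
        net, fundamentals, plans = consensus_protocol(
            matrix, config=config.learn, threshold=config.threshold,
            k=config.k_folds, seed=_derived_seed(config.seed, 20, i),
            n_rounds=config.n_rounds, cm=cm)
        for f_idx, fnet in enumerate(fundamentals):
            write_network(fnet, outdir / f"{lab}.fundamental_{f_idx}.graphml")
        write_network(net, outdir / f"{lab}.consensus.graphml")
        write_network(net, outdir / f"{lab}.consensus.sif", format="sif")
        report = _consensus_report(net, plans, config)
        pattern = find_patterns(net)
        report["patterns"] = {
            "n_patterns": pattern.n_patterns,
            "patterns": [sorted(p) for p in pattern.patterns],
            "singletons": sorted(pattern.singleton_nodes),
        }
        with (outdir / f"{lab}.consensus.json").open("w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        consensus[lab] = net
        state(f"consensus:{lab}")

    # included-vs-excluded diffs per region
    regions = sorted({_label_region(lab) for lab in datasets})
    for region in regions:
        inc = f"included_{region}"
        exc = f"excluded_{region}"
        if inc in consensus and exc in consensus:
            diff = diff_networks(consensus[inc], consensus[exc])
            payload = {
                "a": inc, "b": exc,
                "edges_only_in_a": sorted(sorted(e) for e in diff.edges_only_in_a),
                "edges_only_in_b": sorted(sorted(e) for e in diff.edges_only_in_b),
                "shared_edges": sorted(sorted(e) for e in diff.shared_edges),
                "sign_agreement": {"|".join(sorted(k)): v
                                   for k, v in diff.sign_agreement.items()},
            }
            with (outdir / f"diff_{region}.json").open("w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            state(f"diff:{region}")

    # combined-matrix outcome-node analysis per region
    if config.outcome_analysis:
        for r_idx, region in enumerate(regions):
            inc = f"included_{region}"
            exc = f"excluded_{region}"
            if inc not in datasets or exc not in datasets:
                continue
            a, b = datasets[inc], datasets[exc]
            if list(a.mark_names) != list(b.mark_names):
                continue
            combined = ModificationMatrix(
                list(a.sample_ids) + list(b.sample_ids),
                list(a.mark_names),
                np.vstack([a.values, b.values]),
                region=region, splicing_class=SplicingClass.MIXED,
                warn_on_zero_rows=a.warn_on_zero_rows and b.warn_on_zero_rows)
            outcome = np.concatenate([np.ones(a.n_samples, dtype=np.uint8),
                                      np.zeros(b.n_samples, dtype=np.uint8)])
            combined = combined.with_column(OUTCOME_NODE, outcome)
            net, _, plans = consensus_protocol(
                combined, config=config.learn, threshold=config.threshold,
                k=config.k_folds, seed=_derived_seed(config.seed, 30, r_idx),
                n_rounds=config.n_rounds)
            payload = _consensus_report(net, plans, config)
            payload["outcome_node"] = OUTCOME_NODE
            payload["direct_marks"] = direct_marks(net, OUTCOME_NODE)
            with (outdir / f"outcome_{region}.json").open("w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            state(f"outcome:{region}")

    # hash identifies the analysis settings, not where they were written
    hashed = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    config_json = json.dumps(hashed, sort_keys=True)
    outputs = sorted(p for p in outdir.iterdir()
                     if p.is_file() and p.name not in ("manifest.json", "state.log"))
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    state("done")
    return manifest
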