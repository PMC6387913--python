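"""Readers and writers for modification matrices and learned networks.

Matrices travel as UTF-8 TSV: header row of mark names, first column the exon
identifier, remaining cells 0/1. Networks are written canonically as GraphML
(lossless round-trip) and for convenience as SIF or DOT.

SIF dialect: one line per edge, ``parent <relation> child`` with the relation
being the correlation sign ``+`` / ``-`` (or ``edge`` when no sign is
annotated); isolated nodes appear as single-token lines.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

from .consensus import ConsensusNetwork
from .matrix import (MatrixFormatError, MatrixParseError, ModificationMatrix,
                     Region, SplicingClass)
from .structure import DAGStructure

Network = Union[DAGStructure, ConsensusNetwork]

_FORMATS = ("graphml", "sif", "dot")


def read_modification_matrix(path: str | Path,
                             region: Region | str = Region.EXON,
                             splicing_class: SplicingClass | str = SplicingClass.MIXED,
                             ) -> ModificationMatrix:
    """Read a binary modification matrix from TSV.

    Row and column order are preserved from the file. Region and splicing
    class are supplied by the caller (they are not encoded in the file).

    Raises
    ------
    MatrixFormatError
        Empty file, missing header, or duplicate mark names.
    MatrixParseError
        Any cell that is not exactly ``0`` or ``1``, with its coordinates.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file") from None
        if len(header) < 3:
            raise MatrixFormatError(
                f"{path}: header must list an id column and >=2 marks")
        marks = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != len(header):
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}")
            sample_ids.append(rec[0])
            row = []
            for mark, cell in zip(marks, rec[1:]):
                cell = cell.strip()
                if cell == "0":
                    row.append(0)
                elif cell == "1":
                    row.append(1)
                else:
                    raise MatrixParseError(
                        f"{path}:{lineno}: non-binary cell {cell!r} at row "
                        f"{rec[0]!r}, column {mark!r}")
            rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    return ModificationMatrix(sample_ids, marks,
                              np.array(rows, dtype=np.uint8),
                              region=region, splicing_class=splicing_class)


def write_modification_matrix(matrix: ModificationMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (inverse of :func:`read_modification_matrix`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["exon_id"] + list(matrix.mark_names))
        for sid, row in zip(matrix.sample_ids, matrix.values):
            writer.writerow([sid] + [str(int(v)) for v in row])


def _to_nx(network: Network) -> nx.DiGraph:
    g = nx.DiGraph()
    if isinstance(network, ConsensusNetwork):
        g.add_nodes_from(network.nodes)
        for e in network.edges:
            attrs = {"stability_count": int(e.stability_count),
                     "correlation_sign": e.correlation_sign}
            if e.correlation_value is not None and np.isfinite(e.correlation_value):
                attrs["correlation_value"] = float(e.correlation_value)
            g.add_edge(e.parent, e.child, **attrs)
    elif isinstance(network, DAGStructure):
        g.add_nodes_from(network.nodes)
        g.add_edges_from(network.edges)
    else:
        raise TypeError(f"cannot serialize {type(network).__name__}")
    return g


def write_network(network: Network, path: str | Path,
                  format: str = "graphml") -> None:
    """Serialize a learned or consensus network.

    GraphML is lossless (node set, edge set and edge attributes round-trip);
    SIF and DOT are convenience exports for Cytoscape / Graphviz.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    g = _to_nx(network)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for u, v, attrs in sorted(g.edges(data=True)):
                rel = attrs.get("correlation_sign")
                rel = rel if rel in ("+", "-") else "edge"
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")
    else:  # dot, hand-rolled: graphviz's DOT is line-oriented and trivial
        with path.open("w", encoding="utf-8") as fh:
            fh.write("digraph network {\n")
            for node in sorted(g.nodes):
                fh.write(f'  "{node}";\n')
            for u, v, attrs in sorted(g.edges(data=True)):
                sign = attrs.get("correlation_sign")
                color = {"+": "red", "-": "blue"}.get(sign, "black")
                label = attrs.get("stability_count")
                extra = f', label="{label}/10"' if label is not None else ""
                fh.write(f'  "{u}" -> "{v}" [color={color}{extra}];\n')
            fh.write("}\n")


def read_network(path: str | Path) -> ConsensusNetwork:
    """Read a GraphML network back into a :class:`ConsensusNetwork`.

    Edges lacking stability/sign attributes default to count 10 and
    ``undefined`` sign, so plain DAG exports round-trip as unanimous networks.
    """
    from .consensus import ConsensusEdge
    g = nx.read_graphml(Path(path))
    nodes = sorted(g.nodes)
    edges = []
    for u, v, attrs in g.edges(data=True):
        edges.append(ConsensusEdge(
            parent=u, child=v,
            stability_count=int(attrs.get("stability_count", 10)),
            correlation_sign=str(attrs.get("correlation_sign", "undefined")),
            correlation_value=attrs.get("correlation_value")))
    return ConsensusNetwork(nodes=nodes, edges=edges)
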