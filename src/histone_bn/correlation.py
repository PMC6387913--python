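"""Pairwise Pearson (phi) correlations over binary mark columns.

On 0/1 data the Pearson coefficient reduces to the phi coefficient of the
2x2 contingency table:

    phi = (n11 * n00 - n10 * n01) / sqrt(n1. * n0. * n.1 * n.0)

Constant columns have no defined correlation; they are reported as NaN (an
explicit "undefined" marker, never silently zeroed) together with the list of
offending columns, and downstream consumers decide policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ModificationMatrix

UNDEFINED = float("nan")


@dataclass
class CorrelationMatrix:
    """Symmetric p x p matrix of phi coefficients with NaN for undefined."""

    mark_names: list[str]
    values: np.ndarray
    n_used: int
    constant_marks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.mark_names)
        if self.values.shape != (p, p):
            raise ValueError(f"values shape {self.values.shape} != ({p}, {p})")

    def get(self, a: str, b: str) -> float:
        i = self.mark_names.index(a)
        j = self.mark_names.index(b)
        return float(self.values[i, j])

    def sign(self, a: str, b: str) -> str:
        """"+", "-", or "undefined" (NaN or exact zero)."""
        v = self.get(a, b)
        if math.isnan(v) or v == 0.0:
            return "undefined"
        return "+" if v > 0 else "-"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mark_names,
                            columns=self.mark_names)

    def to_tsv(self, path) -> None:
        """TSV export with marks as header row/column and NA for undefined."""
        self.to_frame().to_csv(path, sep="\t", na_rep="NA",
                               index_label="mark")


def pearson_binary(x, y) -> float:
    """Phi coefficient of two equal-length binary vectors.

    Returns NaN when either vector is constant (the coefficient is undefined:
    a constant column carries no covariance information).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("inputs must be binary (0/1)")
    n1x = int(x.sum())
    n1y = int(y.sum())
    if n1x in (0, n) or n1y in (0, n):
        return UNDEFINED
    n11 = int((x.astype(np.int64) & y.astype(np.int64)).sum())
    n10 = n1x - n11          # x=1, y=0
    n01 = n1y - n11          # x=0, y=1
    n00 = n - n11 - n10 - n01
    num = n11 * n00 - n10 * n01
    den = math.sqrt(float(n1x) * (n - n1x) * n1y * (n - n1y))
    return num / den


def correlation_matrix(matrix: ModificationMatrix) -> CorrelationMatrix:
    """All-pairs phi matrix of a binary modification matrix.

    Each unordered pair is computed once and mirrored; the diagonal is 1 for
    non-constant columns. Rows/columns of constant marks are NaN and the
    marks are listed in ``constant_marks``.
    """
    if matrix.n_marks < 2:
        raise ValueError("need at least two marks")
    v = matrix.values.astype(np.float64)
    n, p = v.shape
    sums = v.sum(axis=0)
    constant = (sums == 0) | (sums == n)
    # vectorised phi: cross products give n11 for every pair at once
    n11 = v.T @ v
    num = n * n11 - np.outer(sums, sums)
    den = np.sqrt(np.outer(sums * (n - sums), sums * (n - sums)))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    values[constant, :] = UNDEFINED
    values[:, constant] = UNDEFINED
    np.fill_diagonal(values, np.where(constant, UNDEFINED, 1.0))
    return CorrelationMatrix(
        mark_names=list(matrix.mark_names),
        values=values,
        n_used=n,
        constant_marks=[m for m, c in zip(matrix.mark_names, constant) if c])


def heatmap_export(cm: CorrelationMatrix, path,
                   order: str = "hierarchical") -> None:
    """Write a clustered correlation heatmap (PNG or SVG by extension).

    ``order="hierarchical"`` applies average-linkage clustering on the
    (1 - r) distance (the block structure of co-occurring marks becomes
    visible); ``order="catalog"`` keeps the input column order. Diverging
    palette centred at zero; undefined cells are left blank.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    if order not in ("catalog", "hierarchical"):
        raise ValueError(f"unknown order {order!r}")
    values = cm.values.copy()
    defined = ~np.all(np.isnan(values), axis=0)
    if not defined.any():
        raise ValueError("correlation matrix is entirely undefined")
    if order == "hierarchical":
        sub = np.where(defined)[0]
        block = values[np.ix_(sub, sub)]
        block = np.nan_to_num(block, nan=0.0)
        dist = 1.0 - block
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # guard float asymmetry
        idx_order = sub[leaves_list(average(squareform(dist, checks=False)))]
        idx_order = np.concatenate([idx_order, np.where(~defined)[0]])
    else:
        idx_order = np.arange(len(cm.mark_names))
    reordered = values[np.ix_(idx_order, idx_order)]
    labels = [cm.mark_names[i] for i in idx_order]

    fig, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(reordered, cmap="RdBu_r", vmin=-1, vmax=1,
                   interpolation="nearest")
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticklabels(labels, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label="phi coefficient")
    fig.tight_layout()
    # strip volatile metadata so identical inputs give identical bytes
    meta = {"Date": None} if str(path).endswith(".svg") else {}
    fig.savefig(path, dpi=150, metadata=meta)
    plt.close(fig)
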