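"""Binary modification matrix: the in-memory container every stage consumes.

Rows are exons (or the matched flanking intronic windows), columns are histone
marks, entries are presence calls in {0, 1}. Region and splicing-class labels
travel with the matrix as metadata.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Region(str, enum.Enum):
    EXON = "exon"
    PRECEDING_INTRON = "preceding_intron"
    SUCCEEDING_INTRON = "succeeding_intron"


class SplicingClass(str, enum.Enum):
    INCLUDED = "included"
    EXCLUDED = "excluded"
    MIXED = "mixed"


class MatrixFormatError(ValueError):
    """Structural problem: duplicate marks, empty file, bad shape."""


class MatrixParseError(ValueError):
    """A cell failed to parse as a binary presence call."""


@dataclass
class ModificationMatrix:
    """n x p binary presence matrix with sample and mark labels.

    Parameters
    ----------
    sample_ids : list of str
        Opaque exon identifiers, one per row.
    mark_names : list of str
        Unique modification names, one per column.
    values : ndarray of shape (n, p)
        Entries must be exactly 0 or 1.
    region : Region
        Which genomic window the calls describe.
    splicing_class : SplicingClass
        Whether the exons are included, excluded, or a mixture.
    """

    sample_ids: list[str]
    mark_names: list[str]
    values: np.ndarray
    region: Region = Region.EXON
    splicing_class: SplicingClass = SplicingClass.MIXED
    #: synthetic samplers legitimately produce all-zero rows; they disable
    #: the upstream-filtering warning
    warn_on_zero_rows: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.region = Region(self.region)
        self.splicing_class = SplicingClass(self.splicing_class)
        self.validate()

    def validate(self) -> None:
        n, p = self.shape
        if n < 1:
            raise MatrixFormatError("matrix must have at least one row")
        if p < 2:
            raise MatrixFormatError("matrix must have at least two marks")
        if len(self.sample_ids) != n:
            raise MatrixFormatError(
                f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.mark_names) != p:
            raise MatrixFormatError(
                f"{len(self.mark_names)} mark names for {p} columns")
        if len(set(self.mark_names)) != p:
            seen: set[str] = set()
            dupes = sorted({m for m in self.mark_names if m in seen or seen.add(m)})
            raise MatrixFormatError(f"duplicate mark names: {dupes}")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise MatrixParseError(
                f"non-binary value {self.values[tuple(bad)]!r} at row "
                f"{self.sample_ids[bad[0]]!r}, column {self.mark_names[bad[1]]!r}")
        self.values = self.values.astype(np.uint8)
        # Upstream processing removed regions with no mark present; an
        # all-zero row is suspicious but legal, so warn exactly once.
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size and self.warn_on_zero_rows:
            ids = [self.sample_ids[i] for i in zero_rows[:5]]
            warnings.warn(
                f"{zero_rows.size} all-zero row(s), first: {ids}",
                UserWarning, stacklevel=2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_marks(self) -> int:
        return self.values.shape[1]

    def column(self, mark: str) -> np.ndarray:
        try:
            j = self.mark_names.index(mark)
        except ValueError:
            raise KeyError(f"unknown mark: {mark!r}") from None
        return self.values[:, j]

    def subset_rows(self, index: np.ndarray) -> "ModificationMatrix":
        """Row subset (boolean mask or integer index), metadata preserved."""
        index = np.asarray(index)
        ids = [self.sample_ids[i] for i in np.arange(self.n_samples)[index]] \
            if index.dtype == bool else [self.sample_ids[i] for i in index]
        return ModificationMatrix(ids, list(self.mark_names),
                                  self.values[index], self.region,
                                  self.splicing_class,
                                  warn_on_zero_rows=self.warn_on_zero_rows)

    def with_column(self, name: str, column: np.ndarray,
                    ) -> "ModificationMatrix":
        """Return a copy with one extra binary column appended."""
        if name in self.mark_names:
            raise MatrixFormatError(f"column {name!r} already present")
        column = np.asarray(column).reshape(-1, 1)
        return ModificationMatrix(
            list(self.sample_ids), list(self.mark_names) + [name],
            np.hstack([self.values, column]), self.region, self.splicing_class,
            warn_on_zero_rows=self.warn_on_zero_rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="exon_id"),
                            columns=self.mark_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModificationMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.mark_names == other.mark_names
                and np.array_equal(self.values, other.values)
                and self.region == other.region
                and self.splicing_class == other.splicing_class)
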