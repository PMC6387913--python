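"""Catalog of the 38 histone modifications profiled in CD4+ T cells.

Twenty methylations and eighteen acetylations; every downstream module that
emulates the real matrices uses these column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

METHYLATIONS: tuple[str, ...] = (
    "H3K27me2", "H3K4me1", "H3K79me2", "H3K9me3", "H4K20me3",
    "H3K27me3", "H3K4me2", "H3K79me3", "H3R2me1", "H4R3me2",
    "H2BK5me1", "H3K36me1", "H3K4me3", "H3K9me1", "H3R2me2",
    "H3K27me1", "H3K36me3", "H3K79me1", "H3K9me2", "H4K20me1",
)

ACETYLATIONS: tuple[str, ...] = (
    "H2AK5ac", "H2BK20ac", "H3K23ac", "H3K9ac", "H4K8ac",
    "H2AK9ac", "H2BK5ac", "H3K27ac", "H4K12ac", "H4K91ac",
    "H2BK120ac", "H3K14ac", "H3K36ac", "H4K16ac", "H2BK12ac",
    "H3K18ac", "H3K4ac", "H4K5ac",
)


@dataclass(frozen=True)
class MarkCatalog:
    """The fixed set of histone-modification names.

    Invariants: 20 methylations, 18 acetylations, 38 unique names in total,
    and every name is exactly one of the two chemistry classes.
    """

    methylations: tuple[str, ...] = METHYLATIONS
    acetylations: tuple[str, ...] = ACETYLATIONS

    def __post_init__(self) -> None:
        if len(set(self.methylations)) != len(self.methylations):
            raise ValueError("duplicate methylation names")
        if len(set(self.acetylations)) != len(self.acetylations):
            raise ValueError("duplicate acetylation names")
        overlap = set(self.methylations) & set(self.acetylations)
        if overlap:
            raise ValueError(f"names in both classes: {sorted(overlap)}")

    @property
    def names(self) -> tuple[str, ...]:
        """All marks, methylations first, in catalog order."""
        return self.methylations + self.acetylations

    def __len__(self) -> int:
        return len(self.methylations) + len(self.acetylations)

    def __contains__(self, name: str) -> bool:
        return name in self.methylations or name in self.acetylations

    def chemistry(self, name: str) -> str:
        if name in self.methylations:
            return "methylation"
        if name in self.acetylations:
            return "acetylation"
        raise KeyError(f"unknown mark: {name!r}")


MARK_CATALOG = MarkCatalog()
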