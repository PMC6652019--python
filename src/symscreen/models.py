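"""Shared domain records used across the screen stages."""
from __future__ import annotations

from dataclasses import dataclass, field


GENE_TABLE_COLUMNS = [
    "gene_id",
    "scaffold",
    "ordinal",
    "start",
    "end",
    "strand",
    "intron_count",
    "protein_length",
    "affinity",
]

#: Affinity classes used for best-match composition summaries.
AFFINITY_CLASSES = ("viral", "prokaryote", "chlorophyte", "other_eukaryote", "no_hit")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene model on a scaffold.

    Coordinates are 1-based inclusive; ``ordinal`` is the 0-based rank of the
    model along its scaffold by start coordinate.
    """

    gene_id: str
    scaffold: str
    ordinal: int
    start: int
    end: int
    strand: str
    intron_count: int = 0
    protein_length: int = 0
    affinity: str = "no_hit"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates for {self.gene_id}: {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class HomologHit:
    """One pairwise alignment record (tabular search output)."""

    query: str
    subject: str
    evalue: float
    similarity: float  # percent, 0-100
    coverage: float  # alignment length / query length

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 100.0:
            raise ValueError(f"similarity out of range: {self.similarity}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be positive: {self.coverage}")


@dataclass
class AnomalousRegion:
    """A detected low-GC interval, 1-based inclusive coordinates."""

    scaffold: str
    start: int
    end: int
    mean_gc: float
    gene_ids: list = field(default_factory=list)
    affinity_fractions: dict = field(default_factory=dict)
    intron_bearing_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
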