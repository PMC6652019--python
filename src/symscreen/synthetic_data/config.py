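"""Configuration objects for the synthetic fixture generators.

A :class:`SimulationConfig` bundles everything needed to emit a complete,
deterministic input set (genome, annotation, counts, predictor calls,
homology tables, alignments) with planted ground truth.  Each simulator draws
from its own RNG stream derived from the master seed so stages can be
regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Fixed stream offsets: one independent RNG lineage per simulator.
GENOME_STREAM = 11
EXPRESSION_STREAM = 12
SECRETION_STREAM = 13
HOMOLOGY_STREAM = 14
ALIGNMENT_STREAM = 15

_DEFAULT_ISLAND_AFFINITY = {
    "viral": 0.35,
    "prokaryote": 0.25,
    "chlorophyte": 0.05,
    "other_eukaryote": 0.05,
    "no_hit": 0.30,
}
_DEFAULT_BACKGROUND_AFFINITY = {
    "viral": 0.02,
    "prokaryote": 0.04,
    "chlorophyte": 0.69,
    "other_eukaryote": 0.10,
    "no_hit": 0.15,
}


def _check_distribution(dist: dict, name: str) -> None:
    if any(v < 0 for v in dist.values()):
        raise ValueError(f"{name}: negative probability")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities sum to {total}, expected 1")


@dataclass
class IslandSpec:
    """A planted low-GC interval terminated by a tandem repeat array."""

    start: int = 1
    length: int = 0
    gc: float = 0.49
    repeat_unit_length: int = 141
    repeat_copies: int = 10
    affinity: dict = field(default_factory=lambda: dict(_DEFAULT_ISLAND_AFFINITY))
    intron_probability: float = 0.08

    @property
    def end(self) -> int:
        """1-based inclusive end; only meaningful when length > 0."""
        return self.start + self.length - 1

    @property
    def array_length(self) -> int:
        return self.repeat_unit_length * self.repeat_copies

    def validate(self, genome_length: int) -> None:
        if self.length < 0:
            raise ValueError("island length must be non-negative")
        if self.length == 0:
            return
        if not 0.0 < self.gc < 1.0:
            raise ValueError("island gc must lie in (0, 1)")
        if self.start < 1:
            raise ValueError("island start must be >= 1")
        if self.repeat_unit_length < 1 or self.repeat_copies < 1:
            raise ValueError("repeat unit length and copies must be positive")
        # The repeat array occupies the final bases of the scaffold; the
        # island must not run into it nor off the scaffold.
        if self.end + self.array_length > genome_length:
            raise ValueError(
                "island overlaps the terminal repeat array or exceeds scaffold"
            )
        _check_distribution(self.affinity, "island affinity")


@dataclass
class ExpressionSpec:
    n_induced: int = 20
    n_repressed: int = 20
    fold_induced: float = 3.0
    fold_repressed: float = 0.33
    dispersion: float = 0.1
    library_size_mono: int = 2_000_000
    library_size_co: int = 2_000_000

    def validate(self) -> None:
        if self.n_induced < 0 or self.n_repressed < 0:
            raise ValueError("planted set sizes must be non-negative")
        if self.fold_induced <= 1.0:
            raise ValueError("fold_induced must exceed 1")
        if not 0.0 < self.fold_repressed < 1.0:
            raise ValueError("fold_repressed must lie in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_mono < 0 or self.library_size_co < 0:
            raise ValueError("library sizes must be non-negative")


@dataclass
class SecretomeSpec:
    n_true_secreted: int = 30
    concordance: float = 1.0
    false_positive_rate: float = 0.02
    background_tm_rate: float = 0.8  # Poisson mean of TM count, non-secreted genes

    def validate(self) -> None:
        if self.n_true_secreted < 0:
            raise ValueError("n_true_secreted must be non-negative")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate must lie in [0, 1]")


@dataclass
class ClusterSpec:
    """Planted clustered homologs for the cluster detector."""

    member_gene_ids: list = field(default_factory=list)
    decoy_gene_ids: list = field(default_factory=list)
    max_gap: int = 6  # intervening-model gap used when planting
    n_queries: int = 2
    n_decoy_hits: int = 20

    def validate(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if set(self.member_gene_ids) & set(self.decoy_gene_ids):
            raise ValueError("decoy genes must not overlap planted members")


@dataclass
class CiliacutSpec:
    """Taxon panel with motility flags plus planted family structure."""

    panel: list = field(
        default_factory=lambda: [
            ["refalga", True],
            ["motile1", True],
            ["motile2", True],
            ["sessile1", False],
            ["sessile2", False],
        ]
    )
    n_motile_only_families: int = 5
    n_universal_families: int = 5
    n_scattered_families: int = 5

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.panel]

    @property
    def motile_taxa(self) -> list[str]:
        return [t for t, m in self.panel if m]

    @property
    def nonmotile_taxa(self) -> list[str]:
        return [t for t, m in self.panel if not m]

    def validate(self) -> None:
        if len(self.panel) < 2:
            raise ValueError("taxon panel needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names in panel")
        for n in (
            self.n_motile_only_families,
            self.n_universal_families,
            self.n_scattered_families,
        ):
            if n < 0:
                raise ValueError("family counts must be non-negative")


@dataclass
class RateSpec:
    n_orthogroups: int = 30
    alignment_length: int = 300
    n_slow: int = 3
    n_fast: int = 3
    slow_multiplier: float = 0.3
    fast_multiplier: float = 3.0
    branch_length: float = 0.2  # expected substitutions per site per branch
    n_triplets: int = 3

    def validate(self) -> None:
        if self.alignment_length < 50:
            raise ValueError("alignment length below test power floor (50)")
        if self.slow_multiplier <= 0 or self.fast_multiplier <= 0:
            raise ValueError("rate multipliers must be positive")
        if self.slow_multiplier >= 1.0 or self.fast_multiplier <= 1.0:
            raise ValueError("expected slow multiplier < 1 < fast multiplier")
        if self.n_slow < 0 or self.n_fast < 0 or self.n_orthogroups < 0:
            raise ValueError("orthogroup counts must be non-negative")
        if self.n_slow + self.n_fast > self.n_orthogroups:
            raise ValueError("planted slow+fast exceed n_orthogroups")
        if self.branch_length < 0:
            raise ValueError("branch length must be non-negative")
        if self.n_triplets < 1:
            raise ValueError("need at least one triplet per orthogroup")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 500_000
    n_genes: int = 400
    background_gc: float = 0.58
    scaffold: str = "scaffold_1"
    background_affinity: dict = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND_AFFINITY)
    )
    background_intron_probability: float = 0.9
    island: IslandSpec = field(default_factory=IslandSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    secretome: SecretomeSpec = field(default_factory=SecretomeSpec)
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    ciliacut: CiliacutSpec = field(default_factory=CiliacutSpec)
    rates: RateSpec = field(default_factory=RateSpec)

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0, 1)")
        _check_distribution(self.background_affinity, "background affinity")
        self.island.validate(self.genome_length)
        self.expression.validate()
        self.secretome.validate()
        self.cluster.validate()
        self.ciliacut.validate()
        self.rates.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key, sub in (
            ("island", IslandSpec),
            ("expression", ExpressionSpec),
            ("secretome", SecretomeSpec),
            ("cluster", ClusterSpec),
            ("ciliacut", CiliacutSpec),
            ("rates", RateSpec),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
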