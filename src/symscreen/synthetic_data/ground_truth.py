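"""Planted ground truth emitted alongside the synthetic fixtures."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class GroundTruth:
    induced_genes: set = field(default_factory=set)
    repressed_genes: set = field(default_factory=set)
    secreted_genes: set = field(default_factory=set)
    island_interval: tuple | None = None  # (start, end), 1-based inclusive
    island_genes: set = field(default_factory=set)
    cluster_members: set = field(default_factory=set)
    motile_only_families: set = field(default_factory=set)
    slow_orthogroups: set = field(default_factory=set)
    fast_orthogroups: set = field(default_factory=set)

    def validate(self, gene_ids: set) -> None:
        """Check planted gene sets against the emitted annotation."""
        for name in (
            "induced_genes",
            "repressed_genes",
            "secreted_genes",
            "island_genes",
            "cluster_members",
        ):
            planted = getattr(self, name)
            missing = planted - gene_ids
            if missing:
                raise ValueError(f"{name} not in annotation: {sorted(missing)[:5]}")
        if self.induced_genes & self.repressed_genes:
            raise ValueError("induced and repressed sets overlap")

    def to_dict(self) -> dict:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, set):
                data[key] = sorted(value)
        if data["island_interval"] is not None:
            data["island_interval"] = list(data["island_interval"])
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        kwargs = dict(data)
        for key, value in kwargs.items():
            if isinstance(value, list) and key != "island_interval":
                kwargs[key] = set(value)
        if kwargs.get("island_interval") is not None:
            kwargs["island_interval"] = tuple(kwargs["island_interval"])
        return cls(**kwargs)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        """Combine truth pieces produced by independent simulators."""
        merged = GroundTruth()
        for key in self.__dataclass_fields__:
            a, b = getattr(self, key), getattr(other, key)
            if isinstance(a, set):
                setattr(merged, key, a | b)
            else:
                setattr(merged, key, b if b is not None else a)
        return merged
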