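"""Three-predictor consensus secretion calls and summary reports."""
from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

DEFAULT_TM_WINDOW = 60


def consensus_secreted(record, n_terminal_window: int = DEFAULT_TM_WINDOW) -> bool:
    """True iff all three predictors agree and the TM profile is compatible.

    Compatible means no TM domain, or exactly one starting within the
    N-terminal window (a signal anchor rather than a true membrane span).
    """
    if not (record["signal_positive"] and record["target_secretory"]):
        return False
    tm_count = int(record["tm_count"])
    if tm_count == 0:
        return True
    if tm_count == 1:
        first = record["tm_first_start"]
        if first is None or (isinstance(first, float) and math.isnan(first)):
            raise ValueError("tm_count >= 1 requires tm_first_start")
        return float(first) <= n_terminal_window
    return False


def call_secretome(
    calls: pd.DataFrame, n_terminal_window: int = DEFAULT_TM_WINDOW
) -> pd.DataFrame:
    """Apply the consensus rule to a predictor-call table."""
    out = calls.copy()
    out["secreted"] = [
        consensus_secreted(row, n_terminal_window)
        for row in calls.to_dict("records")
    ]
    return out


def size_summary(protein_lengths: dict, subsets: dict) -> dict:
    """Arithmetic mean protein length per named subset (None when empty)."""
    unknown = set().union(*subsets.values()) - set(protein_lengths) if subsets else set()
    if unknown:
        raise ValueError(f"subset genes without lengths: {sorted(unknown)[:5]}")
    means = {}
    for name, members in subsets.items():
        if not members:
            means[name] = None
        else:
            means[name] = float(np.mean([protein_lengths[g] for g in members]))
    return means


@dataclass(frozen=True)
class OverlapReport:
    """Contingency counts for the secreted-among-induced comparison."""

    N: int  # genome size
    K: int  # secreted genes genome-wide
    n: int  # induced genes
    k: int  # induced and secreted

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(f"inconsistent contingency counts {self}")

    @property
    def background_percent(self) -> float:
        """100 * K / N rounded to one decimal."""
        return round(100.0 * self.K / self.N, 1)

    @property
    def sample_percent(self) -> float | None:
        """100 * k / n rounded to one decimal (None for empty sample)."""
        if self.n == 0:
            return None
        return round(100.0 * self.k / self.n, 1)


def secretome_overlap(induced: set, secreted: set, genome_size: int) -> OverlapReport:
    if len(induced) > genome_size or len(secreted) > genome_size:
        raise ValueError("subset larger than genome")
    return OverlapReport(
        N=genome_size,
        K=len(secreted),
        n=len(induced),
        k=len(induced & secreted),
    )
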