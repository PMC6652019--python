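"""Predictor-call fixture emulating a three-program secretion screen.

Each planted secreted gene receives three independent positive calls with
probability ``concordance`` (the third being a secretion-compatible TM
annotation); all other genes get independent low-rate false positives and a
background TM-count draw.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SECRETION_STREAM, SecretomeSpec
from .ground_truth import GroundTruth

CALL_COLUMNS = [
    "gene_id",
    "signal_positive",
    "target_secretory",
    "tm_count",
    "tm_first_start",
    "protein_length",
]


@dataclass
class SimulatedSecretion:
    calls: pd.DataFrame
    truth: GroundTruth


def simulate_secretion_calls(
    genes: pd.DataFrame, spec: SecretomeSpec, seed: int
) -> SimulatedSecretion:
    spec.validate()
    n = len(genes)
    if spec.n_true_secreted > n:
        raise ValueError("n_true_secreted exceeds gene count")
    rng = np.random.default_rng([SECRETION_STREAM, seed])

    gene_ids = genes["gene_id"].to_numpy()
    plengths = genes["protein_length"].to_numpy()
    secreted_idx = rng.choice(n, size=spec.n_true_secreted, replace=False)
    is_secreted = np.zeros(n, dtype=bool)
    is_secreted[secreted_idx] = True

    p_pos = np.where(is_secreted, spec.concordance, spec.false_positive_rate)
    signal = rng.random(n) < p_pos
    target = rng.random(n) < p_pos
    tm_ok = rng.random(n) < p_pos  # secreted gene keeps a clean TM profile

    tm_count = np.where(
        is_secreted,
        np.where(tm_ok, 0, 2),
        rng.poisson(spec.background_tm_rate, n),
    )
    # First TM start: uniform over the protein for background genes, forced
    # past any plausible N-terminal window for the discordant secreted cases.
    first = np.full(n, np.nan)
    has_tm = tm_count >= 1
    uniform_start = 1 + rng.integers(0, np.maximum(plengths, 2) - 1, n)
    forced_start = np.maximum(plengths // 2, 101)
    first[has_tm] = np.where(is_secreted, forced_start, uniform_start)[has_tm]

    calls = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "signal_positive": signal,
            "target_secretory": target,
            "tm_count": tm_count,
            "tm_first_start": first,
            "protein_length": plengths,
        },
        columns=CALL_COLUMNS,
    )
    truth = GroundTruth(secreted_genes=set(gene_ids[secreted_idx]))
    return SimulatedSecretion(calls=calls, truth=truth)
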