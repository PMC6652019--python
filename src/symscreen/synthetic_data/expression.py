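"""Read-count fixture with planted coculture induction and repression.

Counts are negative binomial in the mean/dispersion parameterization: the
expected count of a gene is proportional to its length, a lognormal
per-gene baseline and the condition library size, with the planted fold
applied in coculture.  The configured library sizes are reported as the
mapped totals so the expected coculture/monoculture RPKM ratio of a planted
gene equals its fold exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EXPRESSION_STREAM, ExpressionSpec
from .ground_truth import GroundTruth


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame  # gene_id, count_mono, count_co
    library_sizes: dict  # condition -> mapped total
    truth: GroundTruth


def simulate_expression(
    genes: pd.DataFrame, spec: ExpressionSpec, seed: int
) -> SimulatedExpression:
    spec.validate()
    n = len(genes)
    if spec.n_induced + spec.n_repressed > n:
        raise ValueError("planted induced+repressed exceed gene count")
    rng = np.random.default_rng([EXPRESSION_STREAM, seed])

    gene_ids = genes["gene_id"].to_numpy()
    lengths_kb = (genes["end"] - genes["start"] + 1).to_numpy() / 1000.0

    planted = rng.choice(n, size=spec.n_induced + spec.n_repressed, replace=False)
    induced_idx = planted[: spec.n_induced]
    repressed_idx = planted[spec.n_induced :]
    fold = np.ones(n)
    fold[induced_idx] = spec.fold_induced
    fold[repressed_idx] = spec.fold_repressed

    baseline = rng.lognormal(0.0, 1.0, n)
    weight = lengths_kb * baseline
    total_weight = weight.sum()
    mean_mono = spec.library_size_mono * weight / total_weight
    mean_co = spec.library_size_co * weight * fold / total_weight

    counts = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "count_mono": _nb_draw(rng, mean_mono, spec.dispersion),
            "count_co": _nb_draw(rng, mean_co, spec.dispersion),
        }
    )
    truth = GroundTruth(
        induced_genes=set(gene_ids[induced_idx]),
        repressed_genes=set(gene_ids[repressed_idx]),
    )
    return SimulatedExpression(
        counts=counts,
        library_sizes={
            "mono": spec.library_size_mono,
            "co": spec.library_size_co,
        },
        truth=truth,
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with Var = m + dispersion * m^2 (zero mean -> zero)."""
    shape = 1.0 / dispersion
    out = np.zeros(len(mean), dtype=np.int64)
    positive = mean > 0
    if positive.any():
        p = shape / (shape + mean[positive])
        out[positive] = rng.negative_binomial(shape, p)
    return out
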