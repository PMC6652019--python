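"""Genome-level fixture: i.i.d. sequence with a planted low-GC island.

The sequence is generated base by base with a GC probability that switches
inside the island interval; a fixed random tandem unit is stamped over the
scaffold terminus to form the repeat array the joining operation looks for.
No codon or intron sequence structure is modelled: the downstream detector
consumes only windowed base composition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..models import GENE_TABLE_COLUMNS
from .config import GENOME_STREAM, SimulationConfig
from .ground_truth import GroundTruth

_BASES = np.array(["A", "T", "G", "C"])


@dataclass
class SimulatedGenome:
    sequence: str
    genes: pd.DataFrame
    truth: GroundTruth
    repeat_unit: str | None = None
    scaffold: str = "scaffold_1"


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    config.validate()
    rng = np.random.default_rng([GENOME_STREAM, config.seed])
    L = config.genome_length
    island = config.island
    has_island = island.length > 0

    gc_prob = np.full(L, config.background_gc)
    if has_island:
        gc_prob[island.start - 1 : island.end] = island.gc

    is_gc = rng.random(L) < gc_prob
    second = rng.random(L) < 0.5  # G-vs-C / A-vs-T coin
    codes = np.where(is_gc, np.where(second, 2, 3), np.where(second, 0, 1))
    seq = _BASES[codes]

    repeat_unit = None
    if has_island:
        unit_codes = rng.integers(0, 4, island.repeat_unit_length)
        unit = _BASES[unit_codes]
        array = np.tile(unit, island.repeat_copies)
        seq[L - len(array) :] = array
        repeat_unit = "".join(unit)

    genes = _place_genes(config, rng, has_island)
    truth = GroundTruth()
    if has_island:
        truth.island_interval = (island.start, island.end)
        mid = (genes["start"] + genes["end"]) / 2.0
        in_island = (mid >= island.start) & (mid <= island.end)
        truth.island_genes = set(genes.loc[in_island, "gene_id"])
    truth.validate(set(genes["gene_id"]))

    return SimulatedGenome(
        sequence="".join(seq),
        genes=genes,
        truth=truth,
        repeat_unit=repeat_unit,
        scaffold=config.scaffold,
    )


def _place_genes(
    config: SimulationConfig, rng: np.random.Generator, has_island: bool
) -> pd.DataFrame:
    """Place non-overlapping gene models, one per equal-width slot."""
    n = config.n_genes
    if n == 0:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    island = config.island
    slot = config.genome_length // n
    if slot < 10:
        raise ValueError("too many genes for genome length")

    classes = sorted(config.background_affinity)
    bg_probs = np.array([config.background_affinity[c] for c in classes])
    isl_probs = np.array([island.affinity.get(c, 0.0) for c in classes])
    if has_island and isl_probs.sum() > 0:
        isl_probs = isl_probs / isl_probs.sum()

    rows = []
    for i in range(n):
        slot_start = i * slot + 1
        glen = max(int(slot * rng.uniform(0.3, 0.7)), 9)
        start = slot_start + int(rng.integers(0, slot - glen))
        end = start + glen - 1
        mid = (start + end) / 2.0
        in_island = has_island and island.start <= mid <= island.end
        probs = isl_probs if in_island else bg_probs
        affinity = classes[int(rng.choice(len(classes), p=probs))]
        p_intron = (
            island.intron_probability
            if in_island
            else config.background_intron_probability
        )
        intron_count = int(1 + rng.poisson(3)) if rng.random() < p_intron else 0
        protein_length = max(int(rng.lognormal(np.log(400.0), 0.5)), 50)
        rows.append(
            {
                "gene_id": f"g{i:05d}",
                "scaffold": config.scaffold,
                "ordinal": i,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "intron_count": intron_count,
                "protein_length": protein_length,
                "affinity": affinity,
            }
        )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
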