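"""Protein-alignment fixture for the relative-rate screen.

Sequences evolve on a star of independent branches from a common ancestor
under a Poisson replacement process with uniform target residues; the focal
branch length is multiplied by the planted rate factor for slow/fast
orthogroups.  Alignments are gap-free by construction (the tests consume
difference counts only).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALIGNMENT_STREAM, RateSpec
from .ground_truth import GroundTruth

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TRIPLET_COLUMNS = ["orthogroup", "focal", "reference", "outgroup"]


@dataclass
class OrthogroupAlignment:
    orthogroup: str
    sequences: dict  # taxon name -> aligned protein sequence
    multiplier: float


@dataclass
class SimulatedAlignments:
    alignments: list  # of OrthogroupAlignment
    triplets: pd.DataFrame  # orthogroup, focal, reference, outgroup
    truth: GroundTruth


def simulate_alignments(spec: RateSpec, seed: int) -> SimulatedAlignments:
    spec.validate()
    rng = np.random.default_rng([ALIGNMENT_STREAM, seed])
    L = spec.alignment_length

    alignments = []
    triplet_rows = []
    slow_ids, fast_ids = set(), set()
    for i in range(spec.n_orthogroups):
        og = f"og{i:04d}"
        if i < spec.n_slow:
            mult = spec.slow_multiplier
            slow_ids.add(og)
        elif i < spec.n_slow + spec.n_fast:
            mult = spec.fast_multiplier
            fast_ids.add(og)
        else:
            mult = 1.0

        ancestor = rng.integers(0, len(AMINO_ACIDS), L)
        seqs = {"focal": _evolve(ancestor, spec.branch_length * mult, rng)}
        for t in range(spec.n_triplets):
            ref, out = f"ref{t}", f"out{t}"
            seqs[ref] = _evolve(ancestor, spec.branch_length, rng)
            seqs[out] = _evolve(ancestor, spec.branch_length, rng)
            triplet_rows.append(
                {"orthogroup": og, "focal": "focal", "reference": ref, "outgroup": out}
            )
        alignments.append(
            OrthogroupAlignment(
                orthogroup=og,
                sequences={k: "".join(AMINO_ACIDS[v]) for k, v in seqs.items()},
                multiplier=mult,
            )
        )

    truth = GroundTruth(slow_orthogroups=slow_ids, fast_orthogroups=fast_ids)
    return SimulatedAlignments(
        alignments=alignments,
        triplets=pd.DataFrame(triplet_rows, columns=TRIPLET_COLUMNS),
        truth=truth,
    )


def _evolve(
    ancestor: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson number of replacement events, uniform over sites and residues."""
    seq = ancestor.copy()
    n_events = rng.poisson(branch_length * len(ancestor))
    if n_events == 0:
        return seq
    sites = rng.integers(0, len(ancestor), n_events)
    # Replacement by a uniformly chosen *different* residue.
    shifts = rng.integers(1, len(AMINO_ACIDS), n_events)
    for site, shift in zip(sites, shifts):
        seq[site] = (seq[site] + shift) % len(AMINO_ACIDS)
    return seq
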