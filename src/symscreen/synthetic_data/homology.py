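"""Pairwise homology-hit fixture emulating tabular protein search output.

Two planted signals are emitted: (a) families whose members are mutual best
hits across a taxon panel (including families present only in motile taxa),
and (b) a genome-vs-query hit table in which planted cluster member genes
pass the retention filter while decoy hits fail it or carry sub-threshold
e-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HOMOLOGY_STREAM, CiliacutSpec, ClusterSpec
from .ground_truth import GroundTruth

HIT_COLUMNS = ["query", "subject", "evalue", "similarity", "coverage"]


def protein_id(taxon: str, family: str) -> str:
    return f"{taxon}|{family}"


@dataclass
class SimulatedHomology:
    pair_hits: dict  # (query_taxon, subject_taxon) -> hit frame
    cluster_hits: pd.DataFrame
    families: dict  # family id -> set of taxa carrying it
    reference_taxon: str
    truth: GroundTruth = field(default_factory=GroundTruth)


def simulate_homology(
    cluster_spec: ClusterSpec, ciliacut_spec: CiliacutSpec, seed: int
) -> SimulatedHomology:
    cluster_spec.validate()
    ciliacut_spec.validate()
    rng = np.random.default_rng([HOMOLOGY_STREAM, seed])

    taxa = ciliacut_spec.taxa
    motile = set(ciliacut_spec.motile_taxa)
    families: dict[str, set] = {}
    motile_only: set[str] = set()
    idx = 0
    for _ in range(ciliacut_spec.n_universal_families):
        families[f"fam{idx:04d}"] = set(taxa)
        idx += 1
    for _ in range(ciliacut_spec.n_motile_only_families):
        fam = f"fam{idx:04d}"
        families[fam] = set(motile)
        motile_only.add(fam)
        idx += 1
    for _ in range(ciliacut_spec.n_scattered_families):
        # Random presence pattern that never matches the motile-only profile.
        while True:
            present = {t for t in taxa if rng.random() < 0.6}
            if len(present) >= 2 and present != motile:
                break
        families[f"fam{idx:04d}"] = present
        idx += 1

    pair_hits = {}
    fam_ids = sorted(families)
    for qt in taxa:
        for st in taxa:
            if qt == st:
                continue
            rows = []
            for fam in fam_ids:
                present = families[fam]
                if qt in present and st in present:
                    rows.append(
                        {
                            "query": protein_id(qt, fam),
                            "subject": protein_id(st, fam),
                            "evalue": 10.0 ** rng.uniform(-50, -10),
                            "similarity": rng.uniform(60, 95),
                            "coverage": rng.uniform(0.8, 1.2),
                        }
                    )
            # Cross-family decoys, all weaker than the pair threshold 1e-5.
            q_pool = [f for f in fam_ids if qt in families[f]]
            s_pool = [f for f in fam_ids if st in families[f]]
            for _ in range(5):
                if not q_pool or not s_pool:
                    break
                qf = q_pool[int(rng.integers(len(q_pool)))]
                sf = s_pool[int(rng.integers(len(s_pool)))]
                if qf == sf:
                    continue
                rows.append(
                    {
                        "query": protein_id(qt, qf),
                        "subject": protein_id(st, sf),
                        "evalue": 10.0 ** rng.uniform(-4.5, -1),
                        "similarity": rng.uniform(20, 40),
                        "coverage": rng.uniform(0.3, 0.8),
                    }
                )
            pair_hits[(qt, st)] = pd.DataFrame(rows, columns=HIT_COLUMNS)

    cluster_hits = _cluster_hit_table(cluster_spec, rng)
    truth = GroundTruth(
        cluster_members=set(cluster_spec.member_gene_ids),
        motile_only_families=motile_only,
    )
    return SimulatedHomology(
        pair_hits=pair_hits,
        cluster_hits=cluster_hits,
        families=families,
        reference_taxon=taxa[0],
        truth=truth,
    )


def _cluster_hit_table(spec: ClusterSpec, rng: np.random.Generator) -> pd.DataFrame:
    queries = [f"hquery{j}" for j in range(max(spec.n_queries, 1))]
    rows = []
    for gid in spec.member_gene_ids:
        q = queries[int(rng.integers(len(queries)))]
        rows.append(
            {
                "query": q,
                "subject": gid,
                "evalue": 10.0 ** rng.uniform(-40, -10),
                "similarity": rng.uniform(50, 90),
                "coverage": rng.uniform(0.6, 1.4),
            }
        )
    decoys = list(spec.decoy_gene_ids)
    for i in range(min(spec.n_decoy_hits, len(decoys))):
        gid = decoys[i]
        q = queries[int(rng.integers(len(queries)))]
        if rng.random() < 0.5:  # fail the similarity floor
            sim, cov = rng.uniform(10, 44.5), rng.uniform(0.6, 1.4)
        else:  # fail the coverage band
            sim = rng.uniform(50, 90)
            cov = rng.uniform(1.6, 2.5) if rng.random() < 0.5 else rng.uniform(0.05, 0.45)
        rows.append(
            {
                "query": q,
                "subject": gid,
                "evalue": 10.0 ** rng.uniform(-20, -6),
                "similarity": sim,
                "coverage": cov,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
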