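"""Homolog retention filtering and gene-cluster detection.

Hits are retained on inclusive similarity and coverage bounds; retained
homolog genes on the same scaffold chain into clusters by single linkage
whenever at most ``max_intervening`` annotated models separate them.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_MIN_SIMILARITY = 45.0
DEFAULT_COVERAGE = (0.5, 1.5)
DEFAULT_MAX_INTERVENING = 6
DEFAULT_FLANK = 10_000


def filter_homologs(
    hits: pd.DataFrame,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    cov_low: float = DEFAULT_COVERAGE[0],
    cov_high: float = DEFAULT_COVERAGE[1],
) -> pd.DataFrame:
    """Keep hits with similarity >= floor and coverage inside the band."""
    if not 0 < cov_low < cov_high:
        raise ValueError("need 0 < cov_low < cov_high")
    keep = (
        (hits["similarity"] >= min_similarity)
        & (hits["coverage"] >= cov_low)
        & (hits["coverage"] <= cov_high)
    )
    return hits[keep].reset_index(drop=True)


@dataclass
class GeneCluster:
    members: list  # gene ids ordered by genomic position
    scaffold: str
    span: tuple  # (first start, last end), 1-based inclusive
    max_intervening_observed: int

    @property
    def size(self) -> int:
        return len(self.members)


def detect_clusters(
    genes: pd.DataFrame,
    homolog_ids: set,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[GeneCluster]:
    """Single-linkage chaining of homolog genes along annotation ordinals.

    Two genes link when the count of intervening models
    (|ordinal difference| - 1) is at most ``max_intervening``; connected
    runs become clusters and isolated homologs are size-1 clusters.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be non-negative")
    known = set(genes["gene_id"])
    missing = set(homolog_ids) - known
    if missing:
        raise KeyError(f"homolog gene absent from gene table: {sorted(missing)[0]}")

    table = genes[genes["gene_id"].isin(homolog_ids)]
    clusters = []
    for scaffold, group in table.groupby("scaffold", sort=True):
        group = group.sort_values("ordinal", kind="stable")
        current: list[dict] = []
        prev_ordinal = None
        for row in group.to_dict("records"):
            if prev_ordinal is not None and (
                row["ordinal"] - prev_ordinal - 1 > max_intervening
            ):
                clusters.append(_build_cluster(current, scaffold))
                current = []
            current.append(row)
            prev_ordinal = row["ordinal"]
        if current:
            clusters.append(_build_cluster(current, scaffold))
    return clusters


def _build_cluster(rows: list[dict], scaffold: str) -> GeneCluster:
    ordinals = [r["ordinal"] for r in rows]
    gaps = [b - a - 1 for a, b in zip(ordinals, ordinals[1:])]
    return GeneCluster(
        members=[r["gene_id"] for r in rows],
        scaffold=scaffold,
        span=(min(r["start"] for r in rows), max(r["end"] for r in rows)),
        max_intervening_observed=max(gaps) if gaps else 0,
    )


def flank_intervals(
    cluster: GeneCluster,
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK,
    scaffold_length: int | None = None,
) -> dict:
    """Upstream/downstream flanks (clipped to the scaffold) and intra gaps.

    Returns 1-based inclusive intervals: ``upstream``/``downstream`` (None
    when empty) and the list of gaps between consecutive member gene spans.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    first, last = cluster.span
    upstream = None
    if flank_bp > 0 and first > 1:
        upstream = (max(1, first - flank_bp), first - 1)
    downstream = None
    if flank_bp > 0:
        limit = scaffold_length if scaffold_length is not None else last + flank_bp
        if last < limit:
            downstream = (last + 1, min(limit, last + flank_bp))

    table = genes[genes["gene_id"].isin(cluster.members)].sort_values("start")
    gaps = []
    prev_end = None
    for row in table.itertuples(index=False):
        if prev_end is not None and row.start > prev_end + 1:
            gaps.append((prev_end + 1, row.start - 1))
        prev_end = max(prev_end or 0, row.end)
    return {"upstream": upstream, "downstream": downstream, "gaps": gaps}


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": f"cluster{i:03d}",
                "scaffold": c.scaffold,
                "start": c.span[0],
                "end": c.span[1],
                "size": c.size,
                "max_intervening": c.max_intervening_observed,
                "members": ",".join(c.members),
            }
            for i, c in enumerate(clusters)
        ]
    )
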