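"""Reciprocal-best-hit orthology, presence/absence matrices and set reports."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_E_THRESHOLD = 1e-5


def _best_hits(hits: pd.DataFrame, e_threshold: float, strict_ties: bool) -> dict:
    """Per-query best subject below the e-value threshold.

    Best = lowest e-value, ties broken by highest similarity then subject id;
    with ``strict_ties`` an unresolved e-value/similarity tie disqualifies
    the query.
    """
    passing = hits[hits["evalue"] < e_threshold]
    best: dict[str, str] = {}
    for query, group in passing.groupby("query", sort=False):
        ranked = group.sort_values(
            ["evalue", "similarity", "subject"],
            ascending=[True, False, True],
            kind="stable",
        )
        top = ranked.iloc[0]
        if strict_ties and len(ranked) > 1:
            runner = ranked.iloc[1]
            if runner["evalue"] == top["evalue"] and runner["similarity"] == top["similarity"]:
                continue
        best[str(query)] = str(top["subject"])
    return best


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    strict_ties: bool = False,
) -> list[tuple[str, str]]:
    """Pairs (a, b) where each is the other's unique best hit below threshold."""
    best_ab = _best_hits(hits_ab, e_threshold, strict_ties)
    best_ba = _best_hits(hits_ba, e_threshold, strict_ties)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


@dataclass
class PresenceMatrix:
    matrix: pd.DataFrame  # index: reference ids, columns: taxa, bool cells
    motile: dict  # taxon -> bool

    def __post_init__(self) -> None:
        if set(self.matrix.columns) != set(self.motile):
            raise ValueError("matrix columns do not match the declared panel")


def build_presence_matrix(
    reference_ids: list,
    panel: list[tuple[str, bool]],
    rbh_results: dict,
) -> PresenceMatrix:
    """Presence = an RBH pair exists for the reference protein in that taxon.

    ``rbh_results`` maps taxon -> RBH pair list (reference protein, taxon
    protein) from :func:`reciprocal_best_hits`.
    """
    taxa = [t for t, _ in panel]
    missing = [t for t in taxa if t not in rbh_results]
    if missing:
        raise KeyError(f"no RBH results for taxon {missing[0]}")
    data = {}
    for taxon in taxa:
        present = {a for a, _ in rbh_results[taxon]}
        data[taxon] = [ref in present for ref in reference_ids]
    matrix = pd.DataFrame(data, index=list(reference_ids), columns=taxa)
    return PresenceMatrix(matrix=matrix, motile=dict(panel))


def panel_rbh(
    reference_ids: list,
    reference_taxon: str,
    panel: list[tuple[str, bool]],
    pair_hits: dict,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    strict_ties: bool = False,
) -> dict:
    """RBH pair lists for every panel taxon against the reference taxon.

    The reference column is trivially present (identity pairs); other taxa
    are computed from the two directed hit tables in ``pair_hits``.
    """
    results = {}
    for taxon, _ in panel:
        if taxon == reference_taxon:
            results[taxon] = [(r, r) for r in reference_ids]
        else:
            results[taxon] = reciprocal_best_hits(
                pair_hits[(reference_taxon, taxon)],
                pair_hits[(taxon, reference_taxon)],
                e_threshold,
                strict_ties,
            )
    return results


def ciliacut_select(presence: PresenceMatrix) -> list[str]:
    """Rows present in every motile taxon and absent in every non-motile one."""
    motile = [t for t, m in presence.motile.items() if m]
    nonmotile = [t for t, m in presence.motile.items() if not m]
    if not motile or not nonmotile:
        raise ValueError("both motility classes must be non-empty")
    mat = presence.matrix
    keep = mat[motile].all(axis=1) & ~mat[nonmotile].any(axis=1)
    return sorted(mat.index[keep])


def set_overlap_report(set_a: set, set_b: set) -> dict:
    """|A|, |B|, |A∩B| and 100*|A∩B|/|A| to one decimal (None if A empty)."""
    inter = len(set_a & set_b)
    pct = round(100.0 * inter / len(set_a), 1) if set_a else None
    return {
        "size_a": len(set_a),
        "size_b": len(set_b),
        "intersection": inter,
        "percent_of_a": pct,
    }
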