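"""RPKM computation and coculture response classification.

Expression is normalized as reads per kilobase of gene model per million
mapped reads.  A gene's coculture response is classified from its
coculture/monoculture RPKM ratio against organism-specific thresholds,
with threshold values inclusive; a log2-based up/down classifier is also
provided.  Genes below the detection floor in both conditions are reported
as not detected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_INDUCED = "induced"
CLASS_REPRESSED = "repressed"
CLASS_UNCHANGED = "unchanged"
CLASS_NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class ThresholdSet:
    """Ratio thresholds for one organism plus detection settings."""

    induce: float
    repress: float
    log2_cut: float = 0.6
    detection_floor: float = 0.5

    def __post_init__(self) -> None:
        if not self.repress < 1.0 < self.induce:
            raise ValueError("need repress < 1 < induce")
        if self.log2_cut <= 0:
            raise ValueError("log2_cut must be positive")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be non-negative")


FUNGUS_THRESHOLDS = ThresholdSet(induce=2.0, repress=0.5)
ALGA_THRESHOLDS = ThresholdSet(induce=1.3, repress=0.77)

THRESHOLD_PRESETS = {"fungus": FUNGUS_THRESHOLDS, "alga": ALGA_THRESHOLDS}


def compute_rpkm(counts, gene_lengths, mapped_total: float) -> np.ndarray:
    """RPKM = count / (length/1000) / (mapped_total/1e6)."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    bad = np.nonzero(lengths <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive gene length at index {bad[0]}")
    return counts / (lengths / 1000.0) / (mapped_total / 1e6)


def bootstrap_rpkm(
    counts,
    gene_lengths,
    mapped_total: float,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial resampling of the count vector at fixed library total.

    Returns per-gene bootstrap mean RPKM with 2.5/97.5 percentile bounds.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    if total == 0:
        resamples = np.zeros((B, len(counts)), dtype=np.int64)
    else:
        resamples = rng.multinomial(total, counts / total, size=B)
    rpkms = compute_rpkm(resamples, np.asarray(gene_lengths)[None, :], mapped_total)
    lo, hi = np.percentile(rpkms, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "rpkm_mean": rpkms.mean(axis=0),
            "rpkm_lo": lo,
            "rpkm_hi": hi,
        }
    )


def build_expression_table(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: dict,
) -> pd.DataFrame:
    """Assemble the per-gene expression record frame from raw counts.

    ``counts`` must carry gene_id/count_mono/count_co; ``gene_lengths`` maps
    gene_id to model length in bp.
    """
    lengths = counts["gene_id"].map(gene_lengths)
    if lengths.isna().any():
        missing = counts.loc[lengths.isna(), "gene_id"].iloc[0]
        raise ValueError(f"no length for gene {missing}")
    table = counts.copy()
    table["length_bp"] = lengths.astype(int)
    table["rpkm_mono"] = compute_rpkm(
        table["count_mono"], table["length_bp"], library_sizes["mono"]
    )
    table["rpkm_co"] = compute_rpkm(
        table["count_co"], table["length_bp"], library_sizes["co"]
    )
    return table


def classify_differential(
    table: pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """Attach ratio, log2_ratio and class columns; one class per gene.

    A zero monoculture RPKM with detectable coculture expression yields an
    infinite ratio and an induced call.
    """
    out = table.copy()
    mono = out["rpkm_mono"].to_numpy(dtype=float)
    co = out["rpkm_co"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mono > 0, co / mono, np.where(co > 0, np.inf, np.nan))
        log2 = np.log2(ratio)
    out["ratio"] = ratio
    out["log2_ratio"] = log2

    floor = thresholds.detection_floor
    not_detected = (mono < floor) & (co < floor)
    induced = ~not_detected & (ratio >= thresholds.induce)
    repressed = ~not_detected & (ratio <= thresholds.repress)
    cls = np.full(len(out), CLASS_UNCHANGED, dtype=object)
    cls[induced] = CLASS_INDUCED
    cls[repressed] = CLASS_REPRESSED
    cls[not_detected] = CLASS_NOT_DETECTED
    out["class"] = cls
    return out


def classify_log2(table: pd.DataFrame, log2_cut: float = 0.6) -> pd.DataFrame:
    """Strict-inequality log2 classifier: > cut up, < -cut down, else neither."""
    if log2_cut <= 0:
        raise ValueError("log2_cut must be positive")
    out = table.copy()
    if "log2_ratio" not in out.columns:
        if "ratio" not in out.columns:
            mono = out["rpkm_mono"].to_numpy(dtype=float)
            co = out["rpkm_co"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                out["ratio"] = np.where(
                    mono > 0, co / mono, np.where(co > 0, np.inf, np.nan)
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log2_ratio"] = np.log2(out["ratio"].to_numpy(dtype=float))
    log2 = out["log2_ratio"].to_numpy(dtype=float)
    cls = np.full(len(out), "neither", dtype=object)
    cls[log2 > log2_cut] = "up"
    cls[log2 < -log2_cut] = "down"
    out["log2_class"] = cls
    return out


def class_sets(table: pd.DataFrame, column: str = "class") -> dict:
    """Gene-id sets per class label (bookkeeping view of the table)."""
    return {
        label: set(table.loc[table[column] == label, "gene_id"])
        for label in table[column].unique()
    }
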