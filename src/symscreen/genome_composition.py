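"""Windowed GC analysis, low-GC region detection and scaffold joining.

Anomalous regions are maximal runs of sliding windows whose GC falls below a
robust threshold (median minus a scaled-MAD multiple), merged across
single-window gaps and length-filtered.  Scaffolds ending in a shared exact
tandem repeat unit can be joined into one synthetic scaffold with a single
unit copy retained at the junction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AFFINITY_CLASSES, AnomalousRegion

DEFAULT_WINDOW = 5000
DEFAULT_STEP = 1000
DEFAULT_Z = 4.0
_MAD_SCALE = 1.4826  # normal-consistency factor

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GCTrack:
    scaffold: str
    window: int
    step: int
    starts: np.ndarray  # 0-based window starts
    gc: np.ndarray  # fraction, NaN where no unambiguous bases

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        """0-based exclusive window ends."""
        return self.starts + self.window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold": self.scaffold, "start": self.starts, "end": self.ends,
             "gc": self.gc}
        )


def gc_windows(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    scaffold: str = "scaffold",
) -> GCTrack:
    """Per-window GC fraction; ambiguous bases are excluded from both tallies."""
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C"]).astype(np.int64)
    is_acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])

    last_start = len(sequence) - window
    if last_start < 0:
        starts = np.array([], dtype=np.int64)
    else:
        starts = np.arange(0, last_start + 1, step, dtype=np.int64)
    gc_counts = cum_gc[starts + window] - cum_gc[starts]
    ok_counts = cum_ok[starts + window] - cum_ok[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(ok_counts > 0, gc_counts / np.maximum(ok_counts, 1), np.nan)
    return GCTrack(scaffold=scaffold, window=window, step=step, starts=starts, gc=gc)


def detect_low_gc_regions(
    track: GCTrack,
    baseline: tuple[float, float] | None = None,
    min_length: int = 20000,
    z: float = DEFAULT_Z,
) -> list[AnomalousRegion]:
    """Maximal low-GC window runs below median - z * scaled MAD.

    ``baseline`` may supply (median, robust spread) directly; otherwise both
    are estimated from the track.  Runs are merged across gaps of at most one
    window and dropped when spanning less than ``min_length`` bp.
    """
    gc = track.gc
    valid = ~np.isnan(gc)
    if valid.sum() == 0:
        return []
    if baseline is None:
        # Two-pass robust baseline: a large planted region inflates the MAD,
        # so windows below a first-pass threshold are excluded before the
        # final estimate.
        median, spread = _robust_baseline(gc[valid], z)
        low = gc[valid] < median - z * spread
        if low.any() and not low.all():
            median, spread = _robust_baseline(gc[valid][~low], z)
    else:
        median, spread = baseline
    threshold = median - z * spread

    below = valid & (gc < threshold)
    regions = []
    runs = _runs_with_gap(below, max_gap=1)
    for first, last in runs:
        start = int(track.starts[first]) + 1  # to 1-based
        end = int(track.starts[last]) + track.window
        if end - start + 1 < min_length:
            continue
        window_gc = gc[first : last + 1]
        regions.append(
            AnomalousRegion(
                scaffold=track.scaffold,
                start=start,
                end=end,
                mean_gc=float(np.nanmean(window_gc)),
            )
        )
    return regions


def _robust_baseline(values: np.ndarray, z: float) -> tuple[float, float]:
    median = float(np.median(values))
    spread = float(np.median(np.abs(values - median)) * _MAD_SCALE)
    return median, spread


def _runs_with_gap(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal index runs of True values, bridging gaps of <= max_gap False."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    runs = []
    first = last = idx[0]
    for i in idx[1:]:
        if i - last <= max_gap + 1:
            last = i
        else:
            runs.append((first, last))
            first = last = i
    runs.append((first, last))
    return [(int(a), int(b)) for a, b in runs]


@dataclass
class TandemArray:
    unit: str
    copies: int

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies


def find_terminal_array(
    sequence: str,
    terminus: str = "end",
    search_bp: int = 5000,
    min_unit: int = 10,
    min_copies: int = 3,
) -> TandemArray | None:
    """Longest exact tandem unit with >= min_copies at a scaffold terminus."""
    if terminus not in ("start", "end"):
        raise ValueError("terminus must be 'start' or 'end'")
    seq = sequence if terminus == "end" else sequence[::-1]
    tail = seq[-min(search_bp, len(seq)) :]
    # Best = longest total array; ties resolved to the primitive (shortest)
    # unit, so N copies of U beat N/2 copies of UU.
    best = None
    best_span = 0
    for u in range(min_unit, len(tail) // min_copies + 1):
        unit = tail[-u:]
        copies = 1
        while (copies + 1) * u <= len(tail) and tail[-(copies + 1) * u : -copies * u] == unit:
            copies += 1
        if copies >= min_copies and copies * u > best_span:
            best = (unit, copies)
            best_span = copies * u
    if best is None:
        return None
    unit, copies = best
    if terminus == "start":
        unit = unit[::-1]
    return TandemArray(unit=unit, copies=copies)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class ScaffoldJoin:
    """A join of two scaffolds at shared terminal repeat arrays.

    The joined sequence is scaffold A minus its array, one unit copy, then
    the reverse complement of scaffold B minus its array.  ``coordinate_map``
    translates original 1-based positions onto the joined scaffold.
    """

    joined_name: str
    sequence: str
    unit: str
    overlap: int  # bases dropped relative to lenA + lenB
    a_name: str
    b_name: str
    a_span: tuple[int, int]  # joined-coordinate span of scaffold A's trunk
    b_span: tuple[int, int]

    def map_position(self, scaffold: str, position: int) -> int | None:
        """Original 1-based position -> joined 1-based position (None if cut)."""
        if scaffold == self.a_name:
            if position > self.a_span[1]:
                return None
            return position
        if scaffold == self.b_name:
            trunk_len = self.b_span[1] - self.b_span[0] + 1
            if position > trunk_len:
                return None
            return self.b_span[1] - position + 1
        raise KeyError(scaffold)


def terminal_repeat_join(
    scaffold_a: tuple[str, str],
    scaffold_b: tuple[str, str],
    min_unit: int = 10,
    min_copies: int = 3,
    search_bp: int = 5000,
    joined_name: str = "joined_scaffold",
) -> ScaffoldJoin | None:
    """Join two scaffolds whose termini carry the same tandem unit.

    Each scaffold must end in a detectable array; the units must match
    exactly or as reverse complements.  Absence of a join is a value, not an
    error.
    """
    a_name, a_seq = scaffold_a
    b_name, b_seq = scaffold_b
    arr_a = find_terminal_array(a_seq, "end", search_bp, min_unit, min_copies)
    arr_b = find_terminal_array(b_seq, "end", search_bp, min_unit, min_copies)
    if arr_a is None or arr_b is None:
        return None
    if arr_b.unit not in (arr_a.unit, reverse_complement(arr_a.unit)):
        # Allow cyclic rotations of the same unit (arrays are phase-free).
        if len(arr_b.unit) != len(arr_a.unit):
            return None
        doubled = arr_a.unit + arr_a.unit
        rc_doubled = reverse_complement(arr_a.unit) * 2
        if arr_b.unit not in doubled and arr_b.unit not in rc_doubled:
            return None

    a_trunk = a_seq[: len(a_seq) - arr_a.length]
    b_trunk = b_seq[: len(b_seq) - arr_b.length]
    joined = a_trunk + arr_a.unit + reverse_complement(b_trunk)
    overlap = arr_a.length + arr_b.length - len(arr_a.unit)
    return ScaffoldJoin(
        joined_name=joined_name,
        sequence=joined,
        unit=arr_a.unit,
        overlap=overlap,
        a_name=a_name,
        b_name=b_name,
        a_span=(1, len(a_trunk)),
        b_span=(
            len(a_trunk) + len(arr_a.unit) + 1,
            len(a_trunk) + len(arr_a.unit) + len(b_trunk),
        ),
    )


@dataclass
class RegionReport:
    n_genes: int
    counts: dict
    fractions: dict
    intron_bearing_fraction: float | None
    rest_counts: dict
    rest_fractions: dict
    rest_intron_bearing_fraction: float | None

    def fraction_percent(self, affinity: str) -> float | None:
        """Region fraction for one class as a percent, one decimal."""
        value = self.fractions.get(affinity)
        return None if value is None else round(100.0 * value, 1)


def region_gene_report(
    region: AnomalousRegion,
    genes: pd.DataFrame,
    affinity: dict | None = None,
) -> RegionReport:
    """Affinity-class and intron composition of a region vs. the rest.

    Genes belong to the region when their midpoint falls inside it.
    ``affinity`` optionally overrides the gene table's affinity column.
    """
    table = genes[genes["scaffold"] == region.scaffold]
    mid = (table["start"] + table["end"]) / 2.0
    inside = (mid >= region.start) & (mid <= region.end)
    labels = (
        table["gene_id"].map(affinity) if affinity is not None else table["affinity"]
    )
    if affinity is not None and labels.isna().any():
        missing = table.loc[labels.isna(), "gene_id"].iloc[0]
        raise ValueError(f"no affinity label for gene {missing}")

    region.gene_ids = list(table.loc[inside, "gene_id"])
    in_counts, in_frac, in_intron = _composition(table[inside], labels[inside])
    rest = genes.index.isin(table[inside].index)
    rest_table = genes[~rest]
    rest_labels = (
        rest_table["gene_id"].map(affinity)
        if affinity is not None
        else rest_table["affinity"]
    )
    out_counts, out_frac, out_intron = _composition(rest_table, rest_labels)
    region.affinity_fractions = in_frac
    region.intron_bearing_fraction = in_intron
    return RegionReport(
        n_genes=int(inside.sum()),
        counts=in_counts,
        fractions=in_frac,
        intron_bearing_fraction=in_intron,
        rest_counts=out_counts,
        rest_fractions=out_frac,
        rest_intron_bearing_fraction=out_intron,
    )


def _composition(table: pd.DataFrame, labels: pd.Series):
    n = len(table)
    classes = sorted(set(AFFINITY_CLASSES) | set(labels.unique()))
    counts = {c: int((labels == c).sum()) for c in classes}
    if n == 0:
        return counts, {}, None
    fractions = {c: counts[c] / n for c in classes}
    intron_frac = float((table["intron_count"] > 0).mean())
    return counts, fractions, intron_frac
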