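"""Triplet relative-rate tests with consensus and multi-method intersection.

For each (focal, reference, outgroup) triplet the chi-square statistic
(n_focal - n_ref)^2 / (n_focal + n_ref) is computed from the counts of
ungapped columns where exactly one ingroup sequence differs from the other
two, with a one-degree-of-freedom upper-tail p value.  Orthogroup-level
calls require a consensus fraction of same-direction significant triplets,
and final candidates must be called in the same direction by a minimum
number of independent methods.  A bootstrap-supported Poisson-corrected
distance comparison provides the second method.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

DIRECTION_SLOW = "focal_slow"
DIRECTION_FAST = "focal_fast"
DIRECTION_NONE = "none"

CALL_SLOW = "slow"
CALL_FAST = "fast"
CALL_NONE = "none"

_GAP_CHARS = set("-.Xx*?")

DEFAULT_ALPHA = 0.05
DEFAULT_CONSENSUS = 0.9
DEFAULT_MIN_METHODS = 2


@dataclass(frozen=True)
class TripletRateResult:
    orthogroup: str
    triplet: tuple  # (focal, reference, outgroup)
    n_focal: int
    n_ref: int
    statistic: float
    p_value: float
    direction: str


def _clean_columns(focal: str, ref: str, out: str) -> np.ndarray:
    """Indices of columns free of gaps/ambiguity in all three sequences."""
    if not (len(focal) == len(ref) == len(out)):
        raise ValueError("sequences differ in aligned length")
    keep = [
        i
        for i, (a, b, c) in enumerate(zip(focal, ref, out))
        if a not in _GAP_CHARS and b not in _GAP_CHARS and c not in _GAP_CHARS
    ]
    return np.array(keep, dtype=np.int64)


def triplet_rate_test(
    alignment: dict,
    triplet: tuple[str, str, str],
    alpha: float = DEFAULT_ALPHA,
    orthogroup: str = "",
) -> TripletRateResult:
    """Relative-rate chi-square on lineage-private substitution counts."""
    focal_name, ref_name, out_name = triplet
    focal, ref, out = (alignment[n] for n in (focal_name, ref_name, out_name))
    cols = _clean_columns(focal, ref, out)
    if cols.size == 0:
        raise ValueError("no informative (ungapped) columns")

    f = np.frombuffer(focal.encode(), dtype="S1")[cols]
    r = np.frombuffer(ref.encode(), dtype="S1")[cols]
    o = np.frombuffer(out.encode(), dtype="S1")[cols]
    n_focal = int(np.sum((f != r) & (r == o)))
    n_ref = int(np.sum((r != f) & (f == o)))

    total = n_focal + n_ref
    if total == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (n_focal - n_ref) ** 2 / total
        p = float(chi2.sf(statistic, df=1))

    direction = DIRECTION_NONE
    if p <= alpha and n_focal != n_ref:
        direction = DIRECTION_FAST if n_focal > n_ref else DIRECTION_SLOW
    return TripletRateResult(
        orthogroup=orthogroup,
        triplet=triplet,
        n_focal=n_focal,
        n_ref=n_ref,
        statistic=float(statistic),
        p_value=p,
        direction=direction,
    )


def consensus_rate_call(
    results: list[TripletRateResult],
    consensus_fraction: float = DEFAULT_CONSENSUS,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "all-triplets",
) -> str:
    """Orthogroup call from per-triplet directions.

    In ``all-triplets`` mode the fraction of significant same-direction
    triplets over *all* triplets must reach ``consensus_fraction`` and no
    triplet may be significant in the opposite direction.  In
    ``significant-only`` mode the denominator is the significant triplets.
    """
    if not results:
        raise ValueError("need at least one triplet result")
    if mode not in ("all-triplets", "significant-only"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    significant = [r for r in results if r.p_value <= alpha and r.direction != DIRECTION_NONE]
    n_slow = sum(1 for r in significant if r.direction == DIRECTION_SLOW)
    n_fast = sum(1 for r in significant if r.direction == DIRECTION_FAST)
    if n_slow and n_fast:
        return CALL_NONE
    denom = len(results) if mode == "all-triplets" else len(significant)
    if denom == 0:
        return CALL_NONE
    if n_slow / denom >= consensus_fraction:
        return CALL_SLOW
    if n_fast / denom >= consensus_fraction:
        return CALL_FAST
    return CALL_NONE


def multi_method_intersection(
    method_calls: dict,
    min_methods: int = DEFAULT_MIN_METHODS,
) -> dict:
    """Final slow/fast candidate lists requiring same-direction agreement.

    ``method_calls`` maps method name -> {orthogroup -> call}; an orthogroup
    is a final candidate in a direction iff at least ``min_methods`` methods
    call it that way.  Opposite directions never combine.
    """
    if len(method_calls) < min_methods:
        raise ValueError("fewer methods supplied than min_methods")
    orthogroups = set()
    for calls in method_calls.values():
        orthogroups |= set(calls)
    final = {CALL_SLOW: [], CALL_FAST: []}
    for og in sorted(orthogroups):
        votes = [calls.get(og, CALL_NONE) for calls in method_calls.values()]
        for direction in (CALL_SLOW, CALL_FAST):
            if votes.count(direction) >= min_methods:
                final[direction].append(og)
    return final


def distance_rate_method(
    alignment: dict,
    triplet: tuple[str, str, str],
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = 200,
    seed: int = 0,
) -> str:
    """Sign of the Poisson-corrected focal-vs-reference distance difference.

    Distances to the outgroup are d = -ln(1 - p) on triplet-ungapped
    columns; a call is made only when a percentile bootstrap over columns
    (``n_boot`` resamples) excludes zero at level ``alpha``.
    """
    focal_name, ref_name, out_name = triplet
    focal, ref, out = (alignment[n] for n in (focal_name, ref_name, out_name))
    cols = _clean_columns(focal, ref, out)
    if cols.size == 0:
        raise ValueError("no informative (ungapped) columns")
    f = np.frombuffer(focal.encode(), dtype="S1")[cols]
    r = np.frombuffer(ref.encode(), dtype="S1")[cols]
    o = np.frombuffer(out.encode(), dtype="S1")[cols]

    diff_f = (f != o).astype(float)
    diff_r = (r != o).astype(float)
    if diff_f.mean() >= 1.0 or diff_r.mean() >= 1.0:
        warnings.warn("saturated pairwise distance; no call", stacklevel=2)
        return CALL_NONE
    if n_boot < 2:
        return CALL_NONE  # degenerate interval by declaration

    rng = np.random.default_rng(seed)
    m = len(cols)
    idx = rng.integers(0, m, size=(n_boot, m))
    pf = diff_f[idx].mean(axis=1)
    pr = diff_r[idx].mean(axis=1)
    valid = (pf < 1.0) & (pr < 1.0)
    if valid.sum() < 2:
        warnings.warn("bootstrap saturated; no call", stacklevel=2)
        return CALL_NONE
    delta = -np.log1p(-pf[valid]) + np.log1p(-pr[valid])
    lo, hi = np.percentile(delta, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if lo > 0:
        return CALL_FAST
    if hi < 0:
        return CALL_SLOW
    return CALL_NONE


def run_rate_screen(
    alignments: dict,
    triplets: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    consensus_fraction: float = DEFAULT_CONSENSUS,
    min_methods: int = DEFAULT_MIN_METHODS,
    consensus_mode: str = "all-triplets",
    seed: int = 0,
) -> dict:
    """Full screen: both methods per orthogroup, consensus, intersection.

    ``alignments`` maps orthogroup id -> {taxon -> sequence}; ``triplets``
    carries orthogroup/focal/reference/outgroup columns.
    """
    chi_calls: dict[str, str] = {}
    dist_calls: dict[str, str] = {}
    per_triplet = []
    for og, group in triplets.groupby("orthogroup", sort=True):
        aln = alignments[og]
        results = []
        d_calls = []
        for i, row in enumerate(group.itertuples(index=False)):
            trip = (row.focal, row.reference, row.outgroup)
            res = triplet_rate_test(aln, trip, alpha=alpha, orthogroup=og)
            results.append(res)
            per_triplet.append(res)
            d_calls.append(
                distance_rate_method(aln, trip, alpha=alpha, seed=seed + i)
            )
        chi_calls[og] = consensus_rate_call(
            results, consensus_fraction, alpha, mode=consensus_mode
        )
        dist_calls[og] = _direction_consensus(d_calls, consensus_fraction)
    final = multi_method_intersection(
        {"chi_square": chi_calls, "distance": dist_calls}, min_methods
    )
    return {
        "per_triplet": per_triplet,
        "method_calls": {"chi_square": chi_calls, "distance": dist_calls},
        "final": final,
    }


def _direction_consensus(calls: list[str], consensus_fraction: float) -> str:
    """Same consensus rule applied to bare direction calls."""
    n_slow = calls.count(CALL_SLOW)
    n_fast = calls.count(CALL_FAST)
    if n_slow and n_fast:
        return CALL_NONE
    if n_slow / len(calls) >= consensus_fraction:
        return CALL_SLOW
    if n_fast / len(calls) >= consensus_fraction:
        return CALL_FAST
    return CALL_NONE


def results_to_frame(results: list[TripletRateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orthogroup": r.orthogroup,
                "focal": r.triplet[0],
                "reference": r.triplet[1],
                "outgroup": r.triplet[2],
                "n_focal": r.n_focal,
                "n_ref": r.n_ref,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in results
        ]
    )
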