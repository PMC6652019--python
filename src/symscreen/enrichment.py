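"""Hypergeometric subgroup enrichment with a similarity-search background.

The p value is the exact one-sided upper tail P(X >= k), evaluated in log
space from log-gamma binomial coefficients, summing upward from the observed
count with early termination once terms stop contributing at relative
tolerance 1e-16.  Backgrounds are built by uniting a subgroup with every
gene it hits below an e-value threshold, mirroring a genome-wide protein
search with the subgroup as query.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass(frozen=True)
class ContingencySpec:
    N: int  # population size
    K: int  # background successes
    n: int  # sample size
    k: int  # observed successes

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.K, self.n)
            and 0 <= self.K <= self.N
            and 0 <= self.n <= self.N
            # sample cannot hold more failures than the population offers
            and self.n - self.k <= self.N - self.K
        )
        if not ok:
            raise ValueError(f"invalid contingency {self}")


@dataclass(frozen=True)
class SubgroupResult:
    subgroup: str
    spec: ContingencySpec
    enrichment_factor: float | None
    p_value: float


def _log_binom(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf(spec: ContingencySpec, k: int) -> float:
    return (
        _log_binom(spec.K, k)
        + _log_binom(spec.N - spec.K, spec.n - k)
        - _log_binom(spec.N, spec.n)
    )


def hypergeom_pvalue(spec: ContingencySpec) -> float:
    """Exact upper tail P(X >= k), summed in log space from k upward."""
    if not isinstance(spec, ContingencySpec):
        spec = ContingencySpec(*spec)
    if spec.k == 0:
        return 1.0
    k_max = min(spec.K, spec.n)
    log_sum = -math.inf
    for k in range(spec.k, k_max + 1):
        term = _log_pmf(spec, k)
        log_sum = np.logaddexp(log_sum, term)
        # Terms decay monotonically past the mode; stop once negligible.
        if term < log_sum + math.log(1e-16) and k > spec.n * spec.K / max(spec.N, 1):
            break
    return float(min(math.exp(log_sum), 1.0))


def enrichment_factor(spec: ContingencySpec) -> float | None:
    """(k/n) / (K/N); None when undefined (empty sample or background)."""
    if spec.n == 0 or spec.K == 0:
        return None
    return (spec.k / spec.n) / (spec.K / spec.N)


def blast_background(
    subgroup: set, hits: pd.DataFrame, e_threshold: float = 1e-5
) -> set:
    """Subgroup plus every gene any member hits below the e-value threshold."""
    if not subgroup:
        raise ValueError("empty subgroup")
    mask = hits["query"].isin(subgroup) & (hits["evalue"] < e_threshold)
    return set(subgroup) | set(hits.loc[mask, "subject"])


def enrich_subgroups(
    induced: set,
    subgroups: dict,
    backgrounds: dict,
    genome_size: int,
) -> pd.DataFrame:
    """Per-subgroup enrichment among induced genes; rows sorted by p value.

    ``subgroups`` maps name -> member genes (each a subset of the induced
    set); ``backgrounds`` maps name -> background gene set (from
    :func:`blast_background`).
    """
    rows = []
    for name in sorted(subgroups):
        members = subgroups[name]
        if not members <= induced:
            raise ValueError(f"subgroup {name} not contained in induced set")
        background = backgrounds[name]
        if not background:
            raise ValueError(f"empty background for subgroup {name}")
        spec = ContingencySpec(
            N=genome_size, K=len(background), n=len(induced), k=len(members)
        )
        rows.append(
            {
                "subgroup": name,
                "N": spec.N,
                "K": spec.K,
                "n": spec.n,
                "k": spec.k,
                "enrichment_factor": enrichment_factor(spec),
                "p_value": hypergeom_pvalue(spec),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q values (optional column behind a CLI flag)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
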