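"""Rank the candidate populations per measure and fuse the rank lists
with an order-statistics Q statistic.

Each measure yields one rank list per (subtype, direction, dataset):
ascending for the enrichment p-value and the shortest-path length,
descending for GSS and SSS. Ranks become rank ratios r = rank / k (k
candidates ranked); for each candidate the ascending ratio vector
(r_1 <= ... <= r_N) over its N available lists enters

    Q(r_1, ..., r_N) = N! V_N,
    V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_{N-k+1}^i / i!,   V_0 = 1,

the probability that N iid uniform(0,1) order statistics are
componentwise <= the observed ratios; smaller Q means a candidate ranks
jointly higher than chance across the lists. Per-dataset fused ranks are
averaged into the overall rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .datatypes import StemtraceError
from .measures import MeasureValue

logger = logging.getLogger("stemtrace")

#: orientation of each measure: True if smaller values rank first
ASCENDING = {"enrich_p": True, "sp": True, "gss": False, "sss": False}

MEASURES = ("enrich_p", "gss", "sss", "sp")
DIRECTIONS = ("up", "down")


@dataclass
class RankRatioVector:
    """A candidate's rank ratios across the available lists, sorted ascending."""

    subtype: str
    population: str
    ratios: List[float]
    n_lists: int

    def __post_init__(self) -> None:
        if self.n_lists != len(self.ratios):
            raise StemtraceError("n_lists must equal the number of ratios")
        if any(not (0 < r <= 1) for r in self.ratios):
            raise StemtraceError("rank ratios must lie in (0, 1]")
        if list(self.ratios) != sorted(self.ratios):
            raise StemtraceError("ratios must be sorted ascending")


@dataclass
class FusionResult:
    subtype: str
    population: str
    q_value: float
    per_dataset_rank: Dict[str, float] = field(default_factory=dict)
    overall_rank: float = float("nan")


def rank_candidates(
    values: Sequence[MeasureValue], measure: str, direction: str
) -> Dict[str, float]:
    """Rank populations on one measure/direction cell (ties -> average rank).

    NaN values drop their candidate from the list; a list with fewer than
    two non-NaN candidates is dropped entirely (empty map returned).
    """
    if measure not in ASCENDING:
        raise StemtraceError(f"unknown measure {measure!r}")
    rows = [v for v in values if v.measure == measure and v.direction == direction]
    subtypes = {v.subtype for v in rows}
    if len(subtypes) > 1:
        raise StemtraceError("rank_candidates expects values of a single subtype")
    rows = [v for v in rows if not math.isnan(v.value)]
    if len(rows) < 2:
        return {}
    vals = np.array([v.value for v in rows])
    if not ASCENDING[measure]:
        vals = -vals
    ranks = rankdata(vals, method="average")
    return {v.population: float(r) for v, r in zip(rows, ranks)}


def q_statistic(ratios: Sequence[float]) -> float:
    """Order-statistics probability Q = N! V_N for ascending rank ratios.

    Evaluates the recursion V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i}
    r_{N-k+1}^i / i! with V_0 = 1 and clamps the result to [0, 1] to
    absorb floating-point drift in the alternating sum.
    """
    r = list(ratios)
    n = len(r)
    if not (1 <= n <= 20):
        raise StemtraceError("need 1 <= N <= 20 rank ratios")
    if any(not (0 < x <= 1) for x in r):
        raise StemtraceError("rank ratios must lie in (0, 1]")
    if r != sorted(r):
        raise StemtraceError("rank ratios must be sorted ascending")
    v = [1.0] + [0.0] * n
    for k in range(1, n + 1):
        rk = r[n - k]  # r_{N-k+1}, 1-based
        acc = 0.0
        comp = 0.0  # Kahan compensation for long alternating sums
        power = 1.0
        for i in range(1, k + 1):
            power *= rk
            term = ((-1.0) ** (i - 1)) * v[k - i] * power / math.factorial(i)
            y = term - comp
            t = acc + y
            comp = (t - acc) - y
            acc = t
        v[k] = acc
    q = math.factorial(n) * v[n]
    return min(1.0, max(0.0, q))


def _available_lists(
    values: Sequence[MeasureValue], subtype: str
) -> List[Dict[str, float]]:
    rows = [v for v in values if v.subtype == subtype]
    lists = []
    for direction in DIRECTIONS:
        for measure in MEASURES:
            cell = [v for v in rows if v.direction == direction and v.measure == measure]
            ranks = rank_candidates(cell, measure, direction)
            if ranks:
                lists.append(ranks)
    return lists


def fuse_dataset(
    values: Sequence[MeasureValue], subtype: str
) -> Dict[str, Tuple[float, float]]:
    """Fuse one dataset's (<= 8) rank lists for one subtype.

    Returns population -> (q_value, fused rank). A NaN measure removes
    that list for the affected candidate (N shrinks) rather than imputing
    a worst rank; candidates present in no list are excluded with a warning.
    Ties on Q break by (mean ratio, population id), deterministically.
    """
    lists = _available_lists(values, subtype)
    populations = sorted({v.population for v in values if v.subtype == subtype})
    ratio_vectors: Dict[str, RankRatioVector] = {}
    for pop in populations:
        ratios = [lst[pop] / len(lst) for lst in lists if pop in lst]
        if not ratios:
            logger.warning("subtype %s: population %s in no rank list, excluded", subtype, pop)
            continue
        ratio_vectors[pop] = RankRatioVector(
            subtype=subtype, population=pop, ratios=sorted(ratios), n_lists=len(ratios)
        )
    qs = {pop: q_statistic(rv.ratios) for pop, rv in ratio_vectors.items()}
    order = sorted(
        qs,
        key=lambda p: (qs[p], float(np.mean(ratio_vectors[p].ratios)), p),
    )
    out: Dict[str, Tuple[float, float]] = {}
    for rank, pop in enumerate(order, 1):
        out[pop] = (qs[pop], float(rank))
    return out


def overall_rank(per_dataset: Sequence[Mapping[str, float]]) -> Dict[str, float]:
    """Arithmetic mean of per-dataset fused ranks per population.

    A population missing from some datasets is averaged over the datasets
    where it is present (flagged in the log); a single dataset passes
    through unchanged.
    """
    if not per_dataset:
        raise StemtraceError("need >= 1 dataset rank map")
    populations = sorted({p for ranks in per_dataset for p in ranks})
    out: Dict[str, float] = {}
    for pop in populations:
        present = [ranks[pop] for ranks in per_dataset if pop in ranks]
        if len(present) < len(per_dataset):
            logger.warning(
                "population %s present in %d/%d datasets; mean over those",
                pop,
                len(present),
                len(per_dataset),
            )
        out[pop] = float(np.mean(present))
    return out


def fuse_all(
    values_per_dataset: Mapping[str, Sequence[MeasureValue]],
) -> List[FusionResult]:
    """Fuse every subtype across datasets and compute overall ranks.

    ``values_per_dataset`` maps dataset label -> MeasureValue rows. A
    subtype absent from a dataset (single-series subtypes) contributes
    ranks only where measured.
    """
    subtypes = sorted(
        {v.subtype for rows in values_per_dataset.values() for v in rows}
    )
    results: List[FusionResult] = []
    for subtype in subtypes:
        per_ds_ranks: Dict[str, Dict[str, float]] = {}
        per_ds_q: Dict[str, Dict[str, float]] = {}
        for ds, rows in values_per_dataset.items():
            if not any(v.subtype == subtype for v in rows):
                continue
            fused = fuse_dataset(list(rows), subtype)
            per_ds_ranks[ds] = {p: r for p, (q, r) in fused.items()}
            per_ds_q[ds] = {p: q for p, (q, r) in fused.items()}
        overall = overall_rank(list(per_ds_ranks.values()))
        for pop, orank in overall.items():
            results.append(
                FusionResult(
                    subtype=subtype,
                    population=pop,
                    q_value=float(
                        np.mean([per_ds_q[ds][pop] for ds in per_ds_q if pop in per_ds_q[ds]])
                    ),
                    per_dataset_rank={
                        ds: per_ds_ranks[ds][pop] for ds in per_ds_ranks if pop in per_ds_ranks[ds]
                    },
                    overall_rank=orank,
                )
            )
    return results
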