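"""Differential expression and signature calling.

A signature gene passes a two-sided two-sample t test at ``p_threshold``
(default 0.05) together with a fold-change gate (default 2-fold, i.e.
|log2FC| > 1). Fold change is the difference of group means on the log2
scale. Population signatures come from one-vs-rest contrasts on a normal
expression matrix; stem-cell (CSC) signatures from CSC vs non-CSC
contrasts per subtype; the origin-specific signature is the direction-
consistent intersection of CSC-vs-origin differentials across datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .datatypes import AnalysisConfig, ExpressionMatrix, SignatureSet, StemtraceError

logger = logging.getLogger("stemtrace")


@dataclass
class DifferentialResult:
    """Per-gene outcome of a two-group contrast (A vs B) on log2 data."""

    gene: str
    mean_a: float
    mean_b: float
    log2fc: float  # mean_a - mean_b
    pvalue: float
    call: str  # "up" | "down" | "none"


def _ttest_calls(
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_ids: Sequence[str],
    config: AnalysisConfig,
) -> List[DifferentialResult]:
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise StemtraceError("each group needs >= 2 samples for a t test")
    mean_a = values_a.mean(axis=1)
    mean_b = values_b.mean(axis=1)
    log2fc = mean_a - mean_b
    equal_var = config.ttest == "pooled"
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes are expected degenerate inputs, resolved below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(values_a, values_b, axis=1, equal_var=equal_var)
    # zero variance in both groups: identical constants -> p = 1, no call
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    thr = config.log2fc_threshold
    out: List[DifferentialResult] = []
    for i, gene in enumerate(gene_ids):
        p = float(pvals[i])
        fc = float(log2fc[i])
        if p < config.p_threshold and fc > thr:
            call = "up"
        elif p < config.p_threshold and fc < -thr:
            call = "down"
        else:
            call = "none"
        out.append(
            DifferentialResult(
                gene=gene,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=fc,
                pvalue=p,
                call=call,
            )
        )
    return out


def differential(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    config: AnalysisConfig,
) -> List[DifferentialResult]:
    """Two-sided t test plus fold-change gate for group_a vs group_b."""
    cols_a = expr.columns_of(group_a)
    cols_b = expr.columns_of(group_b)
    if cols_a.size == 0:
        raise StemtraceError(f"group {group_a!r} not in matrix")
    if cols_b.size == 0:
        raise StemtraceError(f"group {group_b!r} not in matrix")
    return _ttest_calls(expr.values[:, cols_a], expr.values[:, cols_b], expr.gene_ids, config)


def cross_matrix_differential(
    expr_a: ExpressionMatrix,
    group_a: str,
    expr_b: ExpressionMatrix,
    group_b: str,
    config: AnalysisConfig,
    standardize: bool = False,
) -> List[DifferentialResult]:
    """Contrast a group of one matrix against a group of another.

    Used for the CSC-vs-candidate-origin contrast that feeds the
    origin-specific signature, where the two groups live in different
    expression series. Restricted to genes present in both matrices.
    With ``standardize`` each matrix is gene-wise centered and scaled
    (over all its samples) before the test, as a crude cross-series
    normalization.
    """
    common = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    if not common:
        raise StemtraceError("no genes shared between the two matrices")
    ia = [expr_a.gene_index(g) for g in common]
    ib = [expr_b.gene_index(g) for g in common]
    va = expr_a.values[ia][:, expr_a.columns_of(group_a)]
    vb = expr_b.values[ib][:, expr_b.columns_of(group_b)]
    if va.shape[1] == 0:
        raise StemtraceError(f"group {group_a!r} not in first matrix")
    if vb.shape[1] == 0:
        raise StemtraceError(f"group {group_b!r} not in second matrix")
    if standardize:
        def _std(full: np.ndarray, sub: np.ndarray) -> np.ndarray:
            mu = full.mean(axis=1, keepdims=True)
            sd = full.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            return (sub - mu) / sd

        fa = expr_a.values[ia]
        fb = expr_b.values[ib]
        va = _std(fa, va)
        vb = _std(fb, vb)
    return _ttest_calls(va, vb, common, config)


def _to_signatures(
    label: str, diffs: Sequence[DifferentialResult]
) -> Tuple[SignatureSet, SignatureSet]:
    up = [d for d in diffs if d.call == "up"]
    down = [d for d in diffs if d.call == "down"]

    def build(items: Sequence[DifferentialResult], direction: str) -> SignatureSet:
        return SignatureSet(
            label=f"{label}.{direction}",
            genes=[d.gene for d in items],
            log2fc={d.gene: d.log2fc for d in items},
            pvalue={d.gene: max(d.pvalue, np.nextafter(0, 1)) for d in items},
            direction=direction,
        )

    return build(up, "up"), build(down, "down")


def call_population_signatures(
    expr: ExpressionMatrix, config: AnalysisConfig
) -> Dict[str, Tuple[SignatureSet, SignatureSet]]:
    """One-vs-rest over/under signatures for every population group."""
    populations = expr.group_labels()
    if len(populations) < 2:
        raise StemtraceError("need >= 2 populations for one-vs-rest contrasts")
    out: Dict[str, Tuple[SignatureSet, SignatureSet]] = {}
    for pop in populations:
        cols_in = expr.columns_of(pop)
        cols_out = np.array(
            [j for j, s in enumerate(expr.sample_ids) if expr.groups[s] != pop], dtype=int
        )
        diffs = _ttest_calls(
            expr.values[:, cols_in], expr.values[:, cols_out], expr.gene_ids, config
        )
        over, under = _to_signatures(pop, diffs)
        over.label = f"{pop}.over"
        under.label = f"{pop}.under"
        out[pop] = (over, under)
    return out


def call_csc_signatures(
    expr: ExpressionMatrix, subtype: str, config: AnalysisConfig
) -> Tuple[SignatureSet, SignatureSet]:
    """Up/down signature of one subtype's CSC vs non-CSC contrast."""
    group_csc = f"{subtype}.CSC"
    group_non = f"{subtype}.nonCSC"
    labels = set(expr.groups.values())
    if group_csc not in labels or group_non not in labels:
        raise StemtraceError(f"matrix lacks groups {group_csc!r}/{group_non!r}")
    diffs = differential(expr, group_csc, group_non, config)
    return _to_signatures(subtype, diffs)


def origin_specific_signature(
    diffs_per_dataset: Sequence[Sequence[DifferentialResult]],
) -> Tuple[Set[str], Set[str]]:
    """Direction-consistent intersection of differential calls across datasets.

    A gene enters the up (down) set only if it is called up (down) in every
    dataset; genes with conflicting calls are excluded.
    """
    if not diffs_per_dataset:
        raise StemtraceError("need differential results from >= 1 dataset")
    up_sets = [set(d.gene for d in diffs if d.call == "up") for diffs in diffs_per_dataset]
    down_sets = [set(d.gene for d in diffs if d.call == "down") for diffs in diffs_per_dataset]
    up = set.intersection(*up_sets)
    down = set.intersection(*down_sets)
    return up - down, down - up
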