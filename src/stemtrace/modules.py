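"""Condition-specific co-expression module detection on an interaction
network.

Edges of the functional-interaction network are weighted by the Pearson
correlation of their endpoint genes across one condition's samples;
weighted-modularity community detection (Louvain, fixed seed) on the
affinely mapped weights (w+1)/2 partitions the nodes into modules.
Modules smaller than ``module_min_size`` or with a mean internal edge
correlation below ``module_min_avg_pcc`` (default 0.5) are removed;
surviving modules are tested for enrichment of the origin-specific
signature (hypergeometric, p < 0.05) and paired across conditions by
shared signature genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .datatypes import (
    AnalysisConfig,
    ExpressionMatrix,
    InteractionNetwork,
    StemtraceError,
    edge,
)
from .measures import overlap_pvalue

logger = logging.getLogger("stemtrace")


@dataclass
class GeneModule:
    module_id: str
    condition: str
    genes: Set[str]
    avg_pcc: float
    enrichment_p: float = float("nan")
    significant: bool = False
    shared_genes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise StemtraceError("module needs >= 2 genes")


def pcc_weight_edges(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    condition_samples: Iterable[str],
) -> InteractionNetwork:
    """Weight each edge by the Pearson correlation of its endpoints.

    Correlations are computed over the condition's samples on the log2
    values. Edges with an endpoint absent from the matrix are dropped
    (logged); a zero-variance endpoint gives weight 0 with a warning.
    """
    samples = list(condition_samples)
    if len(samples) < 3:
        raise StemtraceError("need >= 3 condition samples for correlations")
    cols = np.array([expr.sample_index(s) for s in samples], dtype=int)
    measured = set(expr.gene_ids)
    sub = expr.values[:, cols]
    mu = sub.mean(axis=1, keepdims=True)
    centered = sub - mu
    norms = np.sqrt((centered**2).sum(axis=1))
    weight: Dict[frozenset, float] = {}
    kept: Set[frozenset] = set()
    n_dropped = 0
    n_zero_var = 0
    for e in net.edges:
        a, b = sorted(e)
        if a not in measured or b not in measured:
            n_dropped += 1
            continue
        ia, ib = expr.gene_index(a), expr.gene_index(b)
        if norms[ia] == 0 or norms[ib] == 0:
            n_zero_var += 1
            w = 0.0
        else:
            w = float(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]))
        kept.add(e)
        weight[e] = w
    if n_dropped:
        logger.info("dropped %d edge(s) with unmeasured endpoints", n_dropped)
    if n_zero_var:
        logger.warning("%d edge(s) with a zero-variance endpoint got weight 0", n_zero_var)
    nodes = {n for e in kept for n in e}
    return InteractionNetwork(nodes=nodes, edges=kept, weight=weight)


def module_avg_pcc(genes: Set[str], weighted_net: InteractionNetwork) -> float:
    """Mean signed correlation over the module's internal edges."""
    internal = [
        weighted_net.weight[e]
        for e in weighted_net.edges
        if e <= genes and weighted_net.weight is not None and e in weighted_net.weight
    ]
    if not internal:
        return float("nan")
    return float(np.mean(internal))


def detect_modules(
    weighted_net: InteractionNetwork,
    seed: int,
    condition: str = "condition",
    resolution: float = 1.0,
    use_weights: bool = False,
) -> List[GeneModule]:
    """Partition the network into modules by Louvain communities.

    By default the partition is driven by topology alone and the
    condition's correlations enter only through the reported ``avg_pcc``
    (and hence the downstream coherence filter): with few samples per
    condition the edge correlations are noisy estimates, and optimizing
    modularity on them selects for sampling noise, which biases the
    post-hoc average-correlation filter upward on null modules. With
    ``use_weights`` the signed correlations are mapped to [0, 1] via
    (w+1)/2 and drive the modularity objective instead. ``resolution``
    sets the community scale (larger values give smaller modules).
    Singleton communities are discarded; deterministic for a fixed seed.
    """
    if weighted_net.n_nodes == 0:
        return []
    g = nx.Graph()
    g.add_nodes_from(sorted(weighted_net.nodes))
    for e in weighted_net.edges:
        a, b = sorted(e)
        w = weighted_net.weight[e] if weighted_net.weight else 1.0
        g.add_edge(a, b, weight=(w + 1.0) / 2.0 if use_weights else 1.0)
    communities = nx.community.louvain_communities(
        g, weight="weight", seed=seed, resolution=resolution
    )
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    modules: List[GeneModule] = []
    for i, genes in enumerate(communities, 1):
        if len(genes) < 2:
            continue
        gene_set = set(genes)
        modules.append(
            GeneModule(
                module_id=f"{condition}.m{i}",
                condition=condition,
                genes=gene_set,
                avg_pcc=module_avg_pcc(gene_set, weighted_net),
            )
        )
    return modules


def filter_modules(modules: Sequence[GeneModule], config: AnalysisConfig) -> List[GeneModule]:
    """Keep modules with >= module_min_size genes and avg PCC >= the cutoff."""
    kept = [
        m
        for m in modules
        if len(m.genes) >= config.module_min_size
        and not np.isnan(m.avg_pcc)
        and m.avg_pcc >= config.module_min_avg_pcc
    ]
    logger.info("module filter kept %d/%d modules", len(kept), len(modules))
    return kept


def enrich_modules(
    modules: Sequence[GeneModule],
    signature: Set[str],
    universe: Set[str],
    p_threshold: float = 0.05,
) -> List[GeneModule]:
    """Hypergeometric enrichment of the origin-specific signature per module."""
    sig = signature & universe
    for m in modules:
        m.enrichment_p = overlap_pvalue(m.genes & universe, sig, universe)
        m.significant = m.enrichment_p < p_threshold
    return list(modules)


def shared_module_pairs(
    modules_a: Sequence[GeneModule],
    modules_b: Sequence[GeneModule],
    signature: Set[str],
) -> List[Tuple[GeneModule, GeneModule, Set[str]]]:
    """Cross-condition module pairs sharing origin-specific signature genes.

    Returns pairs whose gene sets overlap each other and the signature,
    sorted by shared-gene count descending, then module ids.
    """
    pairs: List[Tuple[GeneModule, GeneModule, Set[str]]] = []
    for ma in modules_a:
        for mb in modules_b:
            shared = ma.genes & mb.genes & signature
            if shared:
                ma.shared_genes |= shared
                mb.shared_genes |= shared
                pairs.append((ma, mb, shared))
    pairs.sort(key=lambda t: (-len(t[2]), t[0].module_id, t[1].module_id))
    return pairs
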