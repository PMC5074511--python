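"""Core data model shared by every pipeline stage.

The containers are deliberately thin: an expression matrix with sample
grouping, directional gene signatures carrying per-gene effect sizes,
an undirected interaction network, an ontology with gene annotations,
position count matrices, and the analysis configuration. Each validates
its own invariants on construction so downstream stages can assume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np


class StemtraceError(ValueError):
    """Raised on contract violations in inputs or intermediate data."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with sample group labels."""

    gene_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise StemtraceError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StemtraceError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StemtraceError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise StemtraceError(f"samples without group label: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise StemtraceError("non-finite expression values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def group_labels(self) -> List[str]:
        """Distinct group labels in first-appearance order over samples."""
        seen: List[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> List[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def columns_of(self, group: str) -> np.ndarray:
        cols = [self._sample_index[s] for s in self.samples_of(group)]
        return np.asarray(cols, dtype=int)


@dataclass
class SignatureSet:
    """A directional gene signature with per-gene log2 fold change and p-value.

    ``direction`` is "up" for genes higher in the focal group (log2fc > 0)
    and "down" for genes lower (log2fc < 0).
    """

    label: str
    genes: List[str]
    log2fc: Dict[str, float]
    pvalue: Dict[str, float]
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise StemtraceError(f"bad direction {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise StemtraceError("duplicate genes in signature")
        for g in self.genes:
            if g not in self.log2fc or g not in self.pvalue:
                raise StemtraceError(f"gene {g} missing log2fc or pvalue")
            fc = self.log2fc[g]
            p = self.pvalue[g]
            if self.direction == "up" and not fc > 0:
                raise StemtraceError(f"up-signature gene {g} has log2fc {fc} <= 0")
            if self.direction == "down" and not fc < 0:
                raise StemtraceError(f"down-signature gene {g} has log2fc {fc} >= 0")
            if not (0.0 < p <= 1.0):
                raise StemtraceError(f"gene {g} p-value {p} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_set(self) -> Set[str]:
        return set(self.genes)


@dataclass
class InteractionNetwork:
    """Undirected gene interaction graph with optional edge weights."""

    nodes: Set[str]
    edges: Set[FrozenSet[str]]
    weight: Optional[Dict[FrozenSet[str], float]] = None

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise StemtraceError(f"self-loop or malformed edge {set(e)}")
            if not e <= self.nodes:
                raise StemtraceError(f"edge {set(e)} references unknown node")
        if self.weight is not None:
            for e, w in self.weight.items():
                if not math.isfinite(w):
                    raise StemtraceError(f"non-finite weight on edge {set(e)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            a, b = sorted(e)
            if self.weight is not None and e in self.weight:
                g.add_edge(a, b, weight=self.weight[e])
            else:
                g.add_edge(a, b)
        return g


@dataclass
class OntologyAnnotation:
    """An is_a DAG of terms plus gene->term annotations and term IC values.

    ``parents`` maps each non-root term to its direct is_a parents; every
    path must reach ``root``. ``ic`` is filled by ``compute_ic`` and is 0 at
    the root, non-decreasing child-ward.
    """

    terms: Set[str]
    parents: Dict[str, Set[str]]
    root: str
    gene2terms: Dict[str, Set[str]]
    ic: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root not in self.terms:
            raise StemtraceError("root not among terms")
        for t, ps in self.parents.items():
            if t not in self.terms:
                raise StemtraceError(f"parent entry for unknown term {t}")
            for p in ps:
                if p not in self.terms:
                    raise StemtraceError(f"unknown parent {p} of {t}")
        self._check_acyclic_rooted()

    def _check_acyclic_rooted(self) -> None:
        state: Dict[str, int] = {}

        def visit(t: str) -> None:
            if state.get(t) == 1:
                raise StemtraceError(f"cycle through term {t}")
            if state.get(t) == 2:
                return
            state[t] = 1
            for p in self.parents.get(t, ()):  # walk child -> parent
                visit(p)
            state[t] = 2

        for t in self.terms:
            visit(t)
        # every term must reach root
        for t in self.terms:
            if t == self.root:
                continue
            frontier = {t}
            seen: Set[str] = set()
            while frontier:
                cur = frontier.pop()
                if cur == self.root:
                    break
                seen.add(cur)
                frontier |= self.parents.get(cur, set()) - seen
            else:
                raise StemtraceError(f"term {t} does not reach root")

    def ancestors(self, term: str) -> Set[str]:
        """All ancestors of ``term`` including itself."""
        out: Set[str] = set()
        frontier = {term}
        while frontier:
            cur = frontier.pop()
            if cur in out:
                continue
            out.add(cur)
            frontier |= self.parents.get(cur, set())
        return out


@dataclass
class PWMRecord:
    """A position count matrix over {A, C, G, T}."""

    name: str
    counts: np.ndarray  # shape (4, L)
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise StemtraceError("counts must be 4 x L")
        if self.counts.shape[1] < 5:
            raise StemtraceError(f"matrix {self.name}: length {self.counts.shape[1]} < 5")
        if np.any(self.counts < 0):
            raise StemtraceError(f"matrix {self.name}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise StemtraceError(f"matrix {self.name}: all-zero position")
        if self.pseudocount < 0:
            raise StemtraceError("negative pseudocount")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class AnalysisConfig:
    """Tunable thresholds for every pipeline stage."""

    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    module_min_size: int = 7
    module_min_avg_pcc: float = 0.5
    module_resolution: float = 4.0
    module_use_weights: bool = False
    promoter_length: int = 2000
    css_cutoff: float = 1.0
    mss_cutoffs: Dict[str, float] = field(default_factory=dict)
    default_mss_cutoff: float = 0.95
    ttest: str = "welch"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise StemtraceError("p_threshold must be in (0, 1]")
        if self.fc_threshold <= 1:
            raise StemtraceError("fc_threshold must exceed 1")
        if self.module_min_size < 2:
            raise StemtraceError("module_min_size must be >= 2")
        if self.promoter_length <= 0:
            raise StemtraceError("promoter_length must be positive")
        if not (0 <= self.css_cutoff <= 1):
            raise StemtraceError("css_cutoff must be in [0, 1]")
        if self.ttest not in ("welch", "pooled"):
            raise StemtraceError("ttest must be 'welch' or 'pooled'")

    @property
    def log2fc_threshold(self) -> float:
        return math.log2(self.fc_threshold)


Edge = FrozenSet[str]


def edge(a: str, b: str) -> Edge:
    if a == b:
        raise StemtraceError(f"self-loop {a}-{b}")
    return frozenset((a, b))
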