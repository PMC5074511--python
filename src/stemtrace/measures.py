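"""The four concordance measures between a stem-cell signature and a
candidate normal population.

* overlap enrichment — upper-tail hypergeometric probability of the
  observed signature overlap,
* GSS — fold-change-weighted, centered-expression concordance score,
  GSS = sum_g x_g (y_g - z_g) / sum_g |x_g|,
* SSS — Lin term similarity combined by best-match averaging (BMA)
  across term sets and gene sets,
* SP — mean unweighted shortest-path length between the two gene sets
  on a protein interaction network.

Smaller is better for the enrichment p-value and SP; larger is better
for GSS and SSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.stats import hypergeom

from .datatypes import (
    ExpressionMatrix,
    InteractionNetwork,
    OntologyAnnotation,
    SignatureSet,
    StemtraceError,
)

logger = logging.getLogger("stemtrace")


@dataclass
class MeasureValue:
    """One measure evaluated for one (subtype, population, direction) cell."""

    subtype: str
    population: str
    direction: str  # "up" | "down"
    measure: str  # "enrich_p" | "gss" | "sss" | "sp"
    value: float
    n_used: int


# ---------------------------------------------------------------------------
# overlap enrichment

def overlap_pvalue(set_a: Set[str], set_b: Set[str], universe: Set[str]) -> float:
    """Upper-tail hypergeometric probability P(X >= q) of the overlap.

    q = |A ∩ B| genes drawn in common when |B| genes are sampled without
    replacement from a universe containing |A| marked genes. q = 0 gives 1.
    """
    if not universe:
        raise StemtraceError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise StemtraceError("sets must be contained in the universe")
    q = len(set_a & set_b)
    if q == 0:
        return 1.0
    return float(hypergeom.sf(q - 1, len(universe), len(set_a), len(set_b)))


# ---------------------------------------------------------------------------
# gene signature score

def gss_sample(
    signature: "SignatureSet | Dict[str, float]",
    normal_expr: ExpressionMatrix,
    sample: str,
) -> float:
    """GSS of one sample: sum_g x_g (y_g - z_g) / sum_g |x_g|.

    x_g is the signature log2 fold change, y_g the sample's log2 value and
    z_g the gene's mean log2 value over all samples of the matrix. Genes
    absent from the matrix are skipped; if none remain the score is NaN.
    ``signature`` may be a directional SignatureSet or a plain gene ->
    fold-change mapping (mixed-direction sets).
    """
    fold_changes = signature.log2fc if isinstance(signature, SignatureSet) else dict(signature)
    if not fold_changes:
        raise StemtraceError("empty signature")
    j = normal_expr.sample_index(sample)
    idx = []
    x = []
    for g, fc in fold_changes.items():
        try:
            idx.append(normal_expr.gene_index(g))
        except KeyError:
            continue
        x.append(fc)
    if not idx:
        logger.warning("no signature genes present in matrix")
        return float("nan")
    xv = np.asarray(x)
    rows = np.asarray(idx, dtype=int)
    y = normal_expr.values[rows, j]
    z = normal_expr.values[rows].mean(axis=1)
    return float(np.sum(xv * (y - z)) / np.sum(np.abs(xv)))


def gss_population(
    signature: "SignatureSet | Dict[str, float]",
    normal_expr: ExpressionMatrix,
    population: str,
) -> float:
    """Arithmetic mean of per-sample GSS over the population's samples."""
    samples = normal_expr.samples_of(population)
    if not samples:
        raise StemtraceError(f"population {population!r} has no samples")
    scores = [gss_sample(signature, normal_expr, s) for s in samples]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# semantic similarity

def compute_ic(onto: OntologyAnnotation) -> OntologyAnnotation:
    """Fill term information content: ic(t) = -ln(n_t / n_root).

    n_t counts distinct genes annotated to t or any of its descendants
    (annotations are propagated to ancestors). Terms annotating no gene
    get no IC entry and are dropped from similarity computations.
    """
    counts: Dict[str, int] = {t: 0 for t in onto.terms}
    for gene, terms in onto.gene2terms.items():
        hit: Set[str] = set()
        for t in terms:
            hit |= onto.ancestors(t)
        for t in hit:
            counts[t] += 1
    n_root = counts[onto.root]
    ic: Dict[str, float] = {}
    if n_root > 0:
        for t, n in counts.items():
            if n > 0:
                ic[t] = -math.log(n / n_root)
    onto.ic = ic
    return onto


def lin_sim(t1: str, t2: str, onto: OntologyAnnotation) -> float:
    """Lin similarity 2 ic(MICA) / (ic(t1) + ic(t2)) of two terms."""
    if t1 not in onto.terms or t2 not in onto.terms:
        raise StemtraceError(f"unknown term {t1 if t1 not in onto.terms else t2}")
    if t1 not in onto.ic or t2 not in onto.ic:
        raise StemtraceError("terms without annotation count (no IC); run compute_ic")
    if t1 == t2:
        return 1.0 if onto.ic[t1] > 0 else 0.0
    denom = onto.ic[t1] + onto.ic[t2]
    if denom == 0:
        return 0.0
    common = onto.ancestors(t1) & onto.ancestors(t2)
    mica_ic = max(onto.ic.get(t, 0.0) for t in common)
    return 2.0 * mica_ic / denom


class SemanticSimilarity:
    """Precomputed Lin term-term matrix with vectorized BMA over gene sets.

    Gene-gene similarity is the best-match average over the two genes'
    term sets; set-set similarity is the best-match average over the
    gene-gene matrix. Results are identical to calling :func:`lin_sim`
    pairwise, but usable on signature-sized gene sets.
    """

    def __init__(self, onto: OntologyAnnotation):
        if not onto.ic:
            compute_ic(onto)
        self.onto = onto
        self.terms = sorted(t for t in onto.terms if t in onto.ic)
        tindex = {t: i for i, t in enumerate(self.terms)}
        n = len(self.terms)
        ic = np.array([onto.ic[t] for t in self.terms])
        anc = np.zeros((n, n), dtype=bool)  # anc[i, j]: term j is ancestor-or-self of i
        for t, i in tindex.items():
            for a in onto.ancestors(t):
                if a in tindex:
                    anc[i, tindex[a]] = True
        sim = np.zeros((n, n))
        for i in range(n):
            common = anc[i] & anc  # (n, n): rows j, common ancestors of (i, j)
            mica = np.where(common, ic, -np.inf).max(axis=1)
            mica[~common.any(axis=1)] = 0.0
            denom = ic[i] + ic
            with np.errstate(divide="ignore", invalid="ignore"):
                sim[i] = np.where(denom > 0, 2.0 * mica / denom, 0.0)
        np.fill_diagonal(sim, np.where(ic > 0, 1.0, 0.0))
        self.term_sim = sim
        self._tindex = tindex
        # per-gene term index lists, restricted to IC-bearing terms; genes
        # with identical term sets share one profile so the profile-profile
        # BMA matrix is computed once
        self._gene_terms: Dict[str, np.ndarray] = {}
        self._gene_profile: Dict[str, int] = {}
        profile_ids: Dict[Tuple[int, ...], int] = {}
        profiles: List[np.ndarray] = []
        for g in sorted(onto.gene2terms):
            ts = onto.gene2terms[g]
            key = tuple(sorted(tindex[t] for t in ts if t in tindex))
            if not key:
                continue
            arr = np.array(key, dtype=int)
            self._gene_terms[g] = arr
            if key not in profile_ids:
                profile_ids[key] = len(profiles)
                profiles.append(arr)
            self._gene_profile[g] = profile_ids[key]
        self._profile_bma = self._bma_matrix(profiles, profiles) if profiles else np.zeros((0, 0))

    def annotated(self, genes: Iterable[str]) -> List[str]:
        return [g for g in genes if g in self._gene_terms]

    def gene_sim_matrix(self, genes_a: Sequence[str], genes_b: Sequence[str]) -> np.ndarray:
        """BMA gene-gene Lin similarity for annotated genes (rows A, cols B)."""
        ia = np.array([self._gene_profile[g] for g in genes_a], dtype=int)
        ib = np.array([self._gene_profile[g] for g in genes_b], dtype=int)
        return self._profile_bma[np.ix_(ia, ib)]

    def _bma_matrix(self, ta: Sequence[np.ndarray], tb: Sequence[np.ndarray]) -> np.ndarray:
        ka = max(len(t) for t in ta)
        kb = max(len(t) for t in tb)
        pad_a = np.zeros((len(ta), ka), dtype=int)
        mask_a = np.zeros((len(ta), ka), dtype=bool)
        for i, t in enumerate(ta):
            pad_a[i, : len(t)] = t
            mask_a[i, : len(t)] = True
        pad_b = np.zeros((len(tb), kb), dtype=int)
        mask_b = np.zeros((len(tb), kb), dtype=bool)
        for i, t in enumerate(tb):
            pad_b[i, : len(t)] = t
            mask_b[i, : len(t)] = True
        # S[i, j, p, q] = term_sim(term p of gene i, term q of gene j)
        s = self.term_sim[pad_a[:, None, :, None], pad_b[None, :, None, :]]
        valid = mask_a[:, None, :, None] & mask_b[None, :, None, :]
        s = np.where(valid, s, -np.inf)
        row_best = s.max(axis=3)  # best match of each A-term in B's terms
        col_best = s.max(axis=2)  # best match of each B-term in A's terms
        row_avg = np.where(mask_a[:, None, :], row_best, np.nan)
        col_avg = np.where(mask_b[None, :, :], col_best, np.nan)
        bma = 0.5 * (np.nanmean(row_avg, axis=2) + np.nanmean(col_avg, axis=2))
        return bma

    def set_sim(self, genes_a: Iterable[str], genes_b: Iterable[str]) -> Tuple[float, int]:
        """Set-set BMA similarity; returns (score, n annotated genes used)."""
        ga = sorted(self.annotated(genes_a))
        gb = sorted(self.annotated(genes_b))
        n_used = min(len(ga), len(gb))
        if not ga or not gb:
            logger.warning("semantic similarity: a gene set has no annotated genes")
            return float("nan"), n_used
        return bma_combine(self.gene_sim_matrix(ga, gb)), n_used


def bma_combine(sim_matrix: np.ndarray) -> float:
    """Best-match average of a similarity matrix: the mean of the row
    maxima and the mean of the column maxima, averaged."""
    m = np.asarray(sim_matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise StemtraceError("similarity matrix must be 2-D and non-empty")
    return float(0.5 * (m.max(axis=1).mean() + m.max(axis=0).mean()))


def setsim_bma(
    genes_a: Iterable[str], genes_b: Iterable[str], onto: OntologyAnnotation
) -> float:
    """Best-match-average Lin similarity between two gene sets."""
    score, _ = SemanticSimilarity(onto).set_sim(genes_a, genes_b)
    return score


# ---------------------------------------------------------------------------
# shortest path

class ShortestPathIndex:
    """Sparse unweighted BFS distances on an interaction network.

    Caches per-source-set distance rows so scoring one signature against
    several populations runs the BFS once.
    """

    def __init__(self, net: InteractionNetwork):
        self.node_ids = sorted(net.nodes)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        n = len(self.node_ids)
        rows, cols = [], []
        for e in net.edges:
            a, b = (self._index[x] for x in sorted(e))
            rows += [a, b]
            cols += [b, a]
        data = np.ones(len(rows), dtype=np.int8)
        self.adj = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        self._dist_cache: Dict[Tuple[int, ...], np.ndarray] = {}

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self._index[g] for g in genes if g in self._index), dtype=int)

    def distances_from(self, sources: np.ndarray) -> np.ndarray:
        key = tuple(sources.tolist())
        if key not in self._dist_cache:
            d = csgraph.shortest_path(
                self.adj, method="D", unweighted=True, directed=False, indices=sources
            )
            self._dist_cache[key] = d
        return self._dist_cache[key]

    def mean_sp(self, set_a: Iterable[str], set_b: Iterable[str]) -> Tuple[float, int, int]:
        """Mean SP over pairs (a, b), a != b; returns (mean, n pairs, n excluded)."""
        ia = self.indices(set_a)
        ib = self.indices(set_b)
        if ia.size == 0 or ib.size == 0:
            raise StemtraceError("a gene set does not intersect the network")
        d = self.distances_from(ia)[:, ib]  # (|A|, |B|)
        same = ia[:, None] == ib[None, :]
        finite = np.isfinite(d) & ~same
        n_pairs = int(finite.sum())
        n_excluded = int((~np.isfinite(d) & ~same).sum())
        if n_pairs == 0:
            logger.warning("shortest path: no connected pair between the sets")
            return float("nan"), 0, n_excluded
        return float(d[finite].mean()), n_pairs, n_excluded


def mean_shortest_path(
    set_a: Iterable[str], set_b: Iterable[str], net: InteractionNetwork
) -> float:
    """Mean unweighted shortest-path length between two gene sets.

    Averages over all pairs (a, b) with a in A, b in B and a != b;
    unreachable pairs are excluded (logged).
    """
    value, _, n_excluded = ShortestPathIndex(net).mean_sp(set_a, set_b)
    if n_excluded:
        logger.info("shortest path: excluded %d unreachable pair(s)", n_excluded)
    return value


# ---------------------------------------------------------------------------
# all measures

def score_all(
    csc_signatures: Dict[str, Tuple[SignatureSet, SignatureSet]],
    population_signatures: Dict[str, Tuple[SignatureSet, SignatureSet]],
    normal_expr: ExpressionMatrix,
    onto: OntologyAnnotation,
    net: InteractionNetwork,
    sem: Optional[SemanticSimilarity] = None,
    sp_index: Optional[ShortestPathIndex] = None,
) -> List[MeasureValue]:
    """All 8 measures (4 per direction) for every (subtype, population).

    Enrichment compares up-vs-over and down-vs-under memberships; GSS
    evaluates the directional stem-cell signature in the population's
    samples; SSS and SP compare the directional signature pair. An empty
    signature yields NaN for its direction's measures, never a dropped cell.
    """
    if sem is None:
        sem = SemanticSimilarity(onto)
    if sp_index is None:
        sp_index = ShortestPathIndex(net)
    universe = set(normal_expr.gene_ids)
    out: List[MeasureValue] = []
    for subtype, (csc_up, csc_down) in csc_signatures.items():
        for direction, csc_sig in (("up", csc_up), ("down", csc_down)):
            csc_genes = csc_sig.gene_set() & universe
            for population, (pop_over, pop_under) in population_signatures.items():
                pop_sig = pop_over if direction == "up" else pop_under
                pop_genes = pop_sig.gene_set() & universe

                def emit(measure: str, value: float, n_used: int) -> None:
                    out.append(
                        MeasureValue(
                            subtype=subtype,
                            population=population,
                            direction=direction,
                            measure=measure,
                            value=value,
                            n_used=n_used,
                        )
                    )

                if not csc_genes or not pop_genes:
                    for m in ("enrich_p", "gss", "sss", "sp"):
                        emit(m, float("nan"), 0)
                    continue
                emit(
                    "enrich_p",
                    overlap_pvalue(csc_genes, pop_genes, universe),
                    len(csc_genes & pop_genes),
                )
                emit("gss", gss_population(csc_sig, normal_expr, population), len(csc_genes))
                sss, n_anno = sem.set_sim(csc_genes, pop_genes)
                emit("sss", sss, n_anno)
                try:
                    sp, _, _ = sp_index.mean_sp(csc_genes, pop_genes)
                    n_sp = min(
                        len(sp_index.indices(csc_genes)), len(sp_index.indices(pop_genes))
                    )
                except StemtraceError:
                    sp, n_sp = float("nan"), 0
                emit("sp", sp, n_sp)
    return out
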