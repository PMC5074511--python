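"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the structure of the study design the pipeline
targets: one expression series of normal cell populations (one-vs-rest
signatures), two stem-cell series with per-subtype CSC vs non-CSC
contrasts, an interaction network, an ontology with gene annotations,
promoter sequences and position weight matrices. A designated true
origin population shares a fraction of each subtype's stem-cell
signature in membership, expression direction, annotated function and
network proximity, so every downstream stage has a recoverable planted
answer.

Expression model: baseline b_g ~ N(8, 1) log2 units; group effects of
±effect_size log2 units on signature genes; i.i.d. sample noise
N(0, noise_sd^2); per-gene dataset offsets N(0, dataset_offset_sd^2)
between the two stem-cell series. Genes of a planted co-expression
module share a latent per-sample factor inside their condition's noise
(correlation module_rho) without changing the marginal noise variance,
so signature calling is unaffected while module edges correlate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    InteractionNetwork,
    OntologyAnnotation,
    PWMRecord,
    StemtraceError,
    edge,
)

ALPHABET = "ACGT"


@dataclass
class SimulationParams:
    n_genes: int = 2000
    n_populations: int = 4
    n_subtypes: int = 4
    samples_per_group: int = 4
    n_signature_per_group: int = 150
    shared_fraction: float = 0.6
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_datasets: int = 2
    network_extra_edges: int = 4000
    seed: int = 0
    # secondary structure: dataset shift, planted modules, promoters
    dataset_offset_sd: float = 0.2
    module_size: int = 10
    modules_per_condition: int = 2
    module_rho: float = 0.9
    promoter_length: int = 2000
    pwm_length: int = 10
    n_promoter_controls: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.shared_fraction <= 1):
            raise StemtraceError("shared_fraction must be in [0, 1]")
        if self.effect_size <= 0:
            raise StemtraceError("effect_size must be positive")
        if self.shared_fraction > 0 and self.shared_fraction * self.n_signature_per_group < 1:
            raise StemtraceError("shared_fraction * n_signature_per_group must be >= 1")
        if not (0 <= self.module_rho < 1):
            raise StemtraceError("module_rho must be in [0, 1)")


@dataclass
class GroundTruth:
    true_origin: Dict[str, str]
    planted_shared_genes: Dict[str, Set[str]]
    planted_modules: Dict[str, List[Set[str]]]
    planted_motif_sites: Dict[Tuple[str, str], List[int]]
    seed: int
    # generating sets, for planted-recovery checks
    population_over: Dict[str, Set[str]] = field(default_factory=dict)
    population_under: Dict[str, Set[str]] = field(default_factory=dict)
    csc_up: Dict[str, Set[str]] = field(default_factory=dict)
    csc_down: Dict[str, Set[str]] = field(default_factory=dict)
    planted_pwm: str = ""


@dataclass
class SimulatedInputs:
    normal: ExpressionMatrix
    csc_datasets: List[ExpressionMatrix]
    network: InteractionNetwork
    ontology: OntologyAnnotation
    promoters: Dict[str, str]
    pwms: List[PWMRecord]
    truth: GroundTruth


def _gene_ids(n: int) -> List[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def _allocate_gene_sets(
    params: SimulationParams, rng: np.random.Generator, null: bool
) -> Tuple[List[str], Dict[str, Set[str]], Dict[str, Set[str]], Dict[str, str],
           Dict[str, List[str]], Dict[str, List[str]], Dict[str, Set[str]]]:
    genes = _gene_ids(params.n_genes)
    n_sig = params.n_signature_per_group
    need_pop = 2 * params.n_populations * n_sig
    n_shared = 0 if null else int(round(params.shared_fraction * n_sig))
    n_unique = n_sig - n_shared
    need_csc = 0 if null else 2 * params.n_subtypes * n_unique
    if need_pop + need_csc > params.n_genes:
        raise StemtraceError(
            f"{need_pop + need_csc} signature genes exceed n_genes={params.n_genes}"
        )
    perm = [genes[i] for i in rng.permutation(params.n_genes)]
    cursor = 0

    def take(k: int) -> List[str]:
        nonlocal cursor
        out = perm[cursor : cursor + k]
        cursor += k
        return out

    populations = [f"pop{i + 1}" for i in range(params.n_populations)]
    subtypes = [f"subtype{i + 1}" for i in range(params.n_subtypes)]
    pop_over = {p: set(take(n_sig)) for p in populations}
    pop_under = {p: set(take(n_sig)) for p in populations}
    origin_order = rng.permutation(params.n_populations)
    true_origin = {s: populations[origin_order[i % params.n_populations]]
                   for i, s in enumerate(subtypes)}
    csc_up: Dict[str, List[str]] = {}
    csc_down: Dict[str, List[str]] = {}
    shared: Dict[str, Set[str]] = {}
    for s in subtypes:
        if null:
            draw = rng.choice(params.n_genes, size=2 * n_sig, replace=False)
            picked = [genes[i] for i in draw]
            csc_up[s] = picked[:n_sig]
            csc_down[s] = picked[n_sig:]
            shared[s] = set()
        else:
            origin = true_origin[s]
            up_shared = [sorted(pop_over[origin])[i]
                         for i in rng.choice(n_sig, size=n_shared, replace=False)]
            down_shared = [sorted(pop_under[origin])[i]
                           for i in rng.choice(n_sig, size=n_shared, replace=False)]
            csc_up[s] = up_shared + take(n_unique)
            csc_down[s] = down_shared + take(n_unique)
            shared[s] = set(up_shared) | set(down_shared)
    return genes, pop_over, pop_under, true_origin, csc_up, csc_down, shared


def _expression(
    genes: List[str],
    group_effects: Dict[str, Dict[str, float]],
    samples_per_group: int,
    noise_sd: float,
    rng: np.random.Generator,
    baseline: np.ndarray,
    gene_offset: Optional[np.ndarray] = None,
    sample_prefix: str = "s",
    module_noise: Optional[Dict[str, Sequence[Set[str]]]] = None,
    module_rho: float = 0.0,
) -> ExpressionMatrix:
    """Build one expression matrix from per-group gene effect maps.

    ``module_noise`` maps a group label to planted module gene sets whose
    sample noise shares a latent factor with correlation ``module_rho``
    (marginal noise variance unchanged).
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_ids: List[str] = []
    groups: Dict[str, str] = {}
    cols: List[np.ndarray] = []
    for group in group_effects:
        effect = np.zeros(len(genes))
        for g, e in group_effects[group].items():
            effect[gene_index[g]] += e
        factors: List[np.ndarray] = []
        if module_noise and group in module_noise and module_rho > 0:
            # standardized over the group's samples so the realized
            # in-sample shared variance is exactly module_rho * noise_sd^2
            for _ in module_noise[group]:
                f = rng.normal(0.0, 1.0, size=samples_per_group)
                factors.append((f - f.mean()) / f.std())
        for k in range(samples_per_group):
            sid = f"{sample_prefix}.{group}.{k + 1}"
            sample_ids.append(sid)
            groups[sid] = group
            noise = rng.normal(0.0, noise_sd, size=len(genes))
            if factors:
                for mod, f in zip(module_noise[group], factors):
                    idx = [gene_index[g] for g in sorted(mod)]
                    shared_part = math.sqrt(module_rho) * f[k]
                    indiv = math.sqrt(1.0 - module_rho) * rng.normal(0.0, 1.0, size=len(idx))
                    noise[idx] = noise_sd * (shared_part + indiv)
            col = baseline + effect + noise
            if gene_offset is not None:
                col = col + gene_offset
            cols.append(col)
    values = np.column_stack(cols)
    return ExpressionMatrix(gene_ids=list(genes), sample_ids=sample_ids,
                            values=values, groups=groups)


def _build_network(
    genes: List[str],
    pop_over: Dict[str, Set[str]],
    pop_under: Dict[str, Set[str]],
    modules: Dict[str, List[Set[str]]],
    n_extra: int,
    rng: np.random.Generator,
) -> InteractionNetwork:
    edges: Set[frozenset] = set()
    for sets in (pop_over, pop_under):
        for members in sets.values():
            ordered = sorted(members)
            hub = ordered[0]
            for g in ordered[1:]:
                edges.add(edge(hub, g))
    for mods in modules.values():
        for mod in mods:
            ordered = sorted(mod)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    edges.add(edge(a, b))
    n = len(genes)
    added = 0
    while added < n_extra:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = edge(genes[i], genes[j])
        if e in edges:
            continue
        edges.add(e)
        added += 1
    return InteractionNetwork(nodes=set(genes), edges=edges)


def _build_ontology(
    genes: List[str],
    pop_over: Dict[str, Set[str]],
    pop_under: Dict[str, Set[str]],
    rng: np.random.Generator,
    n_noise_terms: int = 10,
    leaves_per_branch: int = 3,
) -> OntologyAnnotation:
    root = "T:root"
    terms: Set[str] = {root}
    parents: Dict[str, Set[str]] = {}
    branch_leaves: Dict[Tuple[str, str], List[str]] = {}
    for direction, sets in (("over", pop_over), ("under", pop_under)):
        for pop in sets:
            branch = f"T:{pop}.{direction}"
            terms.add(branch)
            parents[branch] = {root}
            leaves = []
            for j in range(leaves_per_branch):
                leaf = f"{branch}.l{j + 1}"
                terms.add(leaf)
                parents[leaf] = {branch}
                leaves.append(leaf)
            branch_leaves[(pop, direction)] = leaves
    noise_terms = []
    for k in range(n_noise_terms):
        t = f"T:noise{k + 1}"
        terms.add(t)
        parents[t] = {root}
        noise_terms.append(t)
    gene2terms: Dict[str, Set[str]] = {}
    assigned: Set[str] = set()
    for direction, sets in (("over", pop_over), ("under", pop_under)):
        for pop, members in sets.items():
            leaves = branch_leaves[(pop, direction)]
            for g in sorted(members):
                k = int(rng.integers(1, len(leaves) + 1))
                pick = rng.choice(len(leaves), size=k, replace=False)
                ts = {leaves[i] for i in pick}
                if rng.random() < 0.3:
                    ts.add(noise_terms[int(rng.integers(0, len(noise_terms)))])
                gene2terms.setdefault(g, set()).update(ts)
                assigned.add(g)
    for g in genes:
        if g not in assigned:
            k = int(rng.integers(1, 3))
            pick = rng.choice(len(noise_terms), size=k, replace=False)
            gene2terms[g] = {noise_terms[i] for i in pick}
    return OntologyAnnotation(terms=terms, parents=parents, root=root,
                              gene2terms=gene2terms)


def _random_pwm(name: str, length: int, rng: np.random.Generator) -> Tuple[PWMRecord, str]:
    consensus_idx = rng.integers(0, 4, size=length)
    counts = rng.integers(0, 3, size=(4, length)).astype(float)
    for i, b in enumerate(consensus_idx):
        counts[b, i] = 12 + float(rng.integers(0, 9))
    consensus = "".join(ALPHABET[b] for b in consensus_idx)
    return PWMRecord(name=name, counts=counts), consensus


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _simulate(params: SimulationParams, null: bool) -> SimulatedInputs:
    rng = np.random.default_rng(params.seed)
    (genes, pop_over, pop_under, true_origin,
     csc_up, csc_down, shared) = _allocate_gene_sets(params, rng, null)
    populations = sorted(pop_over)
    subtypes = sorted(csc_up)

    # planted co-expression modules: condition "csc" (first subtype's CSC
    # samples, dataset 1) and condition "origin" (its true origin's normal
    # samples), drawn from the first subtype's non-shared up genes
    focal = subtypes[0]
    unique_up = [g for g in csc_up[focal] if g not in shared[focal]]
    msize = params.module_size
    n_fresh = max(1, msize // 5)  # genes unique to the origin-side partner
    need = (2 * params.modules_per_condition) * msize
    if len(unique_up) < need:
        raise StemtraceError(
            f"{need} module genes needed but only {len(unique_up)} unique up genes"
        )
    modules_csc = [set(unique_up[i * msize : (i + 1) * msize])
                   for i in range(params.modules_per_condition)]
    # the first origin-condition module shares most genes with the first
    # csc module (exercises cross-condition pairing); the rest are disjoint
    fresh_start = params.modules_per_condition * msize
    modules_origin = [set(unique_up[n_fresh:msize])
                      | set(unique_up[fresh_start : fresh_start + n_fresh])]
    for i in range(1, params.modules_per_condition):
        start = fresh_start + n_fresh + (i - 1) * msize
        modules_origin.append(set(unique_up[start : start + msize]))
    planted_modules = {"csc": modules_csc, "origin": modules_origin}

    baseline = rng.normal(8.0, 1.0, size=params.n_genes)

    # normal series: population effects; origin-condition module noise on
    # the focal subtype's true-origin population
    normal_effects: Dict[str, Dict[str, float]] = {}
    for pop in populations:
        eff: Dict[str, float] = {}
        for g in pop_over[pop]:
            eff[g] = params.effect_size
        for g in pop_under[pop]:
            eff[g] = -params.effect_size
        normal_effects[pop] = eff
    origin_pop = true_origin[focal]
    normal = _expression(
        genes,
        normal_effects,
        params.samples_per_group,
        params.noise_sd,
        rng,
        baseline,
        sample_prefix="n",
        module_noise={origin_pop: modules_origin},
        module_rho=params.module_rho,
    )

    # stem-cell series: CSC vs nonCSC per subtype; csc-condition module
    # noise on the focal subtype's CSC group of dataset 1
    csc_datasets: List[ExpressionMatrix] = []
    for d in range(params.n_datasets):
        effects: Dict[str, Dict[str, float]] = {}
        for s in subtypes:
            eff_csc: Dict[str, float] = {}
            for g in csc_up[s]:
                eff_csc[g] = params.effect_size
            for g in csc_down[s]:
                eff_csc[g] = -params.effect_size
            effects[f"{s}.CSC"] = eff_csc
            effects[f"{s}.nonCSC"] = {}
        offset = rng.normal(0.0, params.dataset_offset_sd, size=params.n_genes)
        module_noise = {f"{focal}.CSC": modules_csc} if d == 0 else None
        csc_datasets.append(
            _expression(
                genes,
                effects,
                params.samples_per_group,
                params.noise_sd,
                rng,
                baseline,
                gene_offset=offset,
                sample_prefix=f"d{d + 1}",
                module_noise=module_noise,
                module_rho=params.module_rho,
            )
        )

    network = _build_network(
        genes, pop_over, pop_under, planted_modules, params.network_extra_edges, rng
    )
    ontology = _build_ontology(genes, pop_over, pop_under, rng)

    # promoters: planted module genes carry one exact consensus site of the
    # designated PWM; control genes carry none
    planted_pwm, consensus = _random_pwm("M_planted", params.pwm_length, rng)
    decoy_pwm, _ = _random_pwm("M_decoy", params.pwm_length, rng)
    module_genes = sorted(set.union(set(), *(modules_csc + modules_origin)))
    control_pool = [g for g in genes
                    if g not in set(module_genes)][: params.n_promoter_controls]
    promoters: Dict[str, str] = {}
    planted_sites: Dict[Tuple[str, str], List[int]] = {}
    L = params.promoter_length
    for g in module_genes:
        seq = _random_seq(L, rng)
        pos = int(rng.integers(0, L - params.pwm_length + 1))
        seq = seq[:pos] + consensus + seq[pos + params.pwm_length :]
        promoters[g] = seq
        planted_sites[(g, planted_pwm.name)] = [pos]
    for g in control_pool:
        promoters[g] = _random_seq(L, rng)

    truth = GroundTruth(
        true_origin=true_origin,
        planted_shared_genes=shared,
        planted_modules=planted_modules,
        planted_motif_sites=planted_sites,
        seed=params.seed,
        population_over=pop_over,
        population_under=pop_under,
        csc_up={s: set(v) for s, v in csc_up.items()},
        csc_down={s: set(v) for s, v in csc_down.items()},
        planted_pwm=planted_pwm.name,
    )
    return SimulatedInputs(
        normal=normal,
        csc_datasets=csc_datasets,
        network=network,
        ontology=ontology,
        promoters=promoters,
        pwms=[planted_pwm, decoy_pwm],
        truth=truth,
    )


def simulate_all(params: SimulationParams) -> SimulatedInputs:
    """Generate all pipeline inputs with a planted true origin."""
    return _simulate(params, null=False)


def simulate_null(params: SimulationParams) -> SimulatedInputs:
    """Null generator: stem-cell signatures drawn independently of every
    population (shared fraction forced to 0); calibrates false-positive
    behavior of the rank fusion."""
    return _simulate(params, null=True)
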