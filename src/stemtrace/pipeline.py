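"""End-to-end orchestration: signatures -> measures -> fusion -> modules
-> motif scan, on in-memory inputs (simulated or loaded from disk)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from . import fusion as fusion_mod
from . import modules as modules_mod
from . import motif as motif_mod
from . import signatures as sig_mod
from .datatypes import AnalysisConfig, ExpressionMatrix, InteractionNetwork, OntologyAnnotation
from .fusion import FusionResult, fuse_all
from .measures import MeasureValue, SemanticSimilarity, ShortestPathIndex, score_all
from .simulate import SimulatedInputs

logger = logging.getLogger("stemtrace")


@dataclass
class OriginResult:
    """Scores, fused ranks and overall ranks of the origin prioritization."""

    measures: Dict[str, List[MeasureValue]]  # dataset label -> rows
    fusion: List[FusionResult]

    def measure_table(self) -> pd.DataFrame:
        rows = []
        for ds, values in self.measures.items():
            for v in values:
                rows.append(
                    (ds, v.subtype, v.population, v.direction, v.measure, v.value, v.n_used)
                )
        return pd.DataFrame(
            rows,
            columns=["dataset", "subtype", "population", "direction", "measure", "value", "n_used"],
        )

    def rank_table(self) -> pd.DataFrame:
        rows = []
        for r in self.fusion:
            row = {
                "subtype": r.subtype,
                "population": r.population,
                "q_value": r.q_value,
                "overall_rank": r.overall_rank,
            }
            for ds, rank in r.per_dataset_rank.items():
                row[f"rank.{ds}"] = rank
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["subtype", "overall_rank"]).reset_index(drop=True)

    def top_origin(self, subtype: str) -> str:
        """The population with the best (lowest) overall rank for a subtype."""
        cands = [r for r in self.fusion if r.subtype == subtype]
        if not cands:
            raise KeyError(subtype)
        return min(cands, key=lambda r: (r.overall_rank, r.population)).population


def prioritize_origins(
    normal: ExpressionMatrix,
    csc_datasets: Sequence[ExpressionMatrix],
    onto: OntologyAnnotation,
    net: InteractionNetwork,
    config: AnalysisConfig,
) -> OriginResult:
    """Run signature calling, the four measures and rank fusion."""
    population_signatures = sig_mod.call_population_signatures(normal, config)
    sem = SemanticSimilarity(onto)
    sp_index = ShortestPathIndex(net)
    measures: Dict[str, List[MeasureValue]] = {}
    for d, expr in enumerate(csc_datasets):
        subtypes = sorted({g.rsplit(".", 1)[0] for g in set(expr.groups.values())})
        csc_signatures = {
            s: sig_mod.call_csc_signatures(expr, s, config) for s in subtypes
        }
        measures[f"dataset{d + 1}"] = score_all(
            csc_signatures, population_signatures, normal, onto, net,
            sem=sem, sp_index=sp_index,
        )
    return OriginResult(measures=measures, fusion=fuse_all(measures))


def origin_specific_signature_for(
    subtype: str,
    origin: str,
    csc_datasets: Sequence[ExpressionMatrix],
    normal: ExpressionMatrix,
    config: AnalysisConfig,
) -> Tuple[Set[str], Set[str]]:
    """Direction-consistent CSC-vs-origin differential genes across datasets."""
    diffs = [
        sig_mod.cross_matrix_differential(
            expr, f"{subtype}.CSC", normal, origin, config
        )
        for expr in csc_datasets
    ]
    return sig_mod.origin_specific_signature(diffs)


@dataclass
class ModuleStageResult:
    modules: Dict[str, List[modules_mod.GeneModule]]  # condition -> kept modules
    significant: Dict[str, List[modules_mod.GeneModule]]
    pairs: List[Tuple[modules_mod.GeneModule, modules_mod.GeneModule, Set[str]]]


def detect_origin_modules(
    net: InteractionNetwork,
    conditions: Dict[str, Tuple[ExpressionMatrix, Sequence[str]]],
    signature: Set[str],
    config: AnalysisConfig,
    seed: int,
) -> ModuleStageResult:
    """Condition-specific modules, filtered, enriched and paired.

    ``conditions`` maps a condition label to (expression matrix, sample
    ids) defining the correlation context.
    """
    kept: Dict[str, List[modules_mod.GeneModule]] = {}
    signif: Dict[str, List[modules_mod.GeneModule]] = {}
    for cond, (expr, samples) in conditions.items():
        weighted = modules_mod.pcc_weight_edges(net, expr, samples)
        detected = modules_mod.detect_modules(
            weighted, seed=seed, condition=cond,
            resolution=config.module_resolution, use_weights=config.module_use_weights,
        )
        filtered = modules_mod.filter_modules(detected, config)
        universe = set(expr.gene_ids) & set(weighted.nodes)
        modules_mod.enrich_modules(filtered, signature, universe, config.p_threshold)
        kept[cond] = filtered
        signif[cond] = [m for m in filtered if m.significant]
    conds = sorted(kept)
    pairs: List[Tuple[modules_mod.GeneModule, modules_mod.GeneModule, Set[str]]] = []
    if len(conds) >= 2:
        pairs = modules_mod.shared_module_pairs(signif[conds[0]], signif[conds[1]], signature)
    return ModuleStageResult(modules=kept, significant=signif, pairs=pairs)


def run_all(sim: SimulatedInputs, config: AnalysisConfig, seed: int) -> Dict[str, object]:
    """Full pipeline on simulated inputs; returns a result bundle."""
    origin_result = prioritize_origins(
        sim.normal, sim.csc_datasets, sim.ontology, sim.network, config
    )
    subtypes = sorted(sim.truth.true_origin)
    focal = subtypes[0]
    predicted = origin_result.top_origin(focal)
    up, down = origin_specific_signature_for(
        focal, predicted, sim.csc_datasets, sim.normal, config
    )
    signature = up | down
    conditions = {
        "csc": (sim.csc_datasets[0], sim.csc_datasets[0].samples_of(f"{focal}.CSC")),
        "origin": (sim.normal, sim.normal.samples_of(predicted)),
    }
    module_result = detect_origin_modules(sim.network, conditions, signature, config, seed)
    profiles = [motif_mod.build_profile(rec) for rec in sim.pwms]
    hits = motif_mod.scan_promoters(sim.promoters, profiles, config)
    return {
        "origin": origin_result,
        "origin_specific_signature": (up, down),
        "modules": module_result,
        "motif_hits": hits,
    }
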