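"""Readers and writers for the pipeline's on-disk formats.

Expression matrices and group labels are TSV, gene sets are GMT,
networks are SIF-like edge lists, ontologies are OBO (parsed with
obonet) with 2-column gene->term annotations, sequences are FASTA
(Bio.SeqIO), transcripts are BED, and position matrices are
TRANSFAC-format count blocks. Every reader has a matching writer and
the pair round-trips exactly.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    ExpressionMatrix,
    InteractionNetwork,
    OntologyAnnotation,
    PWMRecord,
    StemtraceError,
    edge,
)

logger = logging.getLogger("stemtrace")

ALPHABET = ("A", "C", "G", "T")

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# expression

def read_groups(path) -> Dict[str, str]:
    groups: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise StemtraceError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        groups[parts[0]] = parts[1]
    return groups


def write_groups(groups: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(groups):
            fh.write(f"{s}\t{groups[s]}\n")


def read_expression(path, groups_path) -> ExpressionMatrix:
    """Read a genes x samples log2 TSV plus a sample->group map.

    Duplicate gene rows are collapsed by the arithmetic mean of their log2
    values (with a warning); a sample missing from the groups file or a
    non-numeric cell is a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise StemtraceError(
                        f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: {cell!r}"
                    ) from None
        raise
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Index(gene_ids)
        n_dup = dup.duplicated().sum()
        logger.warning("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        collapsed = pd.DataFrame(values, index=gene_ids).groupby(level=0, sort=False).mean()
        gene_ids = [str(g) for g in collapsed.index]
        values = collapsed.to_numpy()
    groups = read_groups(groups_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise StemtraceError(f"{groups_path}: no group label for samples {missing}")
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        groups={s: groups[s] for s in sample_ids},
    )


def write_expression(expr: ExpressionMatrix, path, groups_path=None) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)
    if groups_path is not None:
        write_groups(expr.groups, groups_path)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise StemtraceError(f"{path}:{lineno}: GMT needs name, description, >=1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path, description: str = "stemtrace") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# network

def read_network(path) -> InteractionNetwork:
    """Read a 2- or 3-column edge list (nodeA nodeB [weight]).

    Undirected; duplicate edges are collapsed, self-loops dropped with a
    logged count. A malformed line is a hard error naming the line number.
    """
    nodes: Set[str] = set()
    edges: Set[frozenset] = set()
    weight: Dict[frozenset, float] = {}
    n_loops = 0
    any_weight = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise StemtraceError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}")
        a, b = parts[0], parts[1]
        if a == b:
            n_loops += 1
            nodes.add(a)
            continue
        nodes.update((a, b))
        e = edge(a, b)
        edges.add(e)
        if len(parts) == 3:
            try:
                weight[e] = float(parts[2])
            except ValueError:
                raise StemtraceError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
            any_weight = True
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return InteractionNetwork(nodes=nodes, edges=edges, weight=weight if any_weight else None)


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(net.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted(e)
            if net.weight is not None and e in net.weight:
                fh.write(f"{a}\t{b}\t{FLOAT_FMT % net.weight[e]}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for n in sorted(net.nodes):
            if not any(n in e for e in net.edges):
                fh.write(f"{n}\t{n}\n")  # isolated node, re-read as node-only


# ---------------------------------------------------------------------------
# ontology

def read_ontology(obo_path, anno_path) -> OntologyAnnotation:
    """Read an OBO term DAG plus a 2-column gene->term annotation TSV.

    Cyclic is_a relations are a hard error; annotations to terms absent
    from the OBO are skipped with a logged count. IC values are left empty
    (fill with :func:`stemtrace.measures.compute_ic`).
    """
    import obonet

    graph = obonet.read_obo(str(obo_path))
    terms: Set[str] = set(graph.nodes)
    parents: Dict[str, Set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parents.setdefault(child, set()).add(parent)
    roots = [t for t in terms if not parents.get(t)]
    if len(roots) != 1:
        raise StemtraceError(f"{obo_path}: expected a single root term, found {sorted(roots)}")
    gene2terms: Dict[str, Set[str]] = {}
    n_skipped = 0
    for lineno, line in enumerate(Path(anno_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise StemtraceError(f"{anno_path}:{lineno}: expected 'gene<TAB>term'")
        gene, term = parts
        if term not in terms:
            n_skipped += 1
            continue
        gene2terms.setdefault(gene, set()).add(term)
    if n_skipped:
        logger.warning("%s: skipped %d annotation(s) to unknown terms", anno_path, n_skipped)
    return OntologyAnnotation(
        terms=terms, parents=parents, root=roots[0], gene2terms=gene2terms
    )


def write_ontology(onto: OntologyAnnotation, obo_path, anno_path) -> None:
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(onto.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {t}\n")
            for p in sorted(onto.parents.get(t, ())):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")
    with open(anno_path, "w") as fh:
        for gene in sorted(onto.gene2terms):
            for term in sorted(onto.gene2terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# sequences / transcripts

def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_transcripts_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into a transcript table.

    Returns columns chrom, tss, strand, name. The TSS is the start
    coordinate on the + strand and the end coordinate on the - strand.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise StemtraceError(f"{path}:{lineno}: BED6 required (chrom start end name score strand)")
        chrom, start, end, name, _score, strand = parts[:6]
        if strand not in "+-":
            raise StemtraceError(f"{path}:{lineno}: bad strand {strand!r}")
        tss = int(start) if strand == "+" else int(end)
        rows.append((chrom, tss, strand, name))
    return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "name"])


# ---------------------------------------------------------------------------
# PWMs (TRANSFAC format)

_POS_ROW = re.compile(r"^\d\d\s")


def read_pwm(path) -> List[PWMRecord]:
    """Read one or more TRANSFAC-format count matrices.

    Recognizes NA (name), PO/P0 (column header) and numbered position rows
    with four numeric fields; matrices are separated by ``//``.
    """
    records: List[PWMRecord] = []
    name = None
    rows: List[List[float]] = []

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if rows:
            counts = np.array(rows, dtype=float).T  # (4, L)
            records.append(PWMRecord(name=name or f"matrix{len(records) + 1}", counts=counts))
        name, rows = None, []

    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("//"):
            flush(lineno)
            continue
        if s.startswith("NA"):
            name = s[2:].strip()
            continue
        if s.startswith(("PO", "P0", "AC", "ID", "DE", "XX", "BF", "CC")):
            continue
        if _POS_ROW.match(s):
            fields = s.split()
            vals = []
            for f in fields[1:5]:
                try:
                    vals.append(float(f))
                except ValueError:
                    break
            if len(vals) < 4:
                raise StemtraceError(f"{path}:{lineno}: position row with <4 numeric fields")
            rows.append(vals)
    flush(-1)
    return records


def write_pwm(records: Sequence[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"NA {rec.name}\n")
            fh.write("PO\tA\tC\tG\tT\n")
            for i in range(rec.length):
                vals = "\t".join(FLOAT_FMT % v for v in rec.counts[:, i])
                fh.write(f"{i + 1:02d}\t{vals}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# config

def read_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise StemtraceError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path) -> None:
    data = {k: getattr(config, k) for k in AnalysisConfig.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
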