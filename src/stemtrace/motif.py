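"""Match-style PWM scanning of promoter sequences.

A count matrix becomes a frequency profile with per-position information
weights I(i) = sum_b f(i,b) ln(4 f(i,b)); the 5 consecutive positions
with the largest total information form the core. A window's matrix
similarity score (MSS) is the information-weighted frequency sum,
min-max normalized to [0, 1] so the consensus scores 1 and the
anticonsensus 0; the core similarity score (CSS) is the same quantity
restricted to the core. Hits must pass the CSS cutoff (default 1, the
strictest setting) and then a per-matrix MSS cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, PWMRecord, StemtraceError

logger = logging.getLogger("stemtrace")

ALPHABET = "ACGT"
CORE_LEN = 5

_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMProfile:
    record: PWMRecord
    freqs: np.ndarray  # (4, L), columns sum to 1
    info: np.ndarray  # (L,) information weights, >= 0
    core_start: int

    @property
    def length(self) -> int:
        return self.record.length


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    matrix: str
    strand: str  # "+" | "-"
    offset: int  # 0-based window start on the forward sequence
    mss: float
    css: float


def build_profile(rec: PWMRecord) -> PWMProfile:
    """Normalize counts to frequencies and locate the 5-position core.

    f(i,b) = (count + pseudocount) / (colsum + 4 pseudocount);
    I(i) = sum_b f(i,b) ln(4 f(i,b)); the core is the window of 5
    consecutive positions maximizing total information (leftmost on ties).
    """
    if rec.length < CORE_LEN:
        raise StemtraceError(f"matrix {rec.name}: length {rec.length} < {CORE_LEN}")
    pc = rec.pseudocount
    colsum = rec.counts.sum(axis=0)
    freqs = (rec.counts + pc) / (colsum + 4 * pc)
    with np.errstate(divide="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4 * np.maximum(freqs, 1e-300)), 0.0)
    info = terms.sum(axis=0)
    info = np.maximum(info, 0.0)  # guard tiny negative drift at uniform columns
    window_sums = np.convolve(info, np.ones(CORE_LEN), mode="valid")
    core_start = int(np.argmax(window_sums))  # argmax takes the leftmost tie
    return PWMProfile(record=rec, freqs=freqs, info=info, core_start=core_start)


def _window_weights(profile: PWMProfile) -> np.ndarray:
    """(5, L) information-weighted frequency table; row 4 scores ambiguous
    bases as the per-position minimum."""
    w = profile.info[None, :] * profile.freqs  # (4, L)
    ambig = w.min(axis=0, keepdims=True)
    return np.vstack([w, ambig])


def match_scores(profile: PWMProfile, window: str) -> Tuple[float, float]:
    """MSS and CSS of a single window of length L.

    score = (Current - Min) / (Max - Min) with Current = sum_i I(i) f(i, b_i)
    and Min/Max the information-weighted minimal/maximal frequencies;
    CSS restricts the sums to the 5 core positions. A degenerate
    Max == Min yields 1 by convention (warned).
    """
    L = profile.length
    if len(window) != L:
        raise StemtraceError(f"window length {len(window)} != matrix length {L}")
    codes = np.array([_CODE.get(b, 4) for b in window.upper()], dtype=int)
    w = _window_weights(profile)
    current = w[codes, np.arange(L)]
    lo = w[:4].min(axis=0)
    hi = w[:4].max(axis=0)

    def normalize(sl: slice) -> float:
        cur = current[sl].sum()
        mn = lo[sl].sum()
        mx = hi[sl].sum()
        if mx - mn <= 0:
            logger.warning("matrix %s: degenerate Max == Min, score 1", profile.record.name)
            return 1.0
        return float((cur - mn) / (mx - mn))

    mss = normalize(slice(None))
    css = normalize(slice(profile.core_start, profile.core_start + CORE_LEN))
    return mss, css


def extract_promoters(
    genome: Mapping[str, str], transcripts: pd.DataFrame, length: int
) -> Dict[str, str]:
    """Upstream promoter sequence per transcript.

    For a + strand transcript the promoter is [TSS - length, TSS) on the
    forward strand; for - strand it is the reverse complement of
    [TSS, TSS + length). Promoters are truncated at contig boundaries
    (logged); transcripts on unknown contigs are skipped with a warning.
    Coordinates are 0-based half-open.
    """
    out: Dict[str, str] = {}
    for row in transcripts.itertuples(index=False):
        chrom, tss, strand, name = row.chrom, int(row.tss), row.strand, row.name
        if chrom not in genome:
            logger.warning("transcript %s: unknown contig %s, skipped", name, chrom)
            continue
        contig = genome[chrom]
        if strand == "+":
            start = max(0, tss - length)
            seq = contig[start:tss]
        else:
            end = min(len(contig), tss + length)
            seq = reverse_complement(contig[tss:end])
        if len(seq) < length:
            logger.info("transcript %s: promoter truncated to %d bases", name, len(seq))
        out[name] = seq.upper()
    return out


def _scan_one_strand(
    profile: PWMProfile, seq: str, weights: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """MSS and CSS for every window start of one oriented sequence."""
    L = profile.length
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    codes = np.fromiter((_CODE.get(b, 4) for b in seq), dtype=np.intp, count=len(seq))
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n, L)
    pos = np.arange(L)
    current = weights[windows, pos].sum(axis=1)
    lo = weights[:4].min(axis=0)
    hi = weights[:4].max(axis=0)
    span = hi.sum() - lo.sum()
    mss = (current - lo.sum()) / span if span > 0 else np.ones(n)
    core = slice(profile.core_start, profile.core_start + CORE_LEN)
    cur_core = weights[windows[:, core], pos[core]].sum(axis=1)
    span_core = hi[core].sum() - lo[core].sum()
    css = (cur_core - lo[core].sum()) / span_core if span_core > 0 else np.ones(n)
    return mss, css


def scan_promoters(
    promoters: Mapping[str, str],
    profiles: Sequence[PWMProfile],
    config: AnalysisConfig,
) -> List[MotifHit]:
    """Scan both strands of every promoter with every profile.

    Emits hits passing css >= css_cutoff and mss >= the matrix's MSS
    cutoff (``config.mss_cutoffs``, falling back to
    ``config.default_mss_cutoff``). Offsets are window starts on the
    forward sequence, 0-based.
    """
    hits: List[MotifHit] = []
    for profile in profiles:
        name = profile.record.name
        if name in config.mss_cutoffs:
            mss_cut = config.mss_cutoffs[name]
        elif config.default_mss_cutoff is not None:
            mss_cut = config.default_mss_cutoff
        else:
            raise StemtraceError(f"no MSS cutoff for matrix {name}")
        weights = _window_weights(profile)
        L = profile.length
        for seq_id in sorted(promoters):
            seq = promoters[seq_id].upper()
            for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
                mss, css = _scan_one_strand(profile, oriented, weights)
                keep = np.nonzero((css >= config.css_cutoff) & (mss >= mss_cut))[0]
                for k in keep:
                    offset = int(k) if strand == "+" else len(seq) - L - int(k)
                    hits.append(
                        MotifHit(
                            sequence_id=seq_id,
                            matrix=name,
                            strand=strand,
                            offset=offset,
                            mss=float(mss[k]),
                            css=float(css[k]),
                        )
                    )
    hits.sort(key=lambda h: (h.sequence_id, h.matrix, h.offset, h.strand))
    return hits


def gene_hit_counts(
    hits: Sequence[MotifHit], gene_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per gene set, the number of genes with >= 1 hit of each matrix.

    ``gene_sets`` maps a set label (e.g. a module id) to promoter /
    sequence ids. Returns a matrices x gene-set count table.
    """
    matrices = sorted({h.matrix for h in hits})
    by_matrix: Dict[str, set] = {m: set() for m in matrices}
    for h in hits:
        by_matrix[h.matrix].add(h.sequence_id)
    data = {
        label: [len(by_matrix[m] & set(genes)) for m in matrices]
        for label, genes in gene_sets.items()
    }
    return pd.DataFrame(data, index=matrices)
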