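import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemtrace.datatypes import AnalysisConfig, PWMRecord, StemtraceError
from stemtrace.motif import (
    build_profile,
    extract_promoters,
    gene_hit_counts,
    match_scores,
    reverse_complement,
    scan_promoters,
)

ALPHABET = "ACGT"


def _rec(counts, name="m", pseudocount=1e-4):
    return PWMRecord(name=name, counts=np.asarray(counts, dtype=float),
                     pseudocount=pseudocount)


def _toy_record():
    # consensus ACGTA with varying information content
    counts = np.array([
        [9, 0, 0, 1, 6],
        [1, 8, 1, 1, 2],
        [0, 1, 9, 0, 1],
        [0, 1, 0, 8, 1],
    ], dtype=float)
    return _rec(counts, "toy")


class TestBuildProfile:
    def test_uniform_column_has_zero_information(self):
        counts = np.ones((4, 5))
        prof = build_profile(_rec(counts))
        np.testing.assert_allclose(prof.info, 0.0, atol=1e-6)

    def test_pure_column_information_is_ln4(self):
        counts = np.zeros((4, 6))
        counts[0, :] = 1.0
        prof = build_profile(_rec(counts, pseudocount=0.0))
        np.testing.assert_allclose(prof.info, math.log(4), atol=1e-12)

    def test_frequency_columns_sum_to_one(self):
        prof = build_profile(_toy_record())
        np.testing.assert_allclose(prof.freqs.sum(axis=0), 1.0, atol=1e-12)

    def test_leftmost_core_window_on_ties(self):
        counts = np.zeros((4, 7))
        counts[0, :] = 1.0  # all positions equally informative
        prof = build_profile(_rec(counts, pseudocount=0.0))
        assert prof.core_start == 0

    def test_core_tracks_most_informative_window(self):
        counts = np.ones((4, 8))
        for i in range(3, 8):
            counts[:, i] = [20, 0, 0, 0]
        prof = build_profile(_rec(counts))
        assert prof.core_start == 3

    def test_too_short_matrix_is_error(self):
        with pytest.raises(StemtraceError):
            PWMRecord(name="short", counts=np.ones((4, 4)))


def brute_force_scores(profile, window):
    """Independent oracle: min-max normalize over all 4^L windows."""
    L = profile.length
    w = profile.info[None, :] * profile.freqs

    def raw(win, sl):
        return sum(w[ALPHABET.index(b), i] for i, b in enumerate(win) if sl.start <= i < sl.stop)

    full = slice(0, L)
    core = slice(profile.core_start, profile.core_start + 5)
    all_windows = ["".join(p) for p in itertools.product(ALPHABET, repeat=L)]
    raws_full = [raw(win, full) for win in all_windows]
    raws_core = [raw(win, core) for win in all_windows]
    cf, cc = raw(window, full), raw(window, core)
    mss = (cf - min(raws_full)) / (max(raws_full) - min(raws_full))
    css = (cc - min(raws_core)) / (max(raws_core) - min(raws_core))
    return mss, css


class TestMatchScores:
    def test_consensus_scores_one(self):
        prof = build_profile(_toy_record())
        consensus = "".join(ALPHABET[i] for i in prof.freqs.argmax(axis=0))
        mss, css = match_scores(prof, consensus)
        assert mss == pytest.approx(1.0, abs=1e-12)
        assert css == pytest.approx(1.0, abs=1e-12)

    def test_anticonsensus_scores_zero(self):
        prof = build_profile(_toy_record())
        anti = "".join(ALPHABET[i] for i in prof.freqs.argmin(axis=0))
        mss, _ = match_scores(prof, anti)
        assert mss == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_window_oracle(self):
        prof = build_profile(_toy_record())
        rng = np.random.default_rng(0)
        for _ in range(10):
            window = "".join(rng.choice(list(ALPHABET), 5))
            mss, css = match_scores(prof, window)
            o_mss, o_css = brute_force_scores(prof, window)
            assert mss == pytest.approx(o_mss, abs=1e-10)
            assert css == pytest.approx(o_css, abs=1e-10)

    def test_scores_bounded(self):
        prof = build_profile(_toy_record())
        rng = np.random.default_rng(1)
        for _ in range(50):
            window = "".join(rng.choice(list(ALPHABET), 5))
            mss, css = match_scores(prof, window)
            assert 0.0 <= mss <= 1.0
            assert 0.0 <= css <= 1.0

    def test_invariant_under_count_rescaling(self):
        rec = _toy_record()
        scaled = _rec(rec.counts * 7.5, "scaled", pseudocount=0.0)
        unscaled = _rec(rec.counts, "raw", pseudocount=0.0)
        p1, p2 = build_profile(unscaled), build_profile(scaled)
        for window in ("ACGTA", "TTTTT", "GCGCG"):
            assert match_scores(p1, window) == pytest.approx(match_scores(p2, window))

    def test_ambiguous_base_scores_position_minimum(self):
        prof = build_profile(_toy_record())
        mss_n, _ = match_scores(prof, "NCGTA")
        anti_first = ALPHABET[prof.freqs[:, 0].argmin()]
        mss_min, _ = match_scores(prof, anti_first + "CGTA")
        assert mss_n == pytest.approx(mss_min, abs=1e-12)

    def test_wrong_window_length_is_error(self):
        prof = build_profile(_toy_record())
        with pytest.raises(StemtraceError):
            match_scores(prof, "ACGTAA")


class TestExtractPromoters:
    GENOME = {"chr1": "".join(
        np.random.default_rng(9).choice(list(ALPHABET), 5000)
    )}

    def _tx(self, tss, strand, name="tx"):
        return pd.DataFrame([("chr1", tss, strand, name)],
                            columns=["chrom", "tss", "strand", "name"])

    def test_plus_strand_window(self):
        out = extract_promoters(self.GENOME, self._tx(2000, "+"), 2000)
        assert out["tx"] == self.GENOME["chr1"][:2000].upper()

    def test_plus_strand_truncated_at_contig_start(self):
        out = extract_promoters(self.GENOME, self._tx(100, "+"), 2000)
        assert len(out["tx"]) == 100

    def test_minus_strand_reverse_complement(self):
        out = extract_promoters(self.GENOME, self._tx(1000, "-"), 2000)
        assert out["tx"] == reverse_complement(self.GENOME["chr1"][1000:3000]).upper()

    def test_unknown_contig_skipped(self):
        tx = pd.DataFrame([("chrX", 10, "+", "tx")],
                          columns=["chrom", "tss", "strand", "name"])
        assert extract_promoters(self.GENOME, tx, 100) == {}


class TestScanPromoters:
    def test_planted_consensus_found_at_strict_cutoffs(self):
        prof = build_profile(_toy_record())
        consensus = "".join(ALPHABET[i] for i in prof.freqs.argmax(axis=0))
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("AC"), 60))  # avoid chance consensus
        seq = bg[:30] + consensus + bg[30:]
        cfg = AnalysisConfig(css_cutoff=1.0, mss_cutoffs={"toy": 0.999})
        hits = scan_promoters({"p1": seq}, [prof], cfg)
        forward = [h for h in hits if h.strand == "+"]
        assert len(forward) == 1
        assert forward[0].offset == 30
        assert forward[0].mss == pytest.approx(1.0)

    def test_strand_symmetry(self):
        prof = build_profile(_toy_record())
        consensus = "".join(ALPHABET[i] for i in prof.freqs.argmax(axis=0))
        seq = "CC" + reverse_complement(consensus) + "CC"
        cfg = AnalysisConfig(css_cutoff=1.0, mss_cutoffs={"toy": 0.999})
        hits = scan_promoters({"p": seq}, [prof], cfg)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].offset == 2

    def test_empty_promoter_set(self):
        prof = build_profile(_toy_record())
        assert scan_promoters({}, [prof], AnalysisConfig()) == []

    def test_random_sequence_rarely_hits_at_strict_cutoffs(self):
        prof = build_profile(_toy_record())
        cfg = AnalysisConfig(css_cutoff=1.0, mss_cutoffs={"toy": 0.999})
        rng = np.random.default_rng(3)
        n_hits = 0
        for _ in range(50):
            seq = "".join(rng.choice(list(ALPHABET), 200))
            n_hits += len(scan_promoters({"p": seq}, [prof], cfg))
        # consensus probability ~ (1/4)^5 per strand and position
        assert n_hits <= 50 * 400 * 2 * (0.25**5) * 5

    def test_gene_hit_count_summary(self):
        prof = build_profile(_toy_record())
        consensus = "".join(ALPHABET[i] for i in prof.freqs.argmax(axis=0))
        cfg = AnalysisConfig(css_cutoff=1.0, mss_cutoffs={"toy": 0.999})
        hits = scan_promoters(
            {"g1": "CC" + consensus, "g2": "CCCCCCCCCC"}, [prof], cfg
        )
        counts = gene_hit_counts(hits, {"setA": ["g1", "g2"], "setB": ["g2"]})
        assert counts.loc["toy", "setA"] == 1
        assert counts.loc["toy", "setB"] == 0


def test_planted_sites_recovered_in_simulation(default_sim):
    """Every planted consensus site is found at core similarity 1."""
    sim = default_sim
    profiles = [build_profile(r) for r in sim.pwms]
    cfg = AnalysisConfig(css_cutoff=1.0,
                         mss_cutoffs={r.name: 0.999 for r in sim.pwms})
    hits = scan_promoters(sim.promoters, profiles, cfg)
    found = {(h.sequence_id, h.matrix, h.offset) for h in hits}
    for (gene, matrix), positions in sim.truth.planted_motif_sites.items():
        for pos in positions:
            assert (gene, matrix, pos) in found
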