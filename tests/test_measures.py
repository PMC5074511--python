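import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemtrace.datatypes import (
    ExpressionMatrix,
    InteractionNetwork,
    OntologyAnnotation,
    SignatureSet,
    StemtraceError,
    edge,
)
from stemtrace.measures import (
    SemanticSimilarity,
    bma_combine,
    compute_ic,
    gss_population,
    gss_sample,
    lin_sim,
    mean_shortest_path,
    overlap_pvalue,
    setsim_bma,
)


def enumeration_overlap_pvalue(n_universe, n_a, n_b, q):
    """Brute-force oracle: enumerate all draws of n_b items from the
    universe and count those sharing >= q items with a fixed n_a-set."""
    hits = total = 0
    marked = set(range(n_a))
    for draw in itertools.combinations(range(n_universe), n_b):
        total += 1
        if len(marked.intersection(draw)) >= q:
            hits += 1
    return hits / total


class TestOverlapPvalue:
    def test_zero_overlap_gives_one(self):
        u = {f"g{i}" for i in range(10)}
        assert overlap_pvalue({"g0"}, {"g5"}, u) == 1.0

    def test_complete_overlap_small_universe(self):
        u = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        assert overlap_pvalue(a, set(a), u) == pytest.approx(1 / 252, abs=1e-12)

    def test_closed_form_sum(self):
        u = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(6)}
        b = {f"g{i}" for i in range(3)} | {"g10", "g11"}  # overlap 3
        expected = sum(
            math.comb(6, x) * math.comb(14, 5 - x) / math.comb(20, 5) for x in range(3, 6)
        )
        assert overlap_pvalue(a, b, u) == pytest.approx(expected, abs=1e-12)

    def test_sets_outside_universe_error(self):
        with pytest.raises(StemtraceError):
            overlap_pvalue({"x"}, {"y"}, {"y"})

    @given(
        n=st.integers(2, 12),
        data=st.data(),
    )
    @settings(max_examples=25, deadline=None)
    def test_matches_enumeration_oracle(self, n, data):
        n_a = data.draw(st.integers(0, n))
        n_b = data.draw(st.integers(1, n))
        u = {f"g{i}" for i in range(n)}
        a = {f"g{i}" for i in range(n_a)}
        b_idx = data.draw(
            st.lists(st.integers(0, n - 1), min_size=1, max_size=n, unique=True)
        )[:n_b]
        b = {f"g{i}" for i in b_idx}
        expected = enumeration_overlap_pvalue(n, n_a, len(b), len(a & b)) if a & b else 1.0
        assert overlap_pvalue(a, b, u) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_overlap(self):
        u = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(10)}
        prev = 1.1
        for q in range(1, 9):
            b = {f"g{i}" for i in range(q)} | {f"g{20 + i}" for i in range(8 - q)}
            p = overlap_pvalue(a, b, u)
            assert p < prev
            prev = p


def _signature(genes, fcs):
    return SignatureSet(
        label="t.up" if all(f > 0 for f in fcs) else "t.mixed",
        genes=list(genes),
        log2fc=dict(zip(genes, fcs)),
        pvalue={g: 0.01 for g in genes},
        direction="up" if all(f > 0 for f in fcs) else "down",
    )


def _expr(gene_ids, values, groups):
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        groups=dict(zip(sample_ids, groups)),
    )


class TestGSS:
    def test_centered_data_scores_zero(self):
        expr = _expr(["g1", "g2"], [[5, 5], [7, 7]], ["A", "A"])
        sig = _signature(["g1", "g2"], [1.5, 2.0])
        assert gss_sample(sig, expr, "s1") == 0.0

    def test_single_gene_direct_evaluation(self):
        # x = 2, y - z = 1 -> (2 * 1) / |2| = 1
        expr = _expr(["g1"], [[9.0, 7.0]], ["A", "A"])  # mean 8, sample1 y=9
        sig = _signature(["g1"], [2.0])
        assert gss_sample(sig, expr, "s1") == pytest.approx(1.0, abs=1e-12)

    def test_mixed_direction_perfect_concordance(self):
        # x = (1, -1), y - z = (1, -1) -> (1 + 1) / 2 = 1
        expr = _expr(["g1", "g2"], [[9.0, 7.0], [7.0, 9.0]], ["A", "A"])
        assert gss_sample({"g1": 1.0, "g2": -1.0}, expr, "s1") == pytest.approx(1.0, abs=1e-12)

    def test_negating_fold_changes_negates_score(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(5, 4))
        expr = _expr([f"g{i}" for i in range(5)], vals, ["A"] * 4)
        genes = expr.gene_ids
        fcs = [1.0, 2.0, 0.5, 1.5, 3.0]
        pos = _signature(genes, fcs)
        neg = SignatureSet(
            label="neg", genes=genes, log2fc={g: -f for g, f in zip(genes, fcs)},
            pvalue={g: 0.01 for g in genes}, direction="down",
        )
        s = gss_sample(pos, expr, "s2")
        assert gss_sample(neg, expr, "s2") == pytest.approx(-s, abs=1e-12)

    def test_invariant_to_constant_gene_shift(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1, size=(3, 4))
        genes = ["g1", "g2", "g3"]
        sig = _signature(genes, [1.0, 2.0, 3.0])
        base = gss_sample(sig, _expr(genes, vals, ["A"] * 4), "s3")
        shifted = vals + np.array([[10.0], [-4.0], [2.5]])
        assert gss_sample(sig, _expr(genes, shifted, ["A"] * 4), "s3") == pytest.approx(
            base, abs=1e-9
        )

    def test_population_mean_and_identical_samples(self):
        vals = np.array([[9.0, 9.0, 7.0], [6.0, 6.0, 9.0]])
        expr = _expr(["g1", "g2"], vals, ["P", "P", "Q"])
        sig = _signature(["g1", "g2"], [2.0, 1.0])
        s1 = gss_sample(sig, expr, "s1")
        assert gss_population(sig, expr, "P") == pytest.approx(s1)

    def test_absent_genes_yield_nan(self):
        expr = _expr(["gX"], [[1.0, 2.0]], ["A", "A"])
        sig = _signature(["g1"], [1.0])
        assert math.isnan(gss_sample(sig, expr, "s1"))


class TestSemanticSimilarity:
    def test_ic_values_on_chain(self, chain_ontology):
        onto = chain_ontology
        assert onto.ic["root"] == 0.0
        assert onto.ic["t1"] == pytest.approx(-math.log(2 / 4))
        assert onto.ic["t2"] == pytest.approx(-math.log(1 / 4))

    def test_ic_antitone_child_to_parent(self, default_sim):
        onto = compute_ic(default_sim.ontology)
        for t, parents in onto.parents.items():
            if t not in onto.ic:
                continue
            for p in parents:
                assert onto.ic[t] >= onto.ic[p] - 1e-12

    def test_self_similarity_is_one(self, chain_ontology):
        assert lin_sim("t2", "t2", chain_ontology) == 1.0

    def test_root_only_common_ancestor_gives_zero(self):
        onto = OntologyAnnotation(
            terms={"root", "a", "b"},
            parents={"a": {"root"}, "b": {"root"}},
            root="root",
            gene2terms={"g1": {"a"}, "g2": {"b"}},
        )
        compute_ic(onto)
        assert lin_sim("a", "b", onto) == 0.0
        assert setsim_bma({"g1"}, {"g2"}, onto) == 0.0

    def test_chain_hand_value(self, chain_ontology):
        # MICA of (t1, t2) is t1: 2 ln2 / (ln2 + ln4) = 2/3 ~ 0.663 with
        # the hand-rounded ICs 0.69 and 1.39
        val = lin_sim("t1", "t2", chain_ontology)
        assert val == pytest.approx(2 / 3, abs=1e-12)
        assert val == pytest.approx(0.663, abs=0.005)

    def test_unknown_term_is_error(self, chain_ontology):
        with pytest.raises(StemtraceError):
            lin_sim("t1", "nope", chain_ontology)

    def test_identical_singletons_score_one(self, chain_ontology):
        assert setsim_bma({"g1"}, {"g1"}, chain_ontology) == 1.0

    def test_bma_of_printed_matrix(self):
        m = np.array([[1.0, 0.2], [0.4, 0.6]])
        assert bma_combine(m) == pytest.approx(0.8, abs=1e-12)

    def test_set_similarity_symmetric_and_bounded(self, default_sim):
        sem = SemanticSimilarity(default_sim.ontology)
        rng = np.random.default_rng(0)
        genes = sorted(default_sim.ontology.gene2terms)
        a = list(rng.choice(genes, 12, replace=False))
        b = list(rng.choice(genes, 15, replace=False))
        ab, _ = sem.set_sim(a, b)
        ba, _ = sem.set_sim(b, a)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 <= ab <= 1.0

    def test_vectorized_matches_pairwise_lin(self, chain_ontology):
        """The cached profile matrix agrees with direct lin_sim BMA."""
        onto = chain_ontology
        sem = SemanticSimilarity(onto)
        m = sem.gene_sim_matrix(["g1"], ["g2"])
        assert m[0, 0] == pytest.approx(lin_sim("t2", "t1", onto), abs=1e-12)


class TestShortestPath:
    def test_single_pair_path_graph(self, path_network):
        assert mean_shortest_path({"a"}, {"c"}, path_network) == 2.0

    def test_two_sources_hand_mean(self, path_network):
        assert mean_shortest_path({"a", "b"}, {"c"}, path_network) == pytest.approx(1.5)

    def test_shared_gene_excluded_from_self_pairing(self, path_network):
        assert mean_shortest_path({"a"}, {"a", "c"}, path_network) == 2.0

    def test_disconnected_pairs_excluded(self):
        net = InteractionNetwork(
            nodes={"a", "b", "x", "y"}, edges={edge("a", "b"), edge("x", "y")}
        )
        assert mean_shortest_path({"a"}, {"b", "x"}, net) == 1.0

    def test_no_connected_pair_gives_nan(self):
        net = InteractionNetwork(nodes={"a", "b"}, edges=set())
        assert math.isnan(mean_shortest_path({"a"}, {"b"}, net))

    def test_symmetry(self, default_sim):
        net = default_sim.network
        rng = np.random.default_rng(1)
        genes = sorted(net.nodes)
        a = set(rng.choice(genes, 10, replace=False))
        b = set(rng.choice(genes, 10, replace=False))
        assert mean_shortest_path(a, b, net) == pytest.approx(
            mean_shortest_path(b, a, net), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(40, 0.08, seed=seed)
        nodes = [f"n{i}" for i in g.nodes]
        net = InteractionNetwork(
            nodes=set(nodes),
            edges={edge(f"n{u}", f"n{v}") for u, v in g.edges},
        )
        a = set(rng.choice(nodes, 8, replace=False))
        b = set(rng.choice(nodes, 8, replace=False))
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        vals = [
            lengths[int(x[1:])][int(y[1:])]
            for x in a
            for y in b
            if x != y and int(y[1:]) in lengths[int(x[1:])]
        ]
        if not vals:
            assert math.isnan(mean_shortest_path(a, b, net))
        else:
            assert mean_shortest_path(a, b, net) == pytest.approx(np.mean(vals), abs=1e-12)
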