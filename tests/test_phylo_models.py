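import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

from clockdiv.io_formats import Msa, SequenceRecord, read_newick
from clockdiv.phylo_models import (
    AA_INDEX,
    AA_ORDER,
    _Propagator,
    base_model,
    build_rate_matrix,
    discrete_gamma_rates,
    load_empirical,
    model_from_name,
    poisson_model,
    prune_loglik,
    select_model,
    transition_probs,
)
from clockdiv.synthetic_data import simulate_alignment

MODELS = ["JTT", "LG", "Dayhoff", "WAG"]


class TestRateMatrix:
    @pytest.mark.parametrize("name", MODELS)
    def test_rows_sum_to_zero_and_unit_rate(self, name):
        m = base_model(name)
        Q = build_rate_matrix(m)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(m.frequencies * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("name", MODELS)
    def test_detailed_balance(self, name):
        m = base_model(name)
        Q = build_rate_matrix(m)
        flux = m.frequencies[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_poisson_closed_form(self):
        # equal exchangeabilities + uniform pi: Q(i,j) = 1/19 off-diagonal
        Q = build_rate_matrix(poisson_model())
        off = Q[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 19, atol=1e-12)
        np.testing.assert_allclose(np.diag(Q), -1.0, atol=1e-12)


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(transition_probs(base_model("LG"), 0.0), np.eye(20), atol=1e-10)

    def test_ergodic_limit_is_pi(self):
        m = base_model("JTT")
        P = transition_probs(m, 500.0)
        np.testing.assert_allclose(P, np.tile(m.frequencies, (20, 1)), atol=1e-6)

    def test_chapman_kolmogorov(self):
        m = base_model("WAG")
        P1 = transition_probs(m, 0.35)
        np.testing.assert_allclose(P1 @ P1, transition_probs(m, 0.7), atol=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(base_model("LG"), -0.1)

    def test_rows_stochastic(self):
        P = transition_probs(base_model("Dayhoff"), 1.3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0


class TestDiscreteGamma:
    def test_single_category(self):
        np.testing.assert_array_equal(discrete_gamma_rates(1.0, 1), [1.0])

    def test_vanishing_heterogeneity(self):
        rates = discrete_gamma_rates(1e6, 4)
        np.testing.assert_allclose(rates, 1.0, atol=2e-3)

    def test_mean_exactly_one(self):
        for alpha in (0.1, 0.5, 1.0, 3.0):
            assert discrete_gamma_rates(alpha, 4).mean() == pytest.approx(1.0, abs=1e-14)

    def test_matches_quadrature_oracle(self):
        alpha, k = 0.5, 4
        qs = stats.gamma.ppf(np.arange(1, k) / k, alpha, scale=1 / alpha)
        bounds = np.concatenate([[0], qs, [np.inf]])
        oracle = np.array(
            [
                integrate.quad(lambda x: x * stats.gamma.pdf(x, alpha, scale=1 / alpha), bounds[i], bounds[i + 1])[0]
                * k
                for i in range(k)
            ]
        )
        oracle /= oracle.mean()
        np.testing.assert_allclose(discrete_gamma_rates(alpha, k), oracle, atol=1e-6)


def brute_force_loglik(tree_newick, msa, model):
    """Sum over all internal-state assignments (rooted at the seed node)."""
    tree = read_newick(tree_newick)
    prop = _Propagator.from_model(model)
    nodes = list(tree.seed_node.postorder_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
    pi = model.frequencies
    P = {id(n): prop.probs(n.edge.length or 0.0) for n in nodes if n.parent_node is not None}
    row = {r.id: r.residues for r in msa.records}
    ll = 0.0
    for site in range(msa.n_cols):
        total = 0.0
        for states in itertools.product(range(20), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, states)}
            for label, node in leaves.items():
                assign[id(node)] = AA_INDEX[row[label][site]]
            p = pi[assign[id(tree.seed_node)]]
            for n in nodes:
                if n.parent_node is not None:
                    p *= P[id(n)][assign[id(n.parent_node)], assign[id(n)]]
            total += p
        ll += math.log(total)
    return ll


class TestPruning:
    def test_zero_branches_identical_sequences(self):
        msa = Msa((SequenceRecord("A", "MKV"), SequenceRecord("B", "MKV")))
        m = base_model("JTT")
        res = prune_loglik(read_newick("(A:0,B:0);"), msa, m)
        expected = sum(math.log(m.frequencies[AA_INDEX[c]]) for c in "MKV")
        assert res.loglik == pytest.approx(expected, abs=1e-10)

    def test_per_site_sums_to_total(self):
        msa = Msa((SequenceRecord("A", "MKVL"), SequenceRecord("B", "MRVL"), SequenceRecord("C", "MKIL")))
        res = prune_loglik(read_newick("((A:0.2,B:0.3):0.1,C:0.4);"), msa, base_model("LG"))
        assert res.per_site.sum() == pytest.approx(res.loglik, abs=1e-8)

    @pytest.mark.parametrize(
        "newick,seqs",
        [
            ("((A:0.3,B:0.5):0.2,C:0.9);", {"A": "MK", "B": "ML", "C": "MR"}),
            ("((A:0.1,B:0.6):0.3,(C:0.2,D:0.4):0.2);", {"A": "FY", "B": "FW", "C": "LY", "D": "IV"}),
        ],
    )
    def test_matches_exhaustive_enumeration(self, newick, seqs):
        msa = Msa(tuple(SequenceRecord(k, v) for k, v in seqs.items()))
        m = base_model("JTT")
        got = prune_loglik(read_newick(newick), msa, m).loglik
        want = brute_force_loglik(newick, msa, m)
        assert got == pytest.approx(want, abs=1e-10)

    def test_gamma_average_matches_manual_mixture(self):
        newick = "(A:0.4,B:0.7);"
        msa = Msa((SequenceRecord("A", "MKW"), SequenceRecord("B", "MRW")))
        m = replace(base_model("LG"), alpha=0.6)
        got = prune_loglik(read_newick(newick), msa, m).loglik
        rates = discrete_gamma_rates(0.6, 4)
        manual = 0.0
        for site in range(3):
            mix = 0.0
            for r in rates:
                scaled = read_newick(f"(A:{0.4 * r},B:{0.7 * r});")
                sub = Msa((msa.records[0], msa.records[1]))
                mix += math.exp(prune_loglik(scaled, sub, base_model("LG")).per_site[site]) / 4
            manual += math.log(mix)
        assert got == pytest.approx(manual, abs=1e-10)

    def test_invariant_component(self):
        newick = "(A:0.4,B:0.4);"
        msa = Msa((SequenceRecord("A", "MM"), SequenceRecord("B", "MK")))
        m = replace(base_model("JTT"), p_inv=0.3)
        got = prune_loglik(read_newick(newick), msa, m)
        plain = prune_loglik(read_newick("(A:0.4,B:0.4);"), msa, base_model("JTT")).per_site
        pi_m = m.frequencies[AA_INDEX["M"]]
        site0 = 0.3 * pi_m + 0.7 * math.exp(plain[0])  # constant column
        site1 = 0.7 * math.exp(plain[1])  # variable column: no invariant mass
        assert got.loglik == pytest.approx(math.log(site0) + math.log(site1), abs=1e-10)

    def test_gaps_are_missing_data(self):
        msa = Msa((SequenceRecord("A", "M-"), SequenceRecord("B", "MX")))
        res = prune_loglik(read_newick("(A:0.2,B:0.2);"), msa, base_model("JTT"))
        # column 2 carries no information: its likelihood is 1
        assert res.per_site[1] == pytest.approx(0.0, abs=1e-12)

    def test_leaf_mismatch_lists_difference(self, tiny_msa):
        with pytest.raises(ValueError, match="only in tree"):
            prune_loglik(read_newick("((A:1,B:1):1,Z:1);"), tiny_msa, base_model("JTT"))

    def test_invariant_under_row_reordering(self):
        m = base_model("WAG")
        recs = (SequenceRecord("A", "MKVL"), SequenceRecord("B", "MRVL"), SequenceRecord("C", "MKIL"))
        t = "((A:0.2,B:0.3):0.1,C:0.4);"
        ll1 = prune_loglik(read_newick(t), Msa(recs), m).loglik
        ll2 = prune_loglik(read_newick(t), Msa(recs[::-1]), m).loglik
        assert ll1 == pytest.approx(ll2, abs=1e-10)


@pytest.fixture(scope="module")
def gamma_data():
    tree = read_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.3):0.1);")
    model = replace(base_model("JTT"), alpha=0.3)
    return tree, simulate_alignment(tree, model, 500, 7)


class TestModelSelection:

    def test_gamma_model_wins_on_heterogeneous_data(self, gamma_data):
        tree, msa = gamma_data
        best, table = select_model(msa, tree, ["Poisson", "Poisson+G", "JTT", "JTT+G"])
        assert best.name == "JTT+G"
        assert 0.15 < best.alpha < 0.6

    def test_added_parameter_never_hurts_optimized_loglik(self, gamma_data):
        tree, msa = gamma_data
        _, table = select_model(msa, tree, ["JTT", "JTT+G", "JTT+I+G"])
        ll = dict(zip(table["name"], table["logL"]))
        assert ll["JTT+G"] >= ll["JTT"] - 1e-6
        assert ll["JTT+I+G"] >= ll["JTT+G"] - 1e-6

    def test_duplicate_candidates_first_wins(self, gamma_data):
        tree, msa = gamma_data
        best, table = select_model(msa, tree, ["JTT+G", "JTT+G"])
        assert best.name == "JTT+G"
        assert len(table) == 2

    def test_empty_candidates_rejected(self, gamma_data):
        tree, msa = gamma_data
        with pytest.raises(ValueError):
            select_model(msa, tree, [])

    def test_plus_F_uses_observed_frequencies(self, gamma_data):
        _, msa = gamma_data
        m = model_from_name("LG+F", msa)
        assert m.plus_F and m.n_free_params == 19
        base = model_from_name("LG")
        assert not np.allclose(m.frequencies, base.frequencies)
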