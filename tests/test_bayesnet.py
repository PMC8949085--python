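"""CPT estimation, exact inference, MCMC structure sampling, arc strength."""

import itertools

import numpy as np
import pandas as pd
import pytest

from credfuse.bayesnet import (
    ArcStrengthTable,
    BayesNetError,
    arc_strength,
    bdeu_score,
    conditional_query,
    dep_causal_strength,
    fit_cpts,
    joint_probability,
    sample_structures_mcmc,
)


def drug_reaction_data(n=100, n_yes=51):
    return pd.DataFrame(
        {
            "drug": ["Dactomicin"] * n,
            "reaction": ["yes"] * n_yes + ["no"] * (n - n_yes),
        }
    )


class TestFitCpts:
    def test_laplace_smoothed_frequency(self):
        # 51 of 100 exposures with a reaction -> (51+1)/(100+2)
        data = drug_reaction_data()
        data["drug"] = ["Dactomicin"] * 50 + ["Morphine"] * 50  # vary the parent
        net = fit_cpts(data, [("drug", "reaction")])
        i_dact = net.states["drug"].index("Dactomicin")
        i_yes = net.states["reaction"].index("yes")
        # Dactomicin rows are the 50 first (all reaction=yes)
        assert net.cpts["reaction"][i_dact, i_yes] == pytest.approx((50 + 1) / (50 + 2))

    def test_marginal_when_no_parents(self):
        data = drug_reaction_data()
        net = fit_cpts(data[["reaction"]], [])
        i_yes = net.states["reaction"].index("yes")
        assert net.cpts["reaction"][i_yes] == pytest.approx((51 + 1) / (100 + 2))

    def test_deterministic_link_approaches_one(self):
        n = 5000
        data = pd.DataFrame({"disease": ["flu"] * n + ["cold"] * n})
        data["symptom"] = np.where(data["disease"] == "flu", "fever", "none")
        net = fit_cpts(data, [("disease", "symptom")])
        i_flu = net.states["disease"].index("flu")
        i_fev = net.states["symptom"].index("fever")
        assert net.cpts["symptom"][i_flu, i_fev] == pytest.approx((n + 1) / (n + 2))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.integers(0, 3, size=(200, 3)), columns=list("abc"))
        net = fit_cpts(data, [("a", "c"), ("b", "c")])
        rows = net.cpts["c"].reshape(-1, 3)
        np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_cyclic_dag_rejected(self):
        data = pd.DataFrame({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(BayesNetError):
            fit_cpts(data, [("a", "b"), ("b", "a")])

    def test_unknown_node_rejected(self):
        with pytest.raises(BayesNetError):
            fit_cpts(pd.DataFrame({"a": [0, 1]}), [("a", "ghost")])


class TestJointAndQuery:
    @pytest.fixture()
    def two_node_net(self):
        # P(A=1) = 0.5 and P(B=1 | A=1) = 0.51 (emission-table style)
        return_states = {"A": (0, 1), "B": (0, 1)}
        cpts = {
            "A": np.array([0.5, 0.5]),
            "B": np.array([[0.8, 0.2], [0.49, 0.51]]),
        }
        from credfuse.bayesnet import DiscreteBayesNet

        return DiscreteBayesNet(return_states, {"A": (), "B": ("A",)}, cpts)

    def test_chain_rule_product(self, two_node_net):
        assert joint_probability(two_node_net, {"A": 1, "B": 1}) == pytest.approx(0.255)

    def test_zero_entry_annihilates(self):
        from credfuse.bayesnet import DiscreteBayesNet

        net = DiscreteBayesNet(
            {"A": (0, 1)}, {"A": ()}, {"A": np.array([1.0, 0.0])}
        )
        assert joint_probability(net, {"A": 1}) == 0.0

    def test_missing_node_rejected(self, two_node_net):
        with pytest.raises(BayesNetError):
            joint_probability(two_node_net, {"A": 1})

    def test_query_no_evidence_is_marginal(self, two_node_net):
        marg = conditional_query(two_node_net, "B")
        assert marg[1] == pytest.approx(0.5 * 0.2 + 0.5 * 0.51)

    def test_collider_query_matches_tensor_oracle(self):
        # disease -> symptom <- drug, with an independent tensor-product oracle
        rng = np.random.default_rng(3)
        from credfuse.bayesnet import DiscreteBayesNet

        p_d = rng.dirichlet([1, 1])
        p_g = rng.dirichlet([1, 1])
        p_s = rng.dirichlet([1, 1], size=(2, 2))
        net = DiscreteBayesNet(
            {"disease": (0, 1), "drug": (0, 1), "symptom": (0, 1)},
            {"disease": (), "drug": (), "symptom": ("disease", "drug")},
            {"disease": p_d, "drug": p_g, "symptom": p_s},
        )
        joint = np.einsum("i,j,ijk->ijk", p_d, p_g, p_s)
        expected = joint[:, 1, :].sum(axis=0) / joint[:, 1, :].sum()
        got = conditional_query(net, "symptom", {"drug": 1})
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_query_agrees_with_full_joint_on_random_small_nets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        names = [f"x{i}" for i in range(n)]
        data = pd.DataFrame(rng.integers(0, 2, size=(300, n)), columns=names)
        edges = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.4]
        net = fit_cpts(data, edges)
        # oracle: explicit joint table by brute-force enumeration
        joint = {}
        for cfg in itertools.product((0, 1), repeat=n):
            joint[cfg] = joint_probability(net, dict(zip(names, cfg)))
        target, evid_var = names[0], names[-1]
        num = {0: 0.0, 1: 0.0}
        for cfg, p in joint.items():
            if cfg[-1] == 1:
                num[cfg[0]] += p
        z = num[0] + num[1]
        got = conditional_query(net, target, {evid_var: 1})
        assert got[0] == pytest.approx(num[0] / z, abs=1e-10)

    def test_impossible_evidence_rejected(self):
        from credfuse.bayesnet import DiscreteBayesNet

        net = DiscreteBayesNet(
            {"A": (0, 1), "B": (0, 1)},
            {"A": (), "B": ("A",)},
            {"A": np.array([1.0, 0.0]), "B": np.array([[1.0, 0.0], [0.5, 0.5]])},
        )
        with pytest.raises(BayesNetError, match="impossible evidence"):
            conditional_query(net, "B", {"A": 1})


class TestMCMC:
    def test_same_seed_identical_samples(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.integers(0, 2, size=(300, 3)), columns=list("abc"))
        s1 = sample_structures_mcmc(data, 500, 100, seed=9)
        s2 = sample_structures_mcmc(data, 500, 100, seed=9)
        assert s1 == s2

    def test_independent_variables_rarely_linked(self):
        rng = np.random.default_rng(21)
        data = pd.DataFrame(
            {"u": rng.integers(0, 2, 2000), "v": rng.integers(0, 2, 2000)}
        )
        samples = sample_structures_mcmc(data, 4000, 1000, seed=5)
        freq = np.mean([(("u", "v") in s) or (("v", "u") in s) for s in samples])
        assert freq < 0.20

    def test_deterministic_dependence_always_linked(self):
        rng = np.random.default_rng(22)
        disease = rng.integers(0, 2, 2000)
        data = pd.DataFrame({"disease": disease, "symptom": disease})
        samples = sample_structures_mcmc(data, 4000, 1000, seed=5)
        freq = np.mean(
            [(("disease", "symptom") in s) or (("symptom", "disease") in s) for s in samples]
        )
        assert freq > 0.95

    def test_never_visits_cycle_and_respects_parent_cap(self):
        rng = np.random.default_rng(23)
        data = pd.DataFrame(rng.integers(0, 2, size=(200, 5)), columns=list("abcde"))
        import networkx as nx

        for sample in sample_structures_mcmc(data, 600, 0, seed=1, max_parents=2)[::50]:
            g = nx.DiGraph(list(sample))
            assert nx.is_directed_acyclic_graph(g)
            assert all(d <= 2 for _, d in g.in_degree())

    def test_bad_iteration_counts_rejected(self):
        data = pd.DataFrame({"a": [0, 1], "b": [0, 1]})
        with pytest.raises(BayesNetError):
            sample_structures_mcmc(data, 100, 100, seed=0)

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"a": [0, 1, 0], "flat": [1, 1, 1]})
        with pytest.raises(BayesNetError, match="flat"):
            sample_structures_mcmc(data, 10, 0, seed=0)

    def test_score_invariant_to_constant_shift(self):
        # acceptance uses score differences only: adding the same constant to
        # every family score leaves the BDeu *difference* between two graphs
        # unchanged, so equality of scores computed independently suffices
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.integers(0, 2, size=(100, 3)), columns=list("abc"))
        d1 = bdeu_score(data, [("a", "b")]) - bdeu_score(data, [])
        d2 = (bdeu_score(data, [("a", "b")]) + 0.0) - (bdeu_score(data, []) + 0.0)
        assert d1 == pytest.approx(d2)


class TestArcStrength:
    def test_counting(self):
        e = ("drug", "symptom")
        samples = [frozenset([e])] * 250 + [frozenset()] * 750
        table = arc_strength(samples)
        assert table.strength(*e) == pytest.approx(0.25)
        assert table.n_samples == 1000
        assert (0.25 * 1000) == pytest.approx(round(0.25 * 1000))

    def test_always_and_never(self):
        e = ("a", "b")
        always = arc_strength([frozenset([e])] * 10)
        assert always.strength("a", "b") == 1.0
        never = arc_strength([frozenset()] * 10, nodes=["a", "b"])
        assert never.strength("a", "b") == 0.0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(BayesNetError):
            arc_strength([])

    def test_dep_causal_strength_lookup_and_unknown_node(self):
        table = ArcStrengthTable({("d", "s"): 0.54}, 100, frozenset({"d", "s"}))
        assert dep_causal_strength("d", "s", table) == 0.54
        with pytest.raises(BayesNetError):
            dep_causal_strength("ghost", "s", table)

    def test_undirected_option_sums_orientations(self):
        table = ArcStrengthTable({("d", "s"): 0.3, ("s", "d"): 0.5}, 10, frozenset({"d", "s"}))
        assert dep_causal_strength("d", "s", table) == 0.3
        assert dep_causal_strength("d", "s", table, undirected=True) == pytest.approx(0.8)

    def test_json_round_trip(self, tmp_path):
        table = ArcStrengthTable({("d", "s"): 0.54}, 100, frozenset({"d", "s"}))
        path = tmp_path / "arcs.json"
        table.to_json(path)
        back = ArcStrengthTable.from_json(path)
        assert back.entries == table.entries and back.n_samples == 100


def test_strength_discriminates_true_adjacencies():
    """On data from a known DAG, true edges out-score non-edges on average."""
    rng = np.random.default_rng(17)
    n = 2000
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < 0.8, a, 1 - a)  # a -> b
    c = np.where(rng.random(n) < 0.75, b, rng.integers(0, 2, n))  # b -> c
    d = rng.integers(0, 2, n)  # isolated
    data = pd.DataFrame({"a": a, "b": b, "c": c, "d": d})
    table = arc_strength(sample_structures_mcmc(data, 3000, 500, seed=3), nodes=data.columns)
    true_pairs = [("a", "b"), ("b", "c")]
    non_pairs = [("a", "c"), ("a", "d"), ("b", "d"), ("c", "d")]
    s_true = np.mean([table.strength(u, v, undirected=True) for u, v in true_pairs])
    s_non = np.mean([table.strength(u, v, undirected=True) for u, v in non_pairs])
    assert s_true > s_non
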