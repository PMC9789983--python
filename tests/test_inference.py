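"""Parameter learning and exact inference."""

import numpy as np
import pandas as pd
import pytest

from symptombn import (
    enumerate_joint,
    fit_cpts,
    predict_from_others,
    predict_proba_all,
    query,
    reference_network,
    sample_binary,
)
from symptombn.graph import CPT, DAG, DiscreteBayesianNetwork

from conftest import make_binary_frame


def enumeration_query(network, target, evidence):
    """Brute-force oracle: condition the enumerated joint directly."""
    joint = enumerate_joint(network)
    pos = {n: i for i, n in enumerate(network.nodes)}
    sub = joint
    # fix evidence axes from the highest axis down so indices stay valid
    for node, val in sorted(evidence.items(), key=lambda kv: -pos[kv[0]]):
        sub = np.take(sub, val, axis=pos[node])
    remaining = [n for n in network.nodes if n not in evidence]
    t_ax = remaining.index(target)
    num = np.take(sub, 1, axis=t_ax).sum()
    den = sub.sum()
    if den == 0:
        raise ZeroDivisionError
    return float(num / den)


class TestFitCpts:
    def test_mle_ratio(self):
        df = make_binary_frame({(1, 1): 10, (1, 0): 30, (0, 0): 20}, ["p", "c"])
        dag = DAG(("p", "c"), [("p", "c")])
        net = fit_cpts(df, dag, smoothing_alpha=0.0)
        assert net.cpts["c"].p_present([1]) == pytest.approx(10 / 40)

    def test_laplace_smoothing(self):
        df = make_binary_frame({(1, 1): 10, (1, 0): 30, (0, 0): 20}, ["p", "c"])
        dag = DAG(("p", "c"), [("p", "c")])
        net = fit_cpts(df, dag, smoothing_alpha=1.0)
        assert net.cpts["c"].p_present([1]) == pytest.approx(11 / 42)

    def test_unseen_configuration_flagged_and_half(self):
        df = make_binary_frame({(0, 1): 5, (0, 0): 5}, ["p", "c"])
        dag = DAG(("p", "c"), [("p", "c")])
        net = fit_cpts(df, dag, smoothing_alpha=0.0)
        assert net.cpts["c"].p_present([1]) == 0.5
        assert ("c", 1) in net.diagnostics["unseen_configs"]

    def test_column_mismatch_rejected(self):
        df = make_binary_frame({(0, 1): 5}, ["p", "c"])
        with pytest.raises(ValueError, match="match"):
            fit_cpts(df, DAG(("x", "y")))

    def test_consistency_error_shrinks_with_n(self, ref_net):
        """CPT estimates on data sampled from a known network converge; the
        mean bound leaves headroom for the rarest parent configurations."""
        max_errs, mean_errs = [], []
        for n in (1_000, 10_000, 100_000):
            df = sample_binary(ref_net, n, seed=13)
            fitted = fit_cpts(df, ref_net.dag, smoothing_alpha=0.0)
            diffs = np.concatenate(
                [np.abs(fitted.cpts[c].table - ref_net.cpts[c].table) for c in ref_net.nodes]
            )
            max_errs.append(float(diffs.max()))
            mean_errs.append(float(diffs.mean()))
        assert max_errs[2] < max_errs[0]
        assert mean_errs[2] < 0.005


class TestEnumerateJoint:
    def test_reference_normalisation(self, ref_net):
        joint = enumerate_joint(ref_net)
        assert joint.size == 2048
        assert joint.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_node_marginal(self):
        net = DiscreteBayesianNetwork(DAG(("f",)), {"f": CPT("f", (), [0.647])})
        joint = enumerate_joint(net)
        assert joint[1] == pytest.approx(0.647)
        assert joint[0] == pytest.approx(0.353)

    def test_independent_nodes_give_product_table(self):
        net = DiscreteBayesianNetwork(
            DAG(("a", "b")), {"a": CPT("a", (), [0.3]), "b": CPT("b", (), [0.8])}
        )
        joint = enumerate_joint(net)
        assert joint[1, 1] == pytest.approx(0.3 * 0.8)
        assert joint[0, 1] == pytest.approx(0.7 * 0.8)

    def test_guard_on_node_count(self):
        nodes = tuple(f"v{i}" for i in range(21))
        net = DiscreteBayesianNetwork(
            DAG(nodes), {n: CPT(n, (), [0.5]) for n in nodes}
        )
        with pytest.raises(ValueError, match="query"):
            enumerate_joint(net)


class TestQuery:
    def test_cpt_rows_reproduced_exactly(self, ref_net):
        assert query(ref_net, "lack of appetite", {"fatigue": 1, "dysphagia": 1}).probability == pytest.approx(0.800)
        assert query(ref_net, "fatigue", {}).probability == pytest.approx(0.647)

    def test_bayes_rule_reversal(self, two_node_net):
        # P(F|A+) = 0.647*0.331 / (0.647*0.331 + 0.353*0.086)
        expected = 0.647 * 0.331 / (0.647 * 0.331 + 0.353 * 0.086)
        assert query(two_node_net, "fatigue", {"anxiety": 1}).probability == pytest.approx(expected)
        assert expected == pytest.approx(0.876, abs=5e-4)

    def test_factorisation_property_every_node_and_configuration(self, ref_net):
        """Evidence equal to exactly the parents returns the CPT entry."""
        for node in ref_net.nodes:
            cpt = ref_net.cpts[node]
            k = len(cpt.parents)
            for r in range(2**k):
                bits = [(r >> (k - 1 - i)) & 1 for i in range(k)]
                ev = dict(zip(cpt.parents, bits))
                assert query(ref_net, node, ev).probability == pytest.approx(
                    float(cpt.table[r]), abs=1e-12
                )

    def test_matches_enumeration_on_randomised_queries(self, ref_net):
        rng = np.random.default_rng(99)
        nodes = list(ref_net.nodes)
        for _ in range(300):
            target = nodes[rng.integers(len(nodes))]
            others = [n for n in nodes if n != target]
            k = int(rng.integers(0, len(others) + 1))
            ev_nodes = list(rng.choice(others, size=k, replace=False))
            ev = {n: int(rng.integers(2)) for n in ev_nodes}
            try:
                oracle = enumeration_query(ref_net, target, ev)
            except ZeroDivisionError:
                continue
            assert query(ref_net, target, ev).probability == pytest.approx(oracle, abs=1e-9)

    def test_law_of_total_probability(self, ref_net):
        rng = np.random.default_rng(5)
        nodes = list(ref_net.nodes)
        for _ in range(20):
            target, extra = rng.choice(nodes, size=2, replace=False)
            p_marg = query(ref_net, target, {}).probability
            total = sum(
                query(ref_net, target, {extra: v}).probability
                * query(ref_net, extra, {}).probability ** (1 if v else 0)
                * (1 - query(ref_net, extra, {}).probability) ** (0 if v else 1)
                for v in (0, 1)
            )
            assert total == pytest.approx(p_marg, abs=1e-9)

    def test_zero_probability_evidence_identified(self):
        net = DiscreteBayesianNetwork(
            DAG(("a", "b"), [("a", "b")]),
            {"a": CPT("a", (), [1.0]), "b": CPT("b", ("a",), [0.0, 0.5])},
        )
        with pytest.raises(ValueError, match="probability zero"):
            query(net, "b", {"a": 0})

    def test_target_in_evidence_rejected(self, ref_net):
        with pytest.raises(ValueError, match="evidence"):
            query(ref_net, "pain", {"pain": 1})


class TestPredictFromOthers:
    def test_markov_blanket_screens_off_the_rest(self, ref_net):
        """Adding evidence outside the target's Markov blanket leaves the
        prediction unchanged."""
        target = "constipation"
        dag = ref_net.dag
        blanket = set(dag.parents(target)) | set(dag.children(target))
        for child in dag.children(target):
            blanket |= set(dag.parents(child))
        blanket.discard(target)
        rng = np.random.default_rng(2)
        row = {n: int(rng.integers(2)) for n in ref_net.nodes}
        p_blanket = query(ref_net, target, {n: row[n] for n in blanket}).probability
        p_full = predict_from_others(ref_net, row, target)
        assert p_full == pytest.approx(p_blanket, abs=1e-9)

    def test_agrees_with_enumeration_oracle(self, ref_net):
        rng = np.random.default_rng(3)
        for _ in range(20):
            row = {n: int(rng.integers(2)) for n in ref_net.nodes}
            target = list(ref_net.nodes)[rng.integers(11)]
            ev = {n: v for n, v in row.items() if n != target}
            assert predict_from_others(ref_net, row, target) == pytest.approx(
                enumeration_query(ref_net, target, ev), abs=1e-9
            )

    def test_zero_probability_evidence_falls_back_to_marginal(self, caplog):
        net = DiscreteBayesianNetwork(
            DAG(("a", "b"), [("a", "b")]),
            {"a": CPT("a", (), [1.0]), "b": CPT("b", ("a",), [0.0, 0.5])},
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="symptombn.inference"):
            p = predict_from_others(net, {"a": 0, "b": 1}, "b")
        assert p == pytest.approx(query(net, "b", {}).probability)
        assert "zero-probability" in caplog.text


class TestPredictProbaAll:
    def test_matches_per_row_variable_elimination(self, ref_net):
        df = sample_binary(ref_net, 40, seed=8)
        preds = predict_proba_all(ref_net, df)
        for i in (0, 7, 23):
            row = df.iloc[i].to_dict()
            for j, node in enumerate(ref_net.nodes):
                assert preds[i, j] == pytest.approx(
                    predict_from_others(ref_net, row, node), abs=1e-9
                )
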