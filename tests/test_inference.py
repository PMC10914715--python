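"""Exact inference: variable elimination vs the enumeration oracle, the
published posterior changes, and the two reasoning modes."""

import numpy as np
import pytest

from metsnet.inference import (
    ZeroProbabilityEvidenceError,
    causal_reasoning,
    enumerate_posterior,
    evidential_reasoning,
    query,
)
from metsnet.network import CategoricalVariable, Cpt, Dag, DiscreteBayesNet

from .conftest import make_random_net


def _chain_net():
    """A -> B -> C with hand-set CPTs (used for the hand enumeration check)."""
    mk = lambda n: CategoricalVariable(n, ("0", "1"))
    dag = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
    cpts = {
        "A": Cpt("A", (), {(): (0.7, 0.3)}),
        "B": Cpt("B", ("A",), {("0",): (0.8, 0.2), ("1",): (0.3, 0.7)}),
        "C": Cpt("C", ("B",), {("0",): (0.6, 0.4), ("1",): (0.1, 0.9)}),
    }
    return DiscreteBayesNet(variables=[mk("A"), mk("B"), mk("C")], dag=dag, cpts=cpts)


class TestQuery:
    def test_published_progression_posteriors(self, progression_net):
        # published figures are whole percents computed from 2-dp CPTs: ±1 pp
        p = query(progression_net, "progression")
        assert abs(100 * p[1] - 36) <= 1.0
        p_yes = query(progression_net, "progression", {"hyperuricemia": "yes"})
        assert abs(100 * p_yes[1] - 60) <= 1.0
        p_no = query(progression_net, "progression", {"hyperuricemia": "no"})
        assert abs(100 * p_no[1] - 33) <= 1.0

    def test_monotone_evidence_direction(self, progression_net):
        base = query(progression_net, "progression")[1]
        hi = query(progression_net, "progression", {"hyperuricemia": "yes"})[1]
        lo = query(progression_net, "progression", {"hyperuricemia": "no"})[1]
        assert hi > base > lo

    def test_evidence_fixing_all_parents_returns_cpt_row(self, progression_net):
        row = progression_net.cpts["progression"].row(("yes", "overweight"))
        post = query(
            progression_net,
            "progression",
            {"hyperuricemia": "yes", "bmi": "overweight"},
        )
        np.testing.assert_allclose(post, row, atol=1e-15)

    def test_target_in_evidence_rejected(self, progression_net):
        with pytest.raises(ValueError, match="fixed by the evidence"):
            query(progression_net, "bmi", {"bmi": "thin"})

    def test_zero_probability_evidence_raises(self):
        v1 = CategoricalVariable("A", ("0", "1"))
        v2 = CategoricalVariable("B", ("0", "1"))
        net = DiscreteBayesNet(
            variables=[v1, v2],
            dag=Dag(["A", "B"], [("A", "B")]),
            cpts={
                "A": Cpt("A", (), {(): (1.0, 0.0)}),
                "B": Cpt("B", ("A",), {("0",): (0.5, 0.5), ("1",): (0.5, 0.5)}),
            },
        )
        with pytest.raises(ZeroProbabilityEvidenceError):
            query(net, "B", {"A": "1"})


class TestEnumerationOracle:
    def test_single_node_marginal(self):
        v = CategoricalVariable("A", ("x", "y"))
        net = DiscreteBayesNet(
            variables=[v], dag=Dag(["A"]), cpts={"A": Cpt("A", (), {(): (0.25, 0.75)})}
        )
        np.testing.assert_allclose(enumerate_posterior(net, "A"), [0.25, 0.75])

    def test_chain_bayes_inversion_by_hand(self):
        """P(A | C=1) by the explicit 8-term sum:
        P(A=a, C=1) = sum_b P(a) P(b|a) P(C=1|b); here
        a=0: 0.7*(0.8*0.4 + 0.2*0.9) = 0.35, a=1: 0.3*(0.3*0.4 + 0.7*0.9) = 0.225."""
        net = _chain_net()
        expected = np.array([0.35, 0.225]) / 0.575
        np.testing.assert_allclose(enumerate_posterior(net, "A", {"C": "1"}), expected, atol=1e-15)
        np.testing.assert_allclose(query(net, "A", {"C": "1"}), expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_query_matches_enumeration_on_random_nets(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_net(rng, max_nodes=8, max_states=512)
        names = list(net.names)
        target = names[int(rng.integers(len(names)))]
        n_ev = int(rng.integers(0, min(3, len(names))))
        ev_vars = [n for n in names if n != target][:n_ev]
        evidence = {v: net.variable(v).levels[int(rng.integers(net.variable(v).cardinality))] for v in ev_vars}
        try:
            expected = enumerate_posterior(net, target, evidence)
        except ZeroProbabilityEvidenceError:
            with pytest.raises(ZeroProbabilityEvidenceError):
                query(net, target, evidence)
            return
        got = query(net, target, evidence)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestCausalReasoning:
    def test_published_recovery_deltas(self, recovery_net):
        table = causal_reasoning(recovery_net, "recovery", ["high_hba1c", "bmi"]).table
        rev = table[table.level == "reverse"].set_index("evidence")
        assert abs(100 * rev.loc["high_hba1c=yes", "posterior"] - 20) <= 1.0
        assert abs(100 * rev.loc["high_hba1c=no", "posterior"] - 34) <= 1.0
        assert abs(100 * rev.loc["bmi=overweight", "posterior"] - 30) <= 1.0
        assert abs(100 * rev.loc["bmi=thin", "posterior"] - 45) <= 1.0
        assert rev.loc["high_hba1c=yes", "trend"] == "↓"

    def test_published_progression_bmi_effect(self, progression_net):
        table = causal_reasoning(progression_net, "progression", ["bmi"]).table
        fwd = table[table.level == "forward"].set_index("evidence")
        assert abs(100 * fwd.loc["bmi=overweight", "posterior"] - 41) <= 1.0
        assert abs(100 * fwd.loc["bmi=thin", "posterior"] - 32) <= 1.0
        assert abs(100 * fwd.loc["bmi=normal", "posterior"] - 31) <= 1.0

    def test_d_separated_factor_has_zero_delta(self, progression_net):
        """age and hyperuricemia share no path, so instantiating age cannot
        move the hyperuricemia posterior."""
        table = causal_reasoning(progression_net, "hyperuricemia", ["age"]).table
        assert np.allclose(table["delta"], 0.0, atol=1e-12)

    def test_posteriors_normalized_per_evidence(self, progression_net):
        table = causal_reasoning(progression_net, "progression", ["bmi", "hyperuricemia"]).table
        sums = table.groupby("evidence")["posterior"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestEvidentialReasoning:
    def test_published_hyperuricemia_posterior_given_forward(self, progression_net):
        table = evidential_reasoning(
            progression_net, "progression", "forward", ["hyperuricemia"]
        ).table
        row = table[(table.variable == "hyperuricemia") & (table.level == "yes")]
        assert abs(100 * float(row.posterior.iloc[0]) - 14.24) < 0.5
        assert row.trend.iloc[0] == "↑"

    def test_bayes_inversion_identity(self, progression_net):
        """P(f|o) == P(o|f) P(f) / P(o) tying the two reasoning modes together."""
        p_o = query(progression_net, "progression")[1]
        for factor in ("hyperuricemia", "bmi", "gender"):
            prior = query(progression_net, factor)
            post = query(progression_net, factor, {"progression": "forward"})
            for k, level in enumerate(progression_net.variable(factor).levels):
                p_o_given_f = query(progression_net, "progression", {factor: level})[1]
                assert post[k] == pytest.approx(p_o_given_f * prior[k] / p_o, abs=1e-12)

    def test_zero_mass_outcome_level_raises(self):
        v1 = CategoricalVariable("A", ("0", "1"))
        v2 = CategoricalVariable("B", ("0", "1"))
        net = DiscreteBayesNet(
            variables=[v1, v2],
            dag=Dag(["A", "B"], [("A", "B")]),
            cpts={
                "A": Cpt("A", (), {(): (0.4, 0.6)}),
                "B": Cpt("B", ("A",), {("0",): (1.0, 0.0), ("1",): (1.0, 0.0)}),
            },
        )
        with pytest.raises(ZeroProbabilityEvidenceError):
            evidential_reasoning(net, "B", "1", ["A"])

    def test_rounded_view_is_percent_scale(self, recovery_net):
        table = evidential_reasoning(recovery_net, "recovery", "reverse", ["bmi"])
        rounded = table.rounded()
        assert rounded.prior.between(0, 100).all()
        raw = table.table
        assert raw.prior.between(0, 1).all()
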