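"""Gain/loss birth-death model: transition probabilities, pruning vs
enumeration, posteriors, event calling and mechanism classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from uvsdr import ancestral, simulate
from uvsdr.ancestral import (
    GainLossModel,
    TreeIndex,
    ancestral_posteriors,
    call_events,
    classify_mechanism,
    discretize_gamma,
    encode_presence,
    fit_gain_loss,
    pattern_likelihood,
    transition_matrix,
)
from uvsdr.core_io import read_tree


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        assert np.allclose(transition_matrix(0.7, 0.3, 0.0), np.eye(2))

    def test_long_time_stationary(self):
        P = transition_matrix(0.7, 0.3, 1e6)
        assert np.allclose(P[0], [0.3, 0.7]) and np.allclose(P[1], [0.3, 0.7])

    def test_closed_form_value(self):
        P = transition_matrix(1.0, 1.0, 1.0)
        assert math.isclose(P[0, 1], 0.5 * (1 - math.exp(-2)), rel_tol=1e-12)
        assert math.isclose(P[0, 1], 0.43233, abs_tol=5e-6)

    def test_rows_sum_to_one(self):
        for g, l, t in [(0.2, 1.4, 0.5), (3.0, 0.1, 2.0), (1e-9, 1.0, 7.0)]:
            assert np.allclose(transition_matrix(g, l, t).sum(axis=1), 1.0)

    def test_zero_rates_identity_with_warning(self, caplog):
        assert np.allclose(transition_matrix(0, 0, 5.0), np.eye(2))


def brute_force_likelihood(index: TreeIndex, pattern: dict,
                           model: GainLossModel) -> float:
    """Enumerate every internal-state assignment; mix gamma categories."""
    internal = [i for i in range(index.n_nodes) if not index.is_tip[i]]
    rates = model.rate_multipliers()
    root_p = model.root_distribution()
    total = 0.0
    for rate in rates:
        lik = 0.0
        for assignment in itertools.product([0, 1], repeat=len(internal)):
            state = {}
            for i, s in zip(internal, assignment):
                state[i] = s
            for i in range(index.n_nodes):
                if index.is_tip[i]:
                    state[i] = pattern[index.labels[i]]
            term = root_p[state[index.root]]
            for i in range(index.n_nodes):
                if i == index.root:
                    continue
                P = transition_matrix(model.gain * rate, model.loss * rate,
                                      index.blen[i], warn=False)
                term *= P[state[index.parent[i]], state[i]]
            lik += term
        total += lik / len(rates)
    return total


def brute_force_posterior(index: TreeIndex, pattern: dict,
                          model: GainLossModel, node_label: str) -> float:
    """P(node = 1 | tips) by direct Bayes over all assignments."""
    node = index.labels.index(node_label)
    rates = model.rate_multipliers()
    root_p = model.root_distribution()
    num = den = 0.0
    internal = [i for i in range(index.n_nodes) if not index.is_tip[i]]
    for rate in rates:
        for assignment in itertools.product([0, 1], repeat=len(internal)):
            state = dict(zip(internal, assignment))
            for i in range(index.n_nodes):
                if index.is_tip[i]:
                    state[i] = pattern[index.labels[i]]
            term = root_p[state[index.root]] / len(rates)
            for i in range(index.n_nodes):
                if i == index.root:
                    continue
                P = transition_matrix(model.gain * rate, model.loss * rate,
                                      index.blen[i], warn=False)
                term *= P[state[index.parent[i]], state[i]]
            den += term
            if state[node] == 1:
                num += term
    return num / den


TREE3 = "((A:0.4,B:0.7):0.3,C:1.1);"
TREE4 = "((A:0.4,B:0.7):0.3,(C:0.5,D:0.2):0.6);"


class TestPatternLikelihood:
    def test_two_tip_matches_enumeration(self):
        index = TreeIndex(read_tree("(A:0.5,B:1.2);"))
        model = GainLossModel(0.8, 1.3, gamma_shape=0.7, n_categories=4)
        for pa, pb in itertools.product([0, 1], repeat=2):
            pattern = {"A": pa, "B": pb}
            assert math.isclose(
                pattern_likelihood(index, pattern, model),
                brute_force_likelihood(index, pattern, model),
                abs_tol=1e-12,
            )

    @pytest.mark.parametrize("newick", [TREE3, TREE4])
    def test_enumeration_equality_within_1e10(self, newick):
        index = TreeIndex(read_tree(newick))
        model = GainLossModel(0.5, 1.0, gamma_shape=1.0, n_categories=10)
        tips = index.tips()
        for states in itertools.product([0, 1], repeat=len(tips)):
            pattern = dict(zip(tips, states))
            assert abs(
                pattern_likelihood(index, pattern, model)
                - brute_force_likelihood(index, pattern, model)
            ) <= 1e-10

    def test_patterns_sum_to_one_on_three_tips(self):
        index = TreeIndex(read_tree(TREE3))
        model = GainLossModel(0.4, 0.9, gamma_shape=2.0, n_categories=5)
        total = sum(
            pattern_likelihood(index, dict(zip(index.tips(), states)), model)
            for states in itertools.product([0, 1], repeat=3)
        )
        assert math.isclose(total, 1.0, abs_tol=1e-12)

    def test_missing_tip_rejected(self):
        index = TreeIndex(read_tree(TREE3))
        with pytest.raises(ValueError, match="missing tips"):
            pattern_likelihood(index, {"A": 1}, GainLossModel(1, 1))


class TestPosteriors:
    def test_tip_posteriors_equal_observations(self):
        index = TreeIndex(read_tree(TREE3))
        matrix = pd.DataFrame({"A": [1, 0], "B": [0, 1], "C": [1, 1]})
        model = GainLossModel(0.5, 1.0, gamma_shape=1.0, n_categories=3)
        post = ancestral_posteriors(index, matrix, model)
        assert np.allclose(post["A"], [1, 0])
        assert np.allclose(post["B"], [0, 1])

    def test_symmetric_discordant_two_tip_root_is_half(self):
        index = TreeIndex(read_tree("(A:1.0,B:1.0);"))
        model = GainLossModel(1.0, 1.0)
        matrix = pd.DataFrame({"A": [1], "B": [0]})
        post = ancestral_posteriors(index, matrix, model)
        root_label = [lab for i, lab in enumerate(index.labels)
                      if not index.is_tip[i]][0]
        assert math.isclose(post[root_label].iloc[0], 0.5, abs_tol=1e-12)

    def test_matches_brute_force_bayes_on_three_tips(self):
        index = TreeIndex(read_tree(TREE3))
        model = GainLossModel(0.6, 1.1, gamma_shape=0.8, n_categories=4)
        internal = [lab for i, lab in enumerate(index.labels)
                    if not index.is_tip[i]]
        for states in itertools.product([0, 1], repeat=3):
            pattern = dict(zip(index.tips(), states))
            matrix = pd.DataFrame([pattern])
            post = ancestral_posteriors(index, matrix, model)
            for lab in internal:
                assert abs(
                    post[lab].iloc[0]
                    - brute_force_posterior(index, pattern, model, lab)
                ) <= 1e-10


class TestFit:
    def test_all_present_pushes_loss_to_boundary(self):
        index = TreeIndex(read_tree(TREE4))
        matrix = pd.DataFrame(
            {t: [1] * 30 for t in index.tips()})
        model, _ = fit_gain_loss(index, matrix, restarts=2, fit_gamma=False)
        assert model.loss < 0.01

    def test_determinism(self):
        index = TreeIndex(read_tree(TREE4))
        matrix, _ = simulate.simulate_family_evolution(
            index, 0.5, 1.0, 1.0, 60, seed=3)
        a = fit_gain_loss(index, matrix, restarts=3, seed=9)
        b = fit_gain_loss(index, matrix, restarts=3, seed=9)
        assert a[0].gain == b[0].gain and a[0].loss == b[0].loss
        assert a[1] == b[1]

    def test_parameter_recovery_on_simulated_families(self):
        tree = simulate.default_species_tree()
        index = TreeIndex(tree)
        matrix, _ = simulate.simulate_family_evolution(
            index, 0.5, 1.0, 1.0, 500, seed=42)
        model, _ = fit_gain_loss(index, matrix, restarts=5, seed=0)
        assert abs(model.gain - 0.5) / 0.5 < 0.25
        assert abs(model.loss - 1.0) / 1.0 < 0.25
        assert abs(model.gamma_shape - 1.0) / 1.0 < 0.5

    def test_expected_counts_match_truth(self):
        tree = simulate.default_species_tree()
        index = TreeIndex(tree)
        matrix, node_truth = simulate.simulate_family_evolution(
            index, 0.5, 1.0, 1.0, 500, seed=21)
        model, _ = fit_gain_loss(index, matrix, restarts=5, seed=0)
        post = ancestral_posteriors(index, matrix, model)
        expected = ancestral.expected_gene_count(post)
        for i, lab in enumerate(index.labels):
            if index.is_tip[i]:
                continue
            truth = sum(node_truth[(f"fam{f}", lab)] for f in range(500))
            assert abs(expected[lab] - truth) <= 0.10 * max(truth, 1)


class TestGammaDiscretization:
    def test_mean_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = discretize_gamma(alpha, 10)
            assert math.isclose(rates.mean(), 1.0, abs_tol=1e-12)
            assert (np.diff(rates) >= 0).all()

    def test_large_shape_concentrates_at_one(self):
        rates = discretize_gamma(500.0, 10)
        assert np.allclose(rates, 1.0, atol=0.2)


class TestEncodePresence:
    def test_coding_rules(self):
        loc = pd.DataFrame({"sp1": ["SDR", "PAR", "UNPLACED"],
                            "sp2": ["AUTOSOME", "SDR", "UNPLACED"]},
                           index=["f1", "f2", "f3"])
        mat = encode_presence(loc)
        assert list(mat.loc["f1"]) == [1, 0]
        assert list(mat.loc["f2"]) == [0, 1]
        assert list(mat.loc["f3"]) == [0, 0]

    def test_unknown_code_rejected(self):
        loc = pd.DataFrame({"sp1": ["WEIRD"]}, index=["f1"])
        with pytest.raises(ValueError, match="unknown location"):
            encode_presence(loc)


class TestEvents:
    def _setup(self):
        index = TreeIndex(read_tree(TREE4))
        return index

    def test_all_present_family_has_no_events(self):
        index = self._setup()
        post = pd.DataFrame([{lab: 1.0 for lab in index.labels}],
                            index=["fam0"])
        events = call_events(post, index)
        assert (events["event"] == "retention").all()

    def test_single_tip_presence_gains_on_terminal_branch(self):
        index = self._setup()
        matrix = pd.DataFrame({"A": [1], "B": [0], "C": [0], "D": [0]})
        model = GainLossModel(0.05, 1.0)
        post = ancestral_posteriors(index, matrix, model)
        events = call_events(post, index)
        gains = events[events["event"] == "gain"]
        assert list(gains["child"]) == ["A"]

    def test_threshold_tie_counts_present(self):
        index = self._setup()
        post = pd.DataFrame([{lab: 0.5 for lab in index.labels}],
                            index=["fam0"])
        events = call_events(post, index, threshold=0.5)
        assert (events["event"] == "retention").all()


class TestMechanism:
    def _tree(self):
        return TreeIndex(read_tree(
            "((A:1,B:1):1,(C:1,D:1):1);"))

    def _loc(self, a, b, c, d):
        return pd.DataFrame({"A": [a], "B": [b], "C": [c], "D": [d]},
                            index=["fam"])

    def test_par_majority_is_boundary_expansion(self):
        loc = self._loc("SDR", "PAR", "PAR", "ABSENT")
        assert classify_mechanism("fam", "A", loc, self._tree()) \
            == ancestral.BOUNDARY_EXPANSION

    def test_autosome_is_translocation(self):
        loc = self._loc("SDR", "ABSENT", "AUTOSOME", "ABSENT")
        assert classify_mechanism("fam", "A", loc, self._tree()) \
            == ancestral.TRANSLOCATION

    def test_all_absent_is_birth(self):
        loc = self._loc("SDR", "ABSENT", "ABSENT", "ABSENT")
        assert classify_mechanism("fam", "A", loc, self._tree()) \
            == ancestral.BIRTH

    def test_par_autosome_tie_is_ambiguous(self):
        loc = self._loc("SDR", "PAR", "AUTOSOME", "ABSENT")
        assert classify_mechanism("fam", "A", loc, self._tree()) \
            == ancestral.AMBIGUOUS
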