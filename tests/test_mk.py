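"""Mk machinery: P(t), pruning likelihood, fitting, LRT, marginal ASR."""

import numpy as np
import pytest

from defchem.errors import ValidationError
from defchem.mk import (
    RateModel,
    StateSpace,
    build_stage_model,
    fit_mk,
    fitzjohn_root,
    likelihood_ratio_test,
    log_likelihood,
    marginal_ancestral_states,
    read_index_matrix,
    transition_probabilities,
    write_index_matrix,
)
from defchem.simulate import simulate_discrete, simulate_tree
from defchem.tree import tree_from_string

from conftest import (
    enumerate_log_likelihood,
    enumerate_marginals,
    enumerate_root_partials,
    random_generator,
    random_tree,
)

S2 = StateSpace(("0", "1"))
S3 = StateSpace(("a", "b", "c"))


def model_from_Q(Q: np.ndarray) -> RateModel:
    """Wrap an explicit generator as an all-rates-different model."""
    k = Q.shape[0]
    states = StateSpace(tuple(str(i) for i in range(k)))
    model = RateModel.ard(states)
    theta = [Q[i, j] for i in range(k) for j in range(k) if i != j]
    return model.with_theta(theta)


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self):
        m = RateModel.er(S3, 0.7)
        assert np.allclose(transition_probabilities(m, 0.0), np.eye(3))

    def test_two_state_closed_form(self):
        m = RateModel.er(S2, 1.0)
        P = transition_probabilities(m, 1.0)
        assert P[0, 0] == pytest.approx((1 + np.exp(-2)) / 2, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            transition_probabilities(RateModel.er(S2, 1.0), -1.0)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            m = model_from_Q(random_generator(rng, k))
            s, t = rng.uniform(0, 5, size=2)
            Pst = transition_probabilities(m, s + t)
            prod = transition_probabilities(m, s) @ transition_probabilities(m, t)
            assert np.abs(Pst - prod).max() < 1e-8

    def test_row_stochastic_large_t(self, rng):
        m = model_from_Q(random_generator(rng, 4))
        for t in (0.0, 1.0, 100.0, 1e3):
            P = transition_probabilities(m, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= 0).all() and (P <= 1).all()

    def test_detailed_balance_symmetric_Q(self, rng):
        m = RateModel.sym(S3).with_theta([0.3, 0.7, 1.1])
        P = transition_probabilities(m, 2.0)
        # uniform stationary distribution for symmetric Q: pi_i P_ij = pi_j P_ji
        assert np.abs(P - P.T).max() < 1e-9


class TestRateModel:
    def test_rows_sum_to_zero(self, rng):
        for maker in (RateModel.er, RateModel.sym, RateModel.ard):
            m = maker(S3)
            m = m.with_theta(rng.uniform(0.1, 2.0, size=m.n_params))
            assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
            assert (m.Q[~np.eye(3, dtype=bool)] >= 0).all()

    def test_parameter_counts(self):
        assert RateModel.er(S3).n_params == 1
        assert RateModel.sym(S3).n_params == 3
        assert RateModel.ard(S3).n_params == 6
        s7 = StateSpace(tuple("abcdefg"))
        assert RateModel.sym(s7).n_params == 21
        assert RateModel.ard(s7).n_params == 42

    def test_shared_index_shares_rate(self):
        M = np.array([[0, 1, 1], [2, 0, 1], [2, 2, 0]])
        m = RateModel(S3, M, [0.5, 1.5])
        assert m.Q[0, 1] == m.Q[0, 2] == m.Q[1, 2] == 0.5
        assert m.Q[1, 0] == m.Q[2, 0] == m.Q[2, 1] == 1.5

    def test_index_matrix_file_round_trip(self, tmp_path):
        m = build_stage_model()
        p = tmp_path / "mat.txt"
        write_index_matrix(m, str(p))
        back = read_index_matrix(str(p))
        assert (back.index_matrix == m.index_matrix).all()
        assert back.states.labels == m.states.labels


class TestStageModel:
    def test_three_free_parameters(self):
        assert build_stage_model().n_params == 3
        assert build_stage_model(allow_total_loss=False).n_params == 3

    def test_direct_gain_structurally_forbidden(self):
        m = build_stage_model().with_theta([1.0, 1.0, 1.0])
        assert m.index_matrix[0, 2] == 0
        # P(none -> benzoquinone) vanishes faster than t as t -> 0
        for t in (1e-3, 1e-5):
            assert transition_probabilities(m, t)[0, 2] / t < 10 * t

    def test_losses_share_one_rate(self):
        m = build_stage_model().with_theta([0.1, 0.2, 0.9])
        assert m.Q[1, 0] == m.Q[2, 1] == m.Q[2, 0] == 0.9

    def test_forbid_total_loss_switch(self):
        m = build_stage_model(allow_total_loss=False)
        assert m.index_matrix[2, 0] == 0


class TestLikelihood:
    def test_pruning_matches_enumeration(self, rng):
        """200 random small instances against the brute-force oracle."""
        for _ in range(200):
            n = int(rng.integers(2, 6))
            k = int(rng.integers(2, 5))
            tree = random_tree(rng, n)
            Q = random_generator(rng, k)
            m = model_from_Q(Q)
            labels = list(m.states.labels)
            data = {lab: str(rng.integers(k)) for lab in tree.tip_labels}
            pi = np.full(k, 1.0 / k)
            got = log_likelihood(tree, data, m, root="flat")
            want = enumerate_log_likelihood(tree, data, Q, labels, pi)
            assert got == pytest.approx(want, abs=1e-9)

    def test_handles_multifurcation(self, rng):
        tree = tree_from_string("(A:1,B:1.5,C:0.5,D:2);")
        Q = random_generator(rng, 3)
        m = model_from_Q(Q)
        data = {"A": "0", "B": "1", "C": "2", "D": "0"}
        got = log_likelihood(tree, data, m, root="flat")
        want = enumerate_log_likelihood(tree, data, Q, list(m.states.labels), np.full(3, 1 / 3))
        assert got == pytest.approx(want, abs=1e-9)

    def test_ambiguous_tip_sums_states(self, rng):
        tree = random_tree(rng, 4)
        Q = random_generator(rng, 2)
        m = model_from_Q(Q)
        labels = tree.tip_labels
        amb = {labels[0]: frozenset({"0", "1"})}
        amb.update({lab: "1" for lab in labels[1:]})
        lls = []
        for s in ("0", "1"):
            d = dict(amb)
            d[labels[0]] = s
            lls.append(log_likelihood(tree, d, m, root="flat"))
        combined = log_likelihood(tree, amb, m, root="flat")
        assert np.exp(combined) == pytest.approx(sum(np.exp(v) for v in lls), rel=1e-9)

    def test_missing_tip_data_rejected(self, rng):
        tree = random_tree(rng, 3)
        m = RateModel.er(S2, 1.0)
        data = {lab: "0" for lab in tree.tip_labels[:-1]}
        with pytest.raises(ValidationError, match="no character data"):
            log_likelihood(tree, data, m)

    def test_state_relabeling_invariance(self, rng):
        for _ in range(10):
            tree = random_tree(rng, 5)
            Q = random_generator(rng, 3)
            perm = rng.permutation(3)
            Qp = Q[np.ix_(perm, perm)]
            data = {lab: str(rng.integers(3)) for lab in tree.tip_labels}
            inv = np.argsort(perm)
            data_p = {lab: str(inv[int(s)]) for lab, s in data.items()}
            ll = log_likelihood(tree, data, model_from_Q(Q), root="flat")
            llp = log_likelihood(tree, data_p, model_from_Q(Qp), root="flat")
            assert ll == pytest.approx(llp, abs=1e-9)

    def test_near_zero_rates_constant_data(self):
        tree = tree_from_string("(A:1,B:1);")
        m = RateModel.er(S2, 1e-12)
        ll = log_likelihood(tree, {"A": "0", "B": "0"}, m, root="flat")
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_fitzjohn_matches_enumeration(self, rng):
        for _ in range(20):
            tree = random_tree(rng, 4)
            Q = random_generator(rng, 3)
            m = model_from_Q(Q)
            data = {lab: str(rng.integers(3)) for lab in tree.tip_labels}
            L = enumerate_root_partials(tree, data, Q, list(m.states.labels))
            want = np.log((L / L.sum() * L).sum())
            got = log_likelihood(tree, data, m, root="fitzjohn")
            assert got == pytest.approx(want, abs=1e-9)


class TestFitzJohnRoot:
    def test_symmetric_input(self):
        out = fitzjohn_root([0.2, 0.2, 0.2])
        assert np.allclose(out.weights, 1 / 3)

    def test_hand_computation(self):
        out = fitzjohn_root([0.3, 0.1])
        assert out.total_likelihood == pytest.approx(0.25)
        assert np.allclose(out.root_marginal, [0.9, 0.1])

    def test_normalization_property(self, rng):
        for _ in range(1000):
            v = rng.uniform(0.01, 10, size=rng.integers(2, 6))
            out = fitzjohn_root(v)
            assert out.weights.sum() == pytest.approx(1.0)
            assert out.root_marginal.sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fitzjohn_root([0.0, 0.0])


class TestFit:
    def test_nesting_on_any_data(self, rng):
        tree = simulate_tree(40, 0.05, 0.0, rng=rng, crown_age=50)
        data, _ = simulate_discrete(tree, RateModel.er(S3, 0.05), "flat", rng=rng)
        fits = {
            name: fit_mk(tree, data, maker(S3), n_restarts=4, seed=1)
            for name, maker in [("ER", RateModel.er), ("SYM", RateModel.sym), ("ARD", RateModel.ard)]
        }
        assert fits["ARD"].log_likelihood >= fits["SYM"].log_likelihood - 1e-6
        assert fits["SYM"].log_likelihood >= fits["ER"].log_likelihood - 1e-6

    def test_constant_character_degenerate(self, rng):
        tree = simulate_tree(20, 0.05, 0.0, rng=rng, crown_age=50)
        data = {lab: "0" for lab in tree.tip_labels}
        fit = fit_mk(tree, data, RateModel.er(S2), root="flat", n_restarts=3, seed=0)
        assert fit.model.theta[0] < 1e-6  # driven to the lower bound
        assert fit.log_likelihood == pytest.approx(np.log(0.5), abs=1e-3)

    def test_seed_reproducibility(self, rng):
        tree = simulate_tree(20, 0.05, 0.0, rng=rng, crown_age=50)
        data, _ = simulate_discrete(tree, RateModel.er(S2, 0.03), "flat", rng=rng)
        f1 = fit_mk(tree, data, RateModel.er(S2), n_restarts=3, seed=7)
        f2 = fit_mk(tree, data, RateModel.er(S2), n_restarts=3, seed=7)
        assert f1.log_likelihood == f2.log_likelihood
        assert (f1.model.theta == f2.model.theta).all()

    def test_parameter_recovery_bias_shrinks(self, rng):
        """Median relative error of q-hat decreases from 50 to 500 tips."""
        errors = {}
        for n in (50, 500):
            errs = []
            for _ in range(8):
                tree = simulate_tree(n, 1.0, 0.0, rng=rng)
                data, _ = simulate_discrete(tree, RateModel.er(S2, 1.0), "flat", rng=rng)
                fit = fit_mk(tree, data, RateModel.er(S2), n_restarts=2, seed=3)
                errs.append(abs(fit.model.theta[0] - 1.0))
            errors[n] = float(np.median(errs))
        assert errors[500] < errors[50]


class TestLRT:
    def _two_fits(self, rng):
        tree = simulate_tree(30, 0.05, 0.0, rng=rng, crown_age=50)
        data, _ = simulate_discrete(tree, RateModel.er(S3, 0.03), "flat", rng=rng)
        er = fit_mk(tree, data, RateModel.er(S3), n_restarts=3, seed=0)
        ard = fit_mk(tree, data, RateModel.ard(S3), n_restarts=3, seed=0)
        return er, ard

    def test_identical_fits_give_p_one(self, rng):
        er, ard = self._two_fits(rng)
        tied = likelihood_ratio_test(
            er, type(er)(**{**er.__dict__, "n_params": 6})
        )
        assert tied.statistic == 0.0
        assert tied.p_value == 1.0

    def test_df_from_parameter_counts(self, rng):
        er, ard = self._two_fits(rng)
        res = likelihood_ratio_test(er, ard)
        assert res.df == 5
        assert 0 <= res.p_value <= 1

    def test_mismatched_data_rejected(self, rng):
        er, ard = self._two_fits(rng)
        ard.data_fingerprint = "deadbeef"
        with pytest.raises(ValidationError, match="same tree and data"):
            likelihood_ratio_test(er, ard)

    def test_requires_nesting_direction(self, rng):
        er, ard = self._two_fits(rng)
        with pytest.raises(ValidationError):
            likelihood_ratio_test(ard, er)


class TestMarginalASR:
    def test_zero_length_pendant_pins_node(self):
        tree = tree_from_string("((A:0.0,B:1):1,C:2);")
        m = RateModel.er(S2, 0.5)
        rec = marginal_ancestral_states(
            tree, {"A": "1", "B": "0", "C": "0"}, m, root="flat"
        )
        node = tree.tip("A").parent
        assert rec.probabilities[node.id, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration(self, rng):
        """100 random small instances against brute-force conditionals."""
        for _ in range(100):
            n = int(rng.integers(2, 6))
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, n)
            Q = random_generator(rng, k)
            m = model_from_Q(Q)
            data = {lab: str(rng.integers(k)) for lab in tree.tip_labels}
            pi = np.full(k, 1.0 / k)
            rec = marginal_ancestral_states(tree, data, m, root="flat")
            want = enumerate_marginals(tree, data, Q, list(m.states.labels), pi)
            for node in tree.internal_nodes:
                assert np.abs(rec.probabilities[node.id] - want[node.id]).max() < 1e-9

    def test_rows_sum_to_one(self, rng):
        tree = random_tree(rng, 10)
        m = RateModel.er(S3, 0.2)
        data = {lab: str(["a", "b", "c"][rng.integers(3)]) for lab in tree.tip_labels}
        rec = marginal_ancestral_states(tree, data, m)
        assert np.allclose(rec.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_child_order_invariance(self, rng):
        ta = tree_from_string("((A:1,B:2):1,C:2);")
        tb = tree_from_string("(C:2,(B:2,A:1):1);")
        m = RateModel.er(S2, 0.4)
        data = {"A": "0", "B": "1", "C": "1"}
        ra = marginal_ancestral_states(ta, data, m, root="flat")
        rb = marginal_ancestral_states(tb, data, m, root="flat")
        assert np.allclose(
            ra.probabilities[ta.root.id], rb.probabilities[tb.root.id], atol=1e-12
        )
        inner_a = ta.tip("A").parent
        inner_b = tb.tip("A").parent
        assert np.allclose(
            ra.probabilities[inner_a.id], rb.probabilities[inner_b.id], atol=1e-12
        )

    def test_threshold_reporting_rule(self):
        tree = tree_from_string("((A:1,B:1):1,C:2);")
        m = RateModel.er(S2, 0.5)
        rec = marginal_ancestral_states(tree, {"A": "0", "B": "0", "C": "0"}, m)
        rec.probabilities[tree.root.id] = np.array([0.8, 0.2])
        assert rec.top_state(tree.root.id) == "0"
        rec.probabilities[tree.root.id] = np.array([0.6, 0.4])
        assert rec.top_state(tree.root.id) == "unresolved"
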