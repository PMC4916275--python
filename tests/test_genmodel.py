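"""The analytic mixture-model layer against brute-force enumeration.

The brute-force oracle below evaluates the unnormalised scores of the
generative model directly from its definition (a dictionary-driven
loop over all states), independently of the vectorised implementation.
"""

import itertools
import math

import numpy as np
import pytest

import wtalearn as wl
from wtalearn.genmodel import (
    DistributionTable,
    Theta,
    alpha_posterior,
    conditional_z,
    construct_theta,
    em_fixed_point,
    joint_full,
    joint_marginal,
    kl_objective,
    mean_update,
    network_objective,
    normalization_residuals,
    theta_from_weights,
    weights_from_theta,
)
from wtalearn.plasticity import PlasticityConfig

W_MINUS = 2.5 * math.log(0.2)


def brute_scores(theta):
    """Unnormalised exp-scores for every (component, x) state, by loops."""
    C = theta.n_components
    states = {}
    x_ranges = [range(m + 1) for m in theta.M]
    comps = list(range(C)) + ["null"]
    for c in comps:
        for x in itertools.product(*x_ranges):
            if c == "null":
                s = theta.T * theta.b_minus
                for i, v in enumerate(x):
                    s += theta.T * theta.w_minus if v != 0 else -theta.V
            else:
                s = theta.b_hat[c]
                for i, v in enumerate(x):
                    s += theta.w_hat[i][v, c]
            states[(c, x)] = math.exp(s)
    return states


class TestThetaMapping:
    def test_affine_map_with_scaling(self):
        cfg = PlasticityConfig(w_minus=W_MINUS, b_minus=-3.0, T=0.4)
        weights = [np.zeros((2, 2)), np.ones((2, 2))]
        biases = np.array([1.0, -1.0])
        th = theta_from_weights(weights, biases, cfg, M=(2, 2), J=(1, 1))
        assert th.w_hat[0][1, 0] == pytest.approx(0.4 * W_MINUS)
        assert th.w_hat[1][1, 0] == pytest.approx(0.4 * (1 + W_MINUS))
        assert th.b_hat[0] == pytest.approx(0.4 * (1.0 - 3.0))
        assert np.all(th.w_hat[0][0, :] == -50.0)  # pinned zero-value row

    def test_roundtrip(self):
        cfg = PlasticityConfig(w_minus=W_MINUS, b_minus=-5.0, T=0.58)
        rng = np.random.default_rng(0)
        weights = [rng.uniform(0, 4, (2, 3)), rng.uniform(0, 4, (3, 3))]
        biases = rng.uniform(-5, 5, 3)
        th = theta_from_weights(weights, biases, cfg, M=(2, 3), J=(2, 1))
        w2, b2 = weights_from_theta(th)
        for a, b in zip(weights, w2):
            assert np.allclose(a, b)
        assert np.allclose(biases, b2)


class TestJointEvaluation:
    def test_deterministic_output_link(self, tiny_theta):
        assert joint_full(tiny_theta, (2, 1), 1, (1, 1)) == 0.0

    def test_constraint_satisfying_theta_has_unit_norm(self):
        th = em_fixed_point(
            wl.target_example1().marginal(["z", "x1", "x2"]),
            M=(2, 2),
            J=(2, 2),
            iters=50,
            seed=1,
        )
        # normalization residuals ~ 0 imply A(theta) ~ 1
        assert abs(math.exp(th.log_norm()) - 1.0) < 1e-6

    def test_matches_brute_force(self, tiny_theta):
        scores = brute_scores(tiny_theta)
        Z = sum(scores.values())
        for c, (l, j) in enumerate([(1, 1), (1, 2), (2, 1), (2, 2)]):
            for x in itertools.product(range(3), range(3)):
                expected = scores[(c, x)] / Z
                got = joint_full(tiny_theta, (l, j), l, x)
                assert got == pytest.approx(expected, rel=1e-10)
        got0 = joint_full(tiny_theta, (0, 1), 0, (1, 2))
        assert got0 == pytest.approx(scores[("null", (1, 2))] / Z, rel=1e-10)

    def test_marginal_sums_to_one(self, tiny_theta):
        tab = joint_marginal(tiny_theta)
        assert tab.probs.sum() == pytest.approx(1.0)

    def test_zero_value_mass_negligible(self, tiny_theta):
        tab = joint_marginal(tiny_theta)
        zero_x_mass = 0.0  # a zero-valued input within a real component
        null_mass = 0.0  # the no-neuron-active component (z = 0)
        for assignment, p in tab.assignments():
            if assignment["z"] == 0:
                null_mass += p
            elif 0 in assignment.values():
                zero_x_mass += p
        domain = tab.probs.size
        # pinned -V entries make in-component zero values vanish
        assert zero_x_mass < math.exp(-tiny_theta.V) * domain * 1e3
        # the null component's prior is exp(T*(b_minus + I*w_minus))
        bound = math.exp(
            tiny_theta.T
            * (tiny_theta.b_minus + 2 * tiny_theta.w_minus)
        ) * domain
        assert null_mass < bound
        assert null_mass < 1e-8  # negligible for this offset choice


class TestConstruction:
    def test_point_mass_reproduces_target(self, example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        th = construct_theta(tm, eps=1e-5)
        model = joint_marginal(th)
        # embed the target into the zero-extended domain
        dom = model
        total = 0.0
        for assignment, p in tm.assignments():
            total += abs(p - dom.prob(assignment))
        assert 0.5 * total < 1e-3


class TestConditionals:
    def test_conditional_normalised_and_two_routes_agree(self, tiny_theta):
        cond, rates = conditional_z(tiny_theta, (2, 1))
        assert cond.sum() == pytest.approx(1.0)
        # at T=1 the network-side intensity equals the probability ratio
        expected = cond[1:] / cond[0] / 0.015
        assert np.allclose(rates, expected, rtol=1e-8)

    def test_alpha_posterior_is_softmax_and_matches_bayes(self, tiny_theta):
        x = (2, 2)
        post = alpha_posterior(tiny_theta, x, 2)
        assert post.sum() == pytest.approx(1.0)
        # Bayes by brute force
        scores = brute_scores(tiny_theta)
        s = [scores[(c, x)] for c in (2, 3)]  # components of l=2
        assert np.allclose(post, np.array(s) / sum(s), rtol=1e-10)
        # softmax of the membrane potentials of that subpopulation
        weights, biases = weights_from_theta(tiny_theta)
        u = biases[2:] + weights[0][1, 2:] + weights[1][1, 2:]
        sm = np.exp(u - u.max())
        sm /= sm.sum()
        assert np.allclose(post, sm, rtol=1e-8)

    def test_degenerate_single_component(self):
        th = construct_theta(
            DistributionTable([("z", [1]), ("x1", [1, 2])], [[0.3, 0.7]]),
            eps=0.01,
        )
        # one component per assignment here; take a J=1 module instead
        cfg = PlasticityConfig(w_minus=W_MINUS, b_minus=-5.0, T=1.0)
        th1 = theta_from_weights(
            [np.array([[1.0], [2.0]])], [0.5], cfg, M=(2,), J=(1,)
        )
        assert alpha_posterior(th1, (2,), 1) == pytest.approx([1.0])


class TestResiduals:
    def test_zero_for_constraint_satisfying_theta(self):
        b_hat = np.log(np.full(4, 0.25))
        w_hat = [
            np.vstack([np.full((1, 4), -50.0), np.log(np.full((2, 4), 0.5))])
            for _ in range(2)
        ]
        th = Theta(M=(2, 2), J=(2, 2), w_hat=w_hat, b_hat=b_hat,
                   w_minus=W_MINUS, b_minus=-15.0)
        c0, cw, mx = normalization_residuals(th)
        assert abs(c0) < 1e-12 and mx < 1e-12

    def test_matches_independent_summation(self, tiny_theta):
        c0, cw, _ = normalization_residuals(tiny_theta)
        assert c0 == pytest.approx(
            sum(math.exp(b) for b in tiny_theta.b_hat) - 1.0
        )
        for i in range(2):
            for c in range(4):
                s = sum(
                    math.exp(tiny_theta.w_hat[i][m, c]) for m in (1, 2)
                )
                assert cw[i, c] == pytest.approx(s - 1.0)


class TestObjectives:
    def test_perfect_model_has_zero_kl(self, example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        th = construct_theta(tm, eps=1e-9)
        r = kl_objective(th, tm)
        assert r["U"] < 1e-6

    def test_decomposition_identity(self, tiny_theta, example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        r = kl_objective(tiny_theta, tm)
        assert abs(r["U"] - r["J"] - r["kl_x"]) < 1e-10

    def test_network_objective_is_sum_and_monotone(self, tiny_theta,
                                                   example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        u1 = kl_objective(tiny_theta, tm)["U"]
        total = network_objective([tiny_theta, tiny_theta], [tm, tm])
        assert total == pytest.approx(2 * u1)
        # worsening one module cannot decrease the sum (KL >= 0 per term)
        worse = Theta(
            M=tiny_theta.M,
            J=tiny_theta.J,
            w_hat=[w - 1.0 * (w != -tiny_theta.V) for w in tiny_theta.w_hat],
            b_hat=tiny_theta.b_hat,
            w_minus=tiny_theta.w_minus,
            b_minus=tiny_theta.b_minus,
        )
        u_worse = kl_objective(worse, tm)["U"]
        assert total <= u1 + max(u1, u_worse) + 1e-12

    def test_missing_support_flags_infinity(self):
        t = DistributionTable([("z", [1, 2]), ("x1", [1, 2])],
                              [[0.5, 0.0], [0.0, 0.5]])
        cfg = PlasticityConfig(w_minus=W_MINUS, b_minus=-5.0, T=1.0)
        th = theta_from_weights(
            [np.full((2, 2), -60.0)], [0.0, 0.0], cfg, M=(2,), J=(1, 1)
        )
        r = kl_objective(th, t)
        assert not r["infinite"]  # exp(-V) mass is small but positive


class TestMeanUpdate:
    def test_zero_at_em_fixed_point(self, example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        th = em_fixed_point(tm, M=(2, 2), J=(2, 2), iters=400, seed=3)
        mu = mean_update(th, tm)
        assert mu.max_abs() < 1e-6

    def test_dot_product_identities(self, tiny_theta, example1_target):
        tm = example1_target.marginal(["z", "x1", "x2"])
        mu = mean_update(tiny_theta, tm)
        c0, cw, _ = normalization_residuals(tiny_theta)
        dot_b = float(np.sum(mu.h_b * np.exp(tiny_theta.b_hat)))
        assert dot_b == pytest.approx(-c0, abs=1e-8)
        for i in range(2):
            lhs = (mu.h_w[i] * np.exp(tiny_theta.w_hat[i][1:, :])).sum(axis=0)
            rhs = -mu.p_star_a * cw[i]
            assert np.allclose(lhs, rhs, atol=1e-8)


class TestDistributionTable:
    def test_text_roundtrip(self, example1_target, tmp_path):
        path = tmp_path / "table.tsv"
        example1_target.dump(path)
        back = DistributionTable.load(path)
        assert back.names == example1_target.names
        assert np.allclose(back.probs, example1_target.probs)

    def test_marginal_and_condition(self, example1_target):
        mz = example1_target.marginal(["z"])
        assert mz.probs == pytest.approx([0.5, 0.5])
        cond = example1_target.condition({"x1": 2, "x2": 2})
        assert cond.prob({"z": 1}) == pytest.approx(0.21 / 0.25)

    def test_normalization_validation(self):
        with pytest.raises(ValueError):
            DistributionTable([("a", [1, 2])], [0.5, 0.4])
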