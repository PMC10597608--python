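"""MAML machinery: adaptation, meta-gradients, attention, train/test loops."""

import numpy as np
import pytest

from em3p2 import (
    RunConfig,
    TaskCollection,
    fd_hvp,
    initialize_meta_state,
    inner_adapt,
    maml_meta_gradient,
    meta_test,
    meta_train,
    meta_update,
    split_tasks,
    task_attention,
)
from em3p2.meta import TaskAdaptation
from conftest import toy_task


def quadratic(a, c):
    """f(x) = a (x - c)^2 with its gradient, as a plug-in objective."""

    def fn(theta):
        x = theta[0]
        return a * (x - c) ** 2, np.array([2 * a * (x - c)])

    return fn


class TestInnerAdapt:
    def test_zero_lr_identity(self):
        theta = np.array([3.0])
        adapted, _ = inner_adapt(theta, quadratic(1.0, 0.0), inner_lr=0.0, n_steps=3)
        np.testing.assert_array_equal(adapted, theta)

    def test_single_step_matches_hand_computation(self):
        """Two-point softmax toy: one step equals theta - lr * analytic gradient.

        Model: logits (w*x, 0) on points x=1 (label 0) and x=2 (label 1);
        dL/dw = mean over points of x * (sigma(w x) - y).
        """

        def loss_grad(theta):
            w = theta[0]
            xs, ys = np.array([1.0, 2.0]), np.array([0, 1])
            p = 1 / (1 + np.exp(-w * xs))  # P(class 0)... class-0 logit is w*x
            # softmax CE with logits (w x, 0): P(y=0) = sigma(w x)
            loss = np.mean(np.where(ys == 0, -np.log(p), -np.log(1 - p)))
            grad = np.mean(xs * (p - (ys == 0)))
            return loss, np.array([grad])

        theta = np.array([0.3])
        _, g = loss_grad(theta)
        adapted, _ = inner_adapt(theta, loss_grad, inner_lr=0.05, n_steps=1)
        np.testing.assert_allclose(adapted, theta - 0.05 * g)

    def test_two_steps_equal_two_single_steps(self):
        theta = np.array([5.0])
        fn = quadratic(0.7, 1.0)
        two, _ = inner_adapt(theta, fn, 0.1, 2)
        one, _ = inner_adapt(theta, fn, 0.1, 1)
        again, _ = inner_adapt(one, fn, 0.1, 1)
        np.testing.assert_allclose(two, again)

    def test_never_mutates_input(self):
        theta = np.array([2.0])
        before = theta.copy()
        inner_adapt(theta, quadratic(1.0, 0.0), 0.1, 3)
        np.testing.assert_array_equal(theta, before)


class TestMamlGradient:
    def test_second_order_matches_analytic_on_quadratic(self):
        """d/dtheta L_q(theta - a L_s'(theta)) = (1 - 2 a a_s) L_q'(theta')."""
        a_s, c_s, a_q, c_q, lr = 0.8, 1.0, 1.3, -2.0, 0.07
        theta = np.array([0.5])
        support, query = quadratic(a_s, c_s), quadratic(a_q, c_q)
        g, adapted, _ = maml_meta_gradient(theta, support, query, lr, 1, second_order=True)
        jac = 1 - lr * 2 * a_s
        expected = jac * 2 * a_q * (adapted[0] - c_q)
        np.testing.assert_allclose(g[0], expected, atol=1e-6)

    def test_first_order_differs_by_hessian_term(self):
        a_s, lr = 0.8, 0.07
        theta = np.array([0.5])
        support, query = quadratic(a_s, 1.0), quadratic(1.3, -2.0)
        g2, adapted, _ = maml_meta_gradient(theta, support, query, lr, 1, second_order=True)
        g1, _, _ = maml_meta_gradient(theta, support, query, lr, 1, second_order=False)
        q_grad = 2 * 1.3 * (adapted[0] - (-2.0))
        np.testing.assert_allclose(g1[0], q_grad, atol=1e-9)
        np.testing.assert_allclose(g2[0] - g1[0], -lr * 2 * a_s * q_grad, atol=1e-6)

    def test_multi_step_second_order(self):
        """n inner steps on a quadratic: Jacobian is (1 - lr f'')^n."""
        a_s, lr, n = 0.6, 0.05, 3
        theta = np.array([2.0])
        support, query = quadratic(a_s, 0.0), quadratic(1.0, 1.0)
        g, adapted, _ = maml_meta_gradient(theta, support, query, lr, n, second_order=True)
        jac = (1 - lr * 2 * a_s) ** n
        np.testing.assert_allclose(g[0], jac * 2 * (adapted[0] - 1.0), atol=1e-6)

    def test_hvp_exact_on_quadratic(self):
        fn = quadratic(2.5, 0.3)
        hv = fd_hvp(fn, np.array([1.7]), np.array([3.0]))
        np.testing.assert_allclose(hv, [2 * 2.5 * 3.0], rtol=1e-6)


class TestTaskAttention:
    def test_single_task_weight_one(self, rng):
        w = task_attention([rng.normal(size=4)], {"att_w": rng.normal(size=4), "att_b": 0.1})
        np.testing.assert_allclose(w, [1.0])

    def test_identical_embeddings_uniform(self, rng):
        h = rng.normal(size=4)
        w = task_attention([h] * 5, {"att_w": rng.normal(size=4), "att_b": 0.0})
        np.testing.assert_allclose(w, np.full(5, 0.2))

    def test_shift_invariance_and_normalization(self, rng):
        hs = [rng.normal(size=4) for _ in range(3)]
        p1 = {"att_w": rng.normal(size=4), "att_b": 0.0}
        p2 = {"att_w": p1["att_w"], "att_b": 7.5}  # constant shift of all scores
        w1, w2 = task_attention(hs, p1), task_attention(hs, p2)
        np.testing.assert_allclose(w1, w2, atol=1e-12)
        assert w1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w1 > 0)


def tiny_collection(seed=0, n_tasks=3):
    rng = np.random.default_rng(seed)
    coll = TaskCollection(tasks=[toy_task(rng, 50, task_id=f"t{i}") for i in range(n_tasks)])
    return split_tasks(coll, n_tasks - 1, 1, seed=seed)


def tiny_config(**kw):
    defaults = dict(epochs=2, n_shot=4, m_query=4, embedding_dim=8, n_layers=2, seed=0)
    defaults.update(kw)
    return RunConfig(**defaults)


class TestMetaUpdate:
    def test_beta_zero_leaves_parameters(self):
        cfg = tiny_config(outer_optimizer="sgd", outer_lr=1e-12)
        state = initialize_meta_state(cfg, np.random.default_rng(0))
        state.outer_lr = 0.0
        theta = state.theta.copy()
        adapt = TaskAdaptation(
            task_id="t",
            adapted_theta=theta.copy(),
            query_loss=_breakdown(1.0),
            mean_node_embedding=np.ones(8),
            meta_grad=np.ones_like(theta),
        )
        state.history.append({"tasks": {}})
        meta_update(state, [adapt])
        np.testing.assert_array_equal(state.theta, theta)

    def test_nonfinite_gradient_skips_update(self):
        cfg = tiny_config()
        state = initialize_meta_state(cfg, np.random.default_rng(0))
        theta = state.theta.copy()
        adapt = TaskAdaptation(
            task_id="t",
            adapted_theta=theta.copy(),
            query_loss=_breakdown(1.0),
            mean_node_embedding=np.ones(8),
            meta_grad=np.full_like(theta, np.nan),
        )
        state.history.append({"tasks": {}})
        meta_update(state, [adapt])
        np.testing.assert_array_equal(state.theta, theta)

    def test_single_task_uniform_attention_is_plain_maml_step(self):
        cfg = tiny_config(outer_optimizer="sgd", outer_lr=0.1, grad_clip=0.0)
        state = initialize_meta_state(cfg, np.random.default_rng(0))
        theta = state.theta.copy()
        g = np.random.default_rng(1).normal(size=theta.size)
        adapt = TaskAdaptation("t", theta.copy(), _breakdown(1.0), np.ones(8), g)
        state.history.append({"tasks": {}})
        meta_update(state, [adapt])
        np.testing.assert_allclose(state.theta, theta - 0.1 * g)


def _breakdown(total):
    from em3p2 import LossBreakdown

    return LossBreakdown(l_dce=total, l_br=0.0, l_avuc=0.0, lambda_b=0.0, lambda_c=0.0)


class TestMetaTrain:
    def test_zero_epochs_returns_initialized_state(self):
        coll = tiny_collection()
        cfg = tiny_config(epochs=0)
        state = meta_train(coll, cfg)
        fresh = initialize_meta_state(cfg, np.random.default_rng(0))
        assert state.epoch == 0
        assert state.theta.shape == fresh.theta.shape

    def test_inner_adaptation_never_mutates_meta_parameters(self):
        """Bitwise check: adaptation leaves Theta untouched until meta_update."""
        coll = tiny_collection()
        cfg = tiny_config()
        state = initialize_meta_state(cfg, np.random.default_rng(0))
        before = state.theta.copy()
        task = coll.train_tasks()[0]
        graphs = [m.graph for m, _ in task.members[:8]]
        labels = np.array([y for _, y in task.members[:8]])

        def fn(vec):
            loss, grad, _ = state.network.loss_and_grad(vec, graphs, labels, "softmax")
            return loss, grad

        maml_meta_gradient(state.theta, fn, fn, inner_lr=0.05, n_steps=2)
        np.testing.assert_array_equal(state.theta, before)
        assert (state.theta == before).all()

    def test_losses_finite_and_logged_every_epoch(self):
        coll = tiny_collection()
        state = meta_train(coll, tiny_config(epochs=3))
        assert len(state.history) == 3
        for rec in state.history:
            for v in rec["tasks"].values():
                assert np.isfinite(v["total"])
            assert "attention" in rec

    def test_deterministic_given_seed(self):
        coll = tiny_collection()
        s1 = meta_train(coll, tiny_config(epochs=2))
        s2 = meta_train(coll, tiny_config(epochs=2))
        np.testing.assert_array_equal(s1.theta, s2.theta)

    def test_attention_weights_normalized_every_step(self):
        coll = tiny_collection(n_tasks=4)
        state = meta_train(coll, tiny_config(epochs=4))
        for rec in state.history:
            assert abs(sum(rec["attention"]) - 1.0) < 1e-6


class TestMetaTest:
    def _trained(self):
        coll = tiny_collection()
        cfg = tiny_config(epochs=2)
        return meta_train(coll, cfg), coll, cfg

    def test_threshold_one_never_rejects(self):
        state, coll, cfg = self._trained()
        task = coll.test_tasks()[0]
        support = task.members[:4]
        queries = [m for m, _ in task.members[4:14]]
        outs = meta_test(state, support, queries, cfg, uncertainty_threshold=1.0)
        assert all(o.decision == "predict" for o in outs)

    def test_tiny_threshold_rejects_everything_uncertain(self):
        state, coll, cfg = self._trained()
        task = coll.test_tasks()[0]
        outs = meta_test(state, task.members[:4], [m for m, _ in task.members[4:14]],
                         cfg, uncertainty_threshold=1e-9)
        assert all(o.decision == "reject" for o in outs)

    def test_zero_adaptation_steps_reproducible_and_state_unmodified(self):
        state, coll, cfg = self._trained()
        theta_before = state.theta.copy()
        task = coll.test_tasks()[0]
        support = task.members[:4]
        queries = [m for m, _ in task.members[4:10]]
        o1 = meta_test(state, support, queries, cfg, n_steps=0)
        o2 = meta_test(state, support, queries, cfg, n_steps=0)
        for a, b in zip(o1, o2):
            np.testing.assert_array_equal(a.evidence, b.evidence)
        np.testing.assert_array_equal(state.theta, theta_before)

    def test_empty_support_rejected(self):
        state, coll, cfg = self._trained()
        with pytest.raises(Exception, match="support"):
            meta_test(state, [], [coll.test_tasks()[0].members[0][0]], cfg)
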