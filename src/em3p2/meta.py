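"""MAML-style meta-training and meta-testing with task attention.

Meta-training (one iteration = one epoch):

  for every training task:
    1. sample N support molecules; adapt Theta' = Theta - alpha * grad of the
       plain softmax cross-entropy on the support set (the inner loop uses the
       softmax reading of the shared head, deliberately NOT the evidential
       one, so per-task adaptation does not bake task-specific uncertainty
       into the meta-model);
    2. sample a class-balanced query set (exactly M/C per class) and evaluate
       the adapted model evidentially: the combined annealed evidential loss
       L'_t plus the task's mean query node embedding h'_t.
  then:
    3. task attention A(T_t) = softmax over a single-layer MLP score of each
       h'_t, and one outer step on Theta through the attended sum
       sum_t A(T_t) * L'_t, with gradients flowing through the inner
       adaptation (second-order by default).

Meta-testing copies Theta, adapts it on the new task's support set under the
evidential loss for a few steps (early stop on a support-loss plateau), and
returns evidence/uncertainty/predict-or-reject for each query molecule.  The
meta-parameters are never mutated.

Second-order meta-gradients are computed as Jacobian-transpose-vector
products: for an inner step u(theta) = theta - alpha * m .* g(theta) the
transpose Jacobian applied to v is v - alpha * H (m .* v), and the
Hessian-vector product uses a central finite difference of the exact support
gradient.  On quadratic objectives this is exact to rounding; in general the
step size scales with sqrt(machine eps).

The inner/outer machinery is written against plain callables
``f(theta_vec) -> (loss, grad)`` so any differentiable objective — including
closed-form toy models used to validate the meta-gradient — can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import RunConfig
from .data_io import (
    BalancedSamplingError,
    DataError,
    Episode,
    Molecule,
    TaskCollection,
    sample_episode,
)
from .evidential import EvidentialOutput, LossBreakdown, annealing, dirichlet_summary
from .gin import GinConfig, GinEvidentialNetwork

logger = logging.getLogger(__name__)

LossGradFn = Callable[[np.ndarray], tuple[float, np.ndarray]]


class NumericError(RuntimeError):
    """A loss or gradient became non-finite."""


# ---------------------------------------------------------------------------
# generic MAML machinery (model-agnostic in the literal sense)
# ---------------------------------------------------------------------------


def inner_adapt(
    theta: np.ndarray,
    loss_grad_fn: LossGradFn,
    inner_lr: float,
    n_steps: int,
    grad_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Gradient-descent adaptation: theta' = theta - lr * grad, n_steps times.

    Returns the adapted vector and the trajectory of pre-step iterates (needed
    to backpropagate a second-order meta-gradient).  ``grad_mask`` freezes
    parameters where it is 0 (e.g. encoder freezing).  Never mutates ``theta``.
    """
    current = np.array(theta, dtype=float, copy=True)
    trajectory: list[np.ndarray] = []
    for _ in range(n_steps):
        loss, grad = loss_grad_fn(current)
        if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
            raise NumericError(f"non-finite inner-loop loss/gradient (loss={loss})")
        if grad_mask is not None:
            grad = grad * grad_mask
        trajectory.append(current)
        current = current - inner_lr * grad
    return current, trajectory


def fd_hvp(
    loss_grad_fn: LossGradFn, theta: np.ndarray, vector: np.ndarray
) -> np.ndarray:
    """Hessian-vector product by central finite difference of the exact gradient."""
    v_norm = float(np.linalg.norm(vector))
    if v_norm == 0.0:
        return np.zeros_like(vector)
    r = np.sqrt(np.finfo(float).eps) * (1.0 + float(np.linalg.norm(theta))) / v_norm
    _, g_plus = loss_grad_fn(theta + r * vector)
    _, g_minus = loss_grad_fn(theta - r * vector)
    return (g_plus - g_minus) / (2.0 * r)


def maml_meta_gradient(
    theta: np.ndarray,
    support_fn: LossGradFn,
    query_fn: LossGradFn,
    inner_lr: float,
    n_steps: int,
    second_order: bool = True,
    grad_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Meta-gradient of the query loss through the inner adaptation.

    Returns (meta_grad at theta, adapted theta', query loss at theta').
    First-order mode drops the Hessian correction and returns the query
    gradient at the adapted parameters unchanged.
    """
    adapted, trajectory = inner_adapt(theta, support_fn, inner_lr, n_steps, grad_mask)
    query_loss, g = query_fn(adapted)
    if second_order:
        for theta_step in reversed(trajectory):
            masked = g if grad_mask is None else g * grad_mask
            g = g - inner_lr * fd_hvp(support_fn, theta_step, masked)
    return g, adapted, query_loss


def task_attention(
    mean_node_embeddings: Sequence[np.ndarray], attention_params: dict
) -> np.ndarray:
    """Softmax over single-layer MLP scores of each task's mean query embedding.

    Weights are positive and sum to 1; shifting all scores by a constant
    leaves them unchanged.
    """
    if len(mean_node_embeddings) == 0:
        raise ValueError("task_attention needs at least one task")
    h = np.stack([np.asarray(e, dtype=float) for e in mean_node_embeddings])
    scores = h @ attention_params["att_w"] + attention_params["att_b"]
    scores = scores - scores.max()
    w = np.exp(scores)
    return w / w.sum()


# ---------------------------------------------------------------------------
# meta state and the outer optimizer
# ---------------------------------------------------------------------------


class AdamState:
    """Minimal Adam optimizer over a flat parameter vector."""

    def __init__(self, n: int, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, vec: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return vec - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TaskAdaptation:
    """One task's contribution to a meta-update."""

    task_id: str
    adapted_theta: np.ndarray
    query_loss: LossBreakdown
    mean_node_embedding: np.ndarray  # mean over query molecules of their mean node embeddings
    meta_grad: np.ndarray  # d(query loss)/d(meta parameters), through the adaptation


@dataclass
class MetaState:
    """Meta-parameters Theta = {encoder Phi, head Psi} plus attention MLP and clocks."""

    network: GinEvidentialNetwork
    theta: np.ndarray  # flat parameter vector
    attention_params: dict  # {"att_w": (d,), "att_b": ()}
    inner_lr: float
    outer_lr: float
    epoch: int
    total_epochs: int
    rng: np.random.Generator
    optimizer: Optional[AdamState] = None
    grad_clip: float = 0.0  # global-norm clip on the combined meta-gradient; 0 disables
    history: list[dict] = field(default_factory=list)

    def params(self) -> dict:
        return self.network.unpack(self.theta)


def initialize_meta_state(config: RunConfig, rng: np.random.Generator) -> MetaState:
    gin_cfg = GinConfig(
        n_layers=config.n_layers,
        dim=config.embedding_dim,
        atom_vocab=tuple(config.atom_vocab),
        bond_vocab=tuple(config.bond_vocab) if config.bond_vocab else None,
        n_classes=config.n_classes,
        learn_epsilon=config.learn_epsilon,
    )
    network = GinEvidentialNetwork(gin_cfg)
    theta = network.pack(network.init_params(rng))
    attention = {"att_w": np.zeros(config.embedding_dim), "att_b": np.zeros(())}
    optimizer = (
        AdamState(theta.size, config.outer_lr) if config.outer_optimizer == "adam" else None
    )
    return MetaState(
        network=network,
        theta=theta,
        attention_params=attention,
        inner_lr=config.inner_lr,
        outer_lr=config.outer_lr,
        epoch=0,
        total_epochs=config.epochs,
        rng=rng,
        optimizer=optimizer,
        grad_clip=config.grad_clip,
    )


# ---------------------------------------------------------------------------
# task-level forward passes
# ---------------------------------------------------------------------------


def _graphs_labels(pairs: Sequence[tuple[Molecule, int]]):
    graphs = [m.graph for m, _ in pairs]
    labels = np.array([y for _, y in pairs], dtype=int)
    return graphs, labels


def task_forward(
    network: GinEvidentialNetwork,
    adapted_theta: np.ndarray,
    query: Sequence[tuple[Molecule, int]],
    lambda_b: float,
    lambda_c: float,
    use_br: bool = True,
    use_avuc: bool = True,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Evidential query loss, its gradient and the mean query embedding."""
    graphs, labels = _graphs_labels(query)
    loss, grad, aux = network.loss_and_grad(
        adapted_theta, graphs, labels, "evidential",
        lambda_b=lambda_b, lambda_c=lambda_c, use_br=use_br, use_avuc=use_avuc,
    )
    return aux["breakdown"], grad, aux["embeddings"].mean(axis=0)


# ---------------------------------------------------------------------------
# the meta-update
# ---------------------------------------------------------------------------


def meta_update(state: MetaState, adaptations: Sequence[TaskAdaptation]) -> MetaState:
    """One outer step: Theta <- Theta - beta * grad of sum_t A(T_t) * L'_t.

    Attention weights treat the task embeddings as constants: the attention
    gradient reaches the attention MLP parameters, not the encoder.  A
    non-finite combined gradient skips the update (logged) rather than
    corrupting the meta-parameters.
    """
    if not adaptations:
        return state
    weights = task_attention(
        [a.mean_node_embedding for a in adaptations], state.attention_params
    )
    meta_grad = np.zeros_like(state.theta)
    for w, a in zip(weights, adaptations):
        meta_grad += w * a.meta_grad

    losses = np.array([a.query_loss.total for a in adaptations])
    # d(sum_t A_t L_t)/d score_s = A_s (L_s - sum_t A_t L_t)
    d_scores = weights * (losses - float(weights @ losses))
    h = np.stack([a.mean_node_embedding for a in adaptations])
    d_att_w = h.T @ d_scores
    d_att_b = d_scores.sum()

    if not (np.all(np.isfinite(meta_grad)) and np.all(np.isfinite(d_att_w))):
        logger.warning("non-finite meta-gradient at epoch %d; skipping update", state.epoch)
        return state

    if state.grad_clip > 0:
        norm = float(np.linalg.norm(meta_grad))
        if norm > state.grad_clip:
            meta_grad = meta_grad * (state.grad_clip / norm)

    if state.optimizer is not None:
        state.theta = state.optimizer.step(state.theta, meta_grad)
    else:
        state.theta = state.theta - state.outer_lr * meta_grad
    state.attention_params["att_w"] = state.attention_params["att_w"] - state.outer_lr * d_att_w
    state.attention_params["att_b"] = state.attention_params["att_b"] - state.outer_lr * d_att_b
    state.history[-1]["attention"] = [float(w) for w in weights]
    return state


# ---------------------------------------------------------------------------
# meta-training
# ---------------------------------------------------------------------------


def meta_train(
    collection: TaskCollection,
    config: RunConfig,
    state: Optional[MetaState] = None,
) -> MetaState:
    """Run the full meta-training loop over the collection's training tasks.

    Deterministic given ``config.seed``.  Episode sampling, parameter
    initialization and any task subsampling draw from independent child
    streams of the master seed.  Per-epoch loss components, annealing weights
    and attention weights are recorded in ``state.history``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    if state is None:
        state = initialize_meta_state(config, np.random.default_rng(seeds[0]))
    episode_rng = np.random.default_rng(seeds[1])

    train_tasks = collection.train_tasks()
    if not train_tasks:
        raise DataError("no tasks assigned to meta_train in the collection split")
    network = state.network
    grad_mask = network.head_param_mask() if config.freeze_encoder else None

    frozen_episodes: dict[str, Episode] = {}

    for epoch in range(config.epochs):
        lam_b, lam_c = annealing(epoch, config.epochs, config.lambda0)
        state.history.append({"epoch": epoch, "lambda_b": lam_b, "lambda_c": lam_c, "tasks": {}})
        tasks = train_tasks
        if config.tasks_per_batch and config.tasks_per_batch < len(train_tasks):
            pick = episode_rng.choice(len(train_tasks), config.tasks_per_batch, replace=False)
            tasks = [train_tasks[int(i)] for i in pick]

        adaptations: list[TaskAdaptation] = []
        for task in tasks:
            try:
                if config.frozen_split and task.task_id in frozen_episodes:
                    episode = frozen_episodes[task.task_id]
                else:
                    episode = sample_episode(
                        task,
                        config.n_shot,
                        config.m_query,
                        balanced=config.balanced_query,
                        rng=episode_rng,
                        n_classes=config.n_classes,
                        support_per_class=config.support_per_class,
                        replacement_fallback=config.balanced_fallback == "replacement",
                    )
                    if config.frozen_split:
                        frozen_episodes[task.task_id] = episode
            except (BalancedSamplingError, DataError) as exc:
                logger.warning("skipping task %s this epoch: %s", task.task_id, exc)
                continue

            s_graphs, s_labels = _graphs_labels(episode.support)

            def support_fn(vec, g=s_graphs, y=s_labels):
                loss, grad, _ = network.loss_and_grad(vec, g, y, "softmax")
                return loss, grad

            q_graphs, q_labels = _graphs_labels(episode.query)
            aux_store: dict = {}

            def query_fn(vec, g=q_graphs, y=q_labels, store=aux_store):
                loss, grad, aux = network.loss_and_grad(
                    vec, g, y, "evidential",
                    lambda_b=lam_b, lambda_c=lam_c,
                    use_br=config.use_br, use_avuc=config.use_avuc,
                )
                store["breakdown"] = aux["breakdown"]
                store["embedding"] = aux["embeddings"].mean(axis=0)
                return loss, grad

            try:
                meta_grad, adapted, _ = maml_meta_gradient(
                    state.theta,
                    support_fn,
                    query_fn,
                    inner_lr=config.inner_lr,
                    n_steps=config.inner_steps_train,
                    second_order=config.order == "second",
                    grad_mask=grad_mask,
                )
            except NumericError as exc:
                logger.warning("aborting episode for task %s: %s", task.task_id, exc)
                continue

            breakdown: LossBreakdown = aux_store["breakdown"]
            adaptations.append(
                TaskAdaptation(
                    task_id=task.task_id,
                    adapted_theta=adapted,
                    query_loss=breakdown,
                    mean_node_embedding=aux_store["embedding"],
                    meta_grad=meta_grad,
                )
            )
            state.history[-1]["tasks"][task.task_id] = {
                "l_dce": breakdown.l_dce,
                "l_br": breakdown.l_br,
                "l_avuc": breakdown.l_avuc,
                "total": breakdown.total,
            }

        meta_update(state, adaptations)
        state.epoch = epoch + 1
    return state


# ---------------------------------------------------------------------------
# meta-testing
# ---------------------------------------------------------------------------


def meta_test(
    state: MetaState,
    support: Sequence[tuple[Molecule, int]],
    queries: Sequence,
    config: RunConfig,
    n_steps: Optional[int] = None,
    uncertainty_threshold: Optional[float] = None,
) -> list[EvidentialOutput]:
    """Adapt a copy of the meta-model to a new task and predict its queries.

    Adaptation minimizes the evidential loss (with the meta-state's final
    annealing weights) on the labeled support set, stopping early when the
    support loss plateaus.  Each query molecule gets evidence, probabilities,
    uncertainty and a predict/reject decision under the threshold.  The
    meta-state itself is left untouched.
    """
    if not support:
        raise DataError("meta_test requires a nonempty labeled support set")
    n_steps = config.inner_steps_test if n_steps is None else n_steps
    threshold = (
        config.uncertainty_threshold if uncertainty_threshold is None else uncertainty_threshold
    )
    network = state.network
    lam_b, lam_c = annealing(state.epoch, state.total_epochs, config.lambda0)
    grad_mask = network.head_param_mask() if config.freeze_encoder else None

    s_graphs, s_labels = _graphs_labels(support)

    def support_fn(vec):
        loss, grad, _ = network.loss_and_grad(
            vec, s_graphs, s_labels, "evidential",
            lambda_b=lam_b, lambda_c=lam_c,
            use_br=config.use_br, use_avuc=config.use_avuc,
        )
        return loss, grad

    theta = np.array(state.theta, copy=True)
    prev_loss = np.inf
    for _ in range(n_steps):
        loss, grad = support_fn(theta)
        if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
            raise NumericError("non-finite support loss during meta-test adaptation")
        if prev_loss - loss < 1e-6 * max(1.0, abs(prev_loss)):
            break
        if grad_mask is not None:
            grad = grad * grad_mask
        theta = theta - config.inner_lr * grad
        prev_loss = loss

    query_graphs = [q.graph if isinstance(q, Molecule) else q for q in queries]
    params = network.unpack(theta)
    logits, _, _ = network.forward(params, query_graphs)
    evidence = np.maximum(logits, 0.0)
    return [
        dirichlet_summary(e, config.n_classes, u_threshold=threshold) for e in evidence
    ]
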