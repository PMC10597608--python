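"""Graph Isomorphism Network encoder with a mean readout, in plain NumPy.

The encoder stacks K message-passing layers

    h_v^(k) = MLP^(k)( (1 + eps^(k)) * h_v^(k-1) + sum_{u in N(v)} h_u^(k-1) )

starting from embedded categorical atom features h_v^(0) = X_v (one learned
lookup table per feature, summed).  Sum aggregation over neighbours makes the
network as expressive as the 1-dimensional Weisfeiler-Lehman test.  The graph
embedding is the arithmetic mean of the last layer's node embeddings; both
node and graph readouts come from the final layer only.

Each layer's MLP is two linear maps with a ReLU between.  eps^(k) is fixed at
0 by default (``learn_epsilon`` adds it to the parameter set).  Bond features,
when enabled, enter as learned bond embeddings added to each neighbour message
before summation — the convention of pre-trained molecular GIN encoders; they
are disabled for synthetic graphs whose bonds carry no information.

Parameters live in a flat ``{name: ndarray}`` dict with a stable ordering, so
the whole model packs into a single vector for the meta-learning machinery.
Forward passes cache per-graph intermediates and ``backward`` replays them to
produce exact gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_io import MolecularGraph
from . import evidential
from .evidential import head_forward

# ---------------------------------------------------------------------------
# configuration and parameter layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GinConfig:
    """Architecture of the encoder + classification head.

    Defaults are desk-scale (K=3, d=64); chemistry-scale runs use K=5, d=300.
    """

    n_layers: int = 3
    dim: int = 64
    atom_vocab: tuple[int, ...] = (8, 3)
    bond_vocab: Optional[tuple[int, ...]] = None  # None: no bond features
    n_classes: int = 2
    learn_epsilon: bool = False
    epsilon: float = 0.0

    def param_spec(self) -> list[tuple[str, tuple[int, ...]]]:
        d = self.dim
        spec: list[tuple[str, tuple[int, ...]]] = []
        for i, v in enumerate(self.atom_vocab):
            spec.append((f"atom_emb{i}", (v, d)))
        if self.bond_vocab:
            for i, v in enumerate(self.bond_vocab):
                spec.append((f"bond_emb{i}", (v, d)))
        for k in range(self.n_layers):
            spec += [
                (f"gin{k}_W1", (d, d)),
                (f"gin{k}_b1", (d,)),
                (f"gin{k}_W2", (d, d)),
                (f"gin{k}_b2", (d,)),
            ]
        if self.learn_epsilon:
            spec.append(("epsilon", (self.n_layers,)))
        spec += [
            ("head_W1", (d, d)),
            ("head_b1", (d,)),
            ("head_W2", (d, self.n_classes)),
            ("head_b2", (self.n_classes,)),
        ]
        return spec


@dataclass
class EmbeddingOutput:
    """Final-layer node embeddings and their mean (the graph embedding)."""

    node_embeddings: np.ndarray  # (n_atoms, d)
    graph_embedding: np.ndarray  # (d,)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# functional layer (the unit the message-passing oracle checks)
# ---------------------------------------------------------------------------


def gin_layer(
    node_states: np.ndarray,
    graph: MolecularGraph,
    layer_params: dict,
    epsilon: float = 0.0,
    bond_messages: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One GIN layer: MLP((1+eps) h_v + sum_{u in N(v)} h_u [+ bond emb])."""
    h = np.asarray(node_states, dtype=float)
    if h.shape[0] != graph.n_atoms:
        raise ValueError(
            f"node_states has {h.shape[0]} rows for a graph with {graph.n_atoms} atoms"
        )
    src, dst = graph.bond_index
    agg = np.zeros_like(h)
    if src.size:
        msg = h[src]
        if bond_messages is not None:
            msg = msg + bond_messages
        np.add.at(agg, dst, msg)
    pre = (1.0 + epsilon) * h + agg
    a = pre @ layer_params["W1"] + layer_params["b1"]
    out = np.maximum(a, 0.0) @ layer_params["W2"] + layer_params["b2"]
    return out


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


class GinEvidentialNetwork:
    """GIN encoder + shared MLP head, with pack/unpack and exact backprop.

    One set of head parameters serves both classification modes: the raw head
    outputs are softmax logits during support adaptation in meta-training, and
    the same outputs pass through ReLU to become evidence for the evidential
    meta-objective and at meta-testing.  Sharing is what lets the adapted head
    from the support step be evaluated evidentially on the query step.
    """

    def __init__(self, config: GinConfig):
        self.config = config
        self.spec = config.param_spec()
        self._sizes = [int(np.prod(s)) for _, s in self.spec]
        self.n_params = int(sum(self._sizes))

    # -- parameter plumbing -------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict:
        params: dict[str, np.ndarray] = {}
        for name, shape in self.spec:
            if name == "head_b2":
                # start with mildly positive raw outputs so the ReLU evidence
                # is active (u < 1) and the evidential loss has live gradients
                params[name] = np.ones(shape)
            elif name.endswith(("_b1", "_b2")) or name == "epsilon":
                params[name] = np.zeros(shape)
            elif "emb" in name:
                params[name] = rng.normal(0.0, 0.1, size=shape)
            else:
                params[name] = _glorot(rng, shape)
        return params

    def pack(self, params: dict) -> np.ndarray:
        return np.concatenate([np.ravel(params[name]) for name, _ in self.spec])

    def unpack(self, vec: np.ndarray) -> dict:
        if vec.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {vec.size}")
        out, off = {}, 0
        for (name, shape), size in zip(self.spec, self._sizes):
            out[name] = vec[off : off + size].reshape(shape)
            off += size
        return out

    def zero_grads(self) -> dict:
        return {name: np.zeros(shape) for name, shape in self.spec}

    def head_param_mask(self) -> np.ndarray:
        """1.0 on head parameters, 0.0 on encoder parameters (for encoder freezing)."""
        mask = []
        for (name, _), size in zip(self.spec, self._sizes):
            mask.append(np.full(size, 1.0 if name.startswith("head_") else 0.0))
        return np.concatenate(mask)

    # -- forward ------------------------------------------------------------

    def _epsilons(self, params: dict) -> np.ndarray:
        if self.config.learn_epsilon:
            return params["epsilon"]
        return np.full(self.config.n_layers, self.config.epsilon)

    def _forward_graph(self, params: dict, graph: MolecularGraph):
        cfg = self.config
        eps = self._epsilons(params)
        src, dst = graph.bond_index
        h = sum(
            params[f"atom_emb{i}"][graph.atom_codes[:, i]]
            for i in range(len(cfg.atom_vocab))
        )
        bond_msg = None
        if cfg.bond_vocab:
            bond_msg = sum(
                params[f"bond_emb{i}"][graph.bond_codes[:, i]]
                for i in range(len(cfg.bond_vocab))
            )
        layers = []
        for k in range(cfg.n_layers):
            lp = {n: params[f"gin{k}_{n}"] for n in ("W1", "b1", "W2", "b2")}
            agg = np.zeros_like(h)
            if src.size:
                msg = h[src] if bond_msg is None else h[src] + bond_msg
                np.add.at(agg, dst, msg)
            pre = (1.0 + eps[k]) * h + agg
            a = pre @ lp["W1"] + lp["b1"]
            r = np.maximum(a, 0.0)
            h_next = r @ lp["W2"] + lp["b2"]
            layers.append({"h_in": h, "pre": pre, "a": a, "r": r})
            h = h_next
        hg = h.mean(axis=0)
        logits, head_cache = head_forward(hg, params)
        return logits, hg, h, {"layers": layers, "hg": hg, "head": head_cache, "h_final": h}

    def forward(self, params: dict, graphs: Sequence[MolecularGraph]):
        """Batch forward: (logits (B, C), graph embeddings (B, d), caches)."""
        logits, embeds, caches = [], [], []
        for g in graphs:
            z, hg, _, cache = self._forward_graph(params, g)
            logits.append(z)
            embeds.append(hg)
            caches.append(cache)
        return np.stack(logits), np.stack(embeds), caches

    def embed_graph(self, graph: MolecularGraph, params: dict) -> EmbeddingOutput:
        """K message-passing layers from embedded atom features; mean readout."""
        _, hg, h_nodes, _ = self._forward_graph(params, graph)
        return EmbeddingOutput(node_embeddings=h_nodes, graph_embedding=hg)

    # -- backward -----------------------------------------------------------

    def _backward_graph(self, params, graph, cache, d_logits, grads) -> None:
        cfg = self.config
        eps = self._epsilons(params)
        src, dst = graph.bond_index
        n = graph.n_atoms

        hg, (h_in_head, z1, r1) = cache["hg"], cache["head"]
        grads["head_W2"] += np.outer(r1, d_logits)
        grads["head_b2"] += d_logits
        dr1 = params["head_W2"] @ d_logits
        dz1 = dr1 * (z1 > 0)
        grads["head_W1"] += np.outer(h_in_head, dz1)
        grads["head_b1"] += dz1
        dhg = params["head_W1"] @ dz1
        dh = np.tile(dhg / n, (n, 1))

        for k in reversed(range(cfg.n_layers)):
            lay = cache["layers"][k]
            da = (dh @ params[f"gin{k}_W2"].T) * (lay["a"] > 0)
            grads[f"gin{k}_W2"] += lay["r"].T @ dh
            grads[f"gin{k}_b2"] += dh.sum(axis=0)
            grads[f"gin{k}_W1"] += lay["pre"].T @ da
            grads[f"gin{k}_b1"] += da.sum(axis=0)
            dpre = da @ params[f"gin{k}_W1"].T
            dh_in = (1.0 + eps[k]) * dpre
            if src.size:
                np.add.at(dh_in, src, dpre[dst])
            if cfg.learn_epsilon:
                grads["epsilon"][k] += float((dpre * lay["h_in"]).sum())
            if cfg.bond_vocab and src.size:
                for i in range(len(cfg.bond_vocab)):
                    np.add.at(grads[f"bond_emb{i}"], graph.bond_codes[:, i], dpre[dst])
            dh = dh_in

        for i in range(len(cfg.atom_vocab)):
            np.add.at(grads[f"atom_emb{i}"], graph.atom_codes[:, i], dh)

    def backward(self, params, graphs, caches, d_logits_batch) -> dict:
        """Accumulate dLoss/dparams given dLoss/dlogits for every graph."""
        grads = self.zero_grads()
        for g, cache, dz in zip(graphs, caches, d_logits_batch):
            self._backward_graph(params, g, cache, dz, grads)
        return grads

    # -- losses over parameter vectors (the meta-learning interface) --------

    def loss_and_grad(
        self,
        theta_vec: np.ndarray,
        graphs: Sequence[MolecularGraph],
        labels: np.ndarray,
        mode: str,
        lambda_b: float = 0.0,
        lambda_c: float = 0.0,
        use_br: bool = True,
        use_avuc: bool = True,
    ):
        """(loss, grad vector, aux) for a batch under either classification mode.

        mode="softmax": plain cross-entropy on the raw head outputs (the
        support objective during meta-training).  mode="evidential": the
        combined annealed evidential loss on ReLU evidence.  aux carries the
        per-graph embeddings and logits for attention and reporting.
        """
        params = self.unpack(theta_vec)
        logits, embeds, caches = self.forward(params, graphs)
        labels = np.asarray(labels).astype(int)
        if mode == "softmax":
            loss, d_logits = evidential.softmax_ce_and_grad(logits, labels)
            breakdown = None
        elif mode == "evidential":
            breakdown, d_logits = evidential.evidential_loss_and_logit_grad(
                logits, labels, lambda_b, lambda_c, use_br=use_br, use_avuc=use_avuc
            )
            loss = breakdown.total
        else:
            raise ValueError(f"unknown head mode {mode!r}")
        grads = self.backward(params, graphs, caches, d_logits)
        aux = {"logits": logits, "embeddings": embeds, "breakdown": breakdown}
        return loss, self.pack(grads), aux
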