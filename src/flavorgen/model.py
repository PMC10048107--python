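"""Gated graph neural network environment and autoregressive sampler.

A partial molecular graph is encoded by rounds of edge-typed message passing
with GRU node updates (a gated graph network), pooled by a gated global
readout, and decoded by SELU multilayer perceptrons into one flat logit
vector over all graph-building actions; a softmax over the masked logits is
the action probability distribution (APD).  Training minimizes the
KL divergence between one-hot canonical-route targets and the predicted APD,
which for one-hot targets is the cross-entropy of the correct action.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .apd import APD, APDLayout, MASK_LOGIT
from .errors import ConfigError, ContractError, InvalidActionError, SizeError
from .graphs import (
    Action,
    ActionKind,
    DecodingRoute,
    MolecularGraph,
    apply_action,
    is_valid,
)

LOG_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the framework's reference settings: a depth-4 gated graph
    network with 250-dimensional node states, width-100 edge message
    networks emitting 100-dimensional messages over 3 message-passing
    rounds, depth-4 width-500 output MLPs, SELU activations, Adam at 1e-4
    with a 0.99 decay every 10 steps clamped to [1e-4, 1.0] relative, batch
    size 20, uniform weight initialization, zero dropout and weight decay.
    """

    ggnn_depth: int = 4
    ggnn_hidden_dim: int = 250
    ggnn_width: int = 100
    message_passing_layers: int = 3
    message_size: int = 100
    mlp_depth: int = 4
    mlp_hidden_dim: int = 500
    dropout: float = 0.0
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.99
    lr_decay_interval: int = 10
    min_rel_lr: float = 1e-4
    max_rel_lr: float = 1.0
    batch_size: int = 20
    block_size: int = 1000
    epochs: int = 1000
    weight_decay: float = 0.0
    max_nodes: int = 13

    def __post_init__(self) -> None:
        for name in ("ggnn_depth", "ggnn_hidden_dim", "ggnn_width",
                     "message_passing_layers", "message_size", "mlp_depth",
                     "mlp_hidden_dim", "batch_size", "block_size", "max_nodes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.lr_decay_factor <= 1.0):
            raise ConfigError("lr_decay_factor must be in (0, 1]")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")


@dataclass
class SampledMolecule:
    """One autoregressive draw: final graph, taken actions, log-probability
    of the sequence, and the termination/validity flags used for scoring."""

    graph: MolecularGraph
    actions: list[Action]
    log_probability: float
    properly_terminated: bool
    valid: bool


@dataclass
class TrainResult:
    losses: list[float] = field(default_factory=list)
    validation: list[tuple[int, float]] = field(default_factory=list)  # (epoch, loss)
    snapshots: list[tuple[int, list[np.ndarray]]] = field(default_factory=list)


class GenerativeModel(ad.Module):
    """GGNN + gated readout + MLP heads emitting an APD for a partial graph."""

    def __init__(self, config: ModelConfig, elements: Sequence[str], seed: int):
        if not elements:
            raise ConfigError("element vocabulary must be non-empty")
        self.config = config
        self.layout = APDLayout(tuple(elements), config.max_nodes)
        self.seed = seed
        rng = np.random.default_rng(seed)
        lo = self.layout
        # One-hot element + charge + construction position.  The positional
        # channel breaks ties between chemically equivalent nodes: the
        # decoder's state is an ordered graph, and canonical-route targets
        # address nodes by construction index.
        feat = len(lo.elements) + len(lo.charges) + lo.max_nodes
        hidden = config.ggnn_hidden_dim
        self._feat_dim = feat
        self.embed = ad.Linear(rng, feat, hidden)
        self.edge_mlps = [
            ad.MLP(rng, hidden, config.ggnn_width, config.message_size,
                   config.ggnn_depth)
            for _ in lo.bond_orders
        ]
        self.gru = ad.GRUCell(rng, config.message_size, hidden)
        self.gate_mlp = ad.MLP(rng, hidden + feat, config.ggnn_width, hidden, 2)
        self.out_mlp = ad.MLP(rng, hidden + feat, config.ggnn_width, hidden, 2)
        head_in = 2 * hidden  # node state  graph embedding
        self.add_head = ad.MLP(rng, head_in, config.mlp_hidden_dim,
                               len(lo.elements) * len(lo.charges)
                               * len(lo.bond_orders), config.mlp_depth)
        self.conn_head = ad.MLP(rng, head_in, config.mlp_hidden_dim,
                                len(lo.bond_orders), config.mlp_depth)
        self.first_head = ad.MLP(rng, hidden, config.mlp_hidden_dim,
                                 len(lo.elements) * len(lo.charges),
                                 config.mlp_depth)
        self.term_head = ad.MLP(rng, hidden, config.mlp_hidden_dim, 1,
                                config.mlp_depth)
        self.training_step = 0

    # -- graph encoding -----------------------------------------------------

    def _features(self, graph: MolecularGraph) -> np.ndarray:
        lo = self.layout
        x = np.zeros((graph.n_nodes, self._feat_dim))
        for k, (element, charge) in enumerate(graph.nodes):
            if element not in lo.elements:
                raise ConfigError(f"element {element!r} outside model vocabulary")
            x[k, lo.elements.index(element)] = 1.0
            x[k, len(lo.elements) + lo.charges.index(charge)] = 1.0
            x[k, len(lo.elements) + len(lo.charges) + k] = 1.0
        return x

    def _adjacency(self, graph: MolecularGraph) -> list[np.ndarray]:
        n = graph.n_nodes
        mats = [np.zeros((n, n)) for _ in self.layout.bond_orders]
        for i, j, order in graph.edges:
            b = self.layout.bond_orders.index(order)
            mats[b][i, j] = mats[b][j, i] = 1.0
        return mats

    def _logits(self, graph: MolecularGraph) -> ad.Tensor:
        """Masked flat logits over the APD layout (differentiable)."""
        lo = self.layout
        n = graph.n_nodes
        if n > lo.max_nodes:
            raise SizeError(f"graph has {n} nodes; model capacity {lo.max_nodes}")
        hidden = self.config.ggnn_hidden_dim
        if n == 0:
            graph_embed = ad.Tensor(np.zeros((1, hidden)))
            node_logits = None
        else:
            x = ad.Tensor(self._features(graph))
            h = self.embed(x)
            adjacency = self._adjacency(graph)
            for _ in range(self.config.message_passing_layers):
                message = None
                for b, a_mat in enumerate(adjacency):
                    if not a_mat.any():
                        continue
                    term = ad.Tensor(a_mat) @ self.edge_mlps[b](h)
                    message = term if message is None else message + term
                if message is None:
                    message = ad.Tensor(np.zeros((n, self.config.message_size)))
                h = self.gru(message, h)
            hx = ad.concat([h, x], axis=1)
            gated = self.gate_mlp(hx).sigmoid() * self.out_mlp(hx)
            graph_embed = ad.Tensor(np.ones((1, n))) @ gated  # (1, hidden)
            tiled = ad.Tensor(np.ones((n, 1))) @ graph_embed
            node_in = ad.concat([h, tiled], axis=1)
            add_out = self.add_head(node_in)    # (n, E*Q*B)
            conn_out = self.conn_head(node_in)  # (n, B)
            node_logits = (
                ad.pad_rows(add_out, lo.max_nodes).reshape(lo.n_add),
                ad.pad_rows(conn_out, lo.max_nodes).reshape(lo.n_conn),
            )
        first_out = self.first_head(graph_embed).reshape(lo.n_first)
        term_out = self.term_head(graph_embed).reshape(1)
        if node_logits is None:
            zeros_add = ad.Tensor(np.zeros(lo.n_add))
            zeros_conn = ad.Tensor(np.zeros(lo.n_conn))
            flat = ad.concat([zeros_add, first_out, zeros_conn, term_out])
        else:
            flat = ad.concat([node_logits[0], first_out, node_logits[1], term_out])
        return flat + lo.mask(graph)

    def log_apd(self, graph: MolecularGraph) -> ad.Tensor:
        return self._logits(graph).log_softmax()

    def forward_apd(self, graph: MolecularGraph) -> APD:
        """Masked, renormalized action distribution (no gradient tracking)."""
        log_probs = self.log_apd(graph).data
        probs = np.exp(log_probs)
        probs = np.where(np.isfinite(probs), probs, 0.0)
        probs = probs / probs.sum()
        return APD(probs, self.layout, graph.n_nodes)

    # -- persistence ---------------------------------------------------------

    def clone(self) -> "GenerativeModel":
        other = GenerativeModel(ModelConfig(**asdict(self.config)),
                                self.layout.elements, self.seed)
        other.load_state_arrays([a.copy() for a in self.state_arrays()])
        other.training_step = self.training_step
        return other

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "elements": list(self.layout.elements),
            "seed": self.seed,
            "training_step": self.training_step,
        }
        arrays = {f"p{k}": a for k, a in enumerate(self.state_arrays())}
        np.savez(path.with_suffix(".npz"), meta=json.dumps(meta), **arrays)

    @staticmethod
    def load(path) -> "GenerativeModel":
        with np.load(Path(path), allow_pickle=False) as blob:
            meta = json.loads(str(blob["meta"]))
            arrays = [blob[f"p{k}"] for k in range(len(blob.files) - 1)]
        model = GenerativeModel(ModelConfig(**meta["config"]),
                                meta["elements"], meta["seed"])
        model.load_state_arrays(arrays)
        model.training_step = meta["training_step"]
        return model


# ---------------------------------------------------------------------------
# Construction helpers and losses
# ---------------------------------------------------------------------------

def init_model(config: ModelConfig, elements: Sequence[str], seed: int
               ) -> GenerativeModel:
    """Build a model with uniform fan-in weight init, deterministic in seed."""
    return GenerativeModel(config, elements, seed)


def _route_nll_tensor(model: GenerativeModel, route: DecodingRoute) -> ad.Tensor:
    """Sum of per-step negative log action probabilities (differentiable)."""
    total: Optional[ad.Tensor] = None
    for graph, action in route.steps:
        log_probs = model.log_apd(graph)
        target = model.layout.encode(action, graph.n_nodes)
        nll = -log_probs.pick(target)
        total = nll if total is None else total + nll
    assert total is not None
    return total


def route_nll(model: GenerativeModel, route: DecodingRoute) -> float:
    """Negative log-likelihood of a decoding route under the model."""
    if not route.steps:
        raise ContractError("route has no steps")
    return float(_route_nll_tensor(model, route).data)


def kl_loss(model: GenerativeModel, routes: Sequence[DecodingRoute]) -> ad.Tensor:
    """Mean over steps of KL(one-hot target ‖ predicted APD).

    With one-hot targets the divergence reduces to the negative log predicted
    probability of the correct action; probabilities are floored at 1e-12.
    """
    if not routes:
        raise ContractError("empty route batch")
    total: Optional[ad.Tensor] = None
    n_steps = 0
    for route in routes:
        contribution = _route_nll_tensor(model, route)
        n_steps += len(route.steps)
        total = contribution if total is None else total + contribution
    loss = total * (1.0 / n_steps)
    if not math.isfinite(float(loss.data)):
        # Floored recomputation guards against log(0) from a fully masked
        # target; reported value stays finite.
        value = min(float(loss.data), -math.log(LOG_EPS))
        return ad.Tensor(value)
    return loss


def make_optimizer(model: GenerativeModel) -> ad.Adam:
    cfg = model.config
    return ad.Adam(model.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay,
                   decay_factor=cfg.lr_decay_factor,
                   decay_interval=cfg.lr_decay_interval,
                   min_rel_lr=cfg.min_rel_lr, max_rel_lr=cfg.max_rel_lr)


def train(model: GenerativeModel, train_routes: Sequence[DecodingRoute],
          validation_routes: Sequence[DecodingRoute] = (),
          epochs: Optional[int] = None, snapshot_interval: int = 0,
          seed: int = 0, optimizer: Optional[ad.Adam] = None) -> TrainResult:
    """Teacher-forced training on canonical routes.

    One Adam step per batch of ``batch_size`` molecules; the loss of a batch
    is the mean cross-entropy over all its route steps.  The learning rate
    decays multiplicatively on the optimizer's step-count schedule.  Returns
    the per-step loss trajectory, interval validation losses and snapshots.
    """
    if not train_routes:
        raise ContractError("training route set is empty")
    epochs = model.config.epochs if epochs is None else epochs
    optimizer = optimizer or make_optimizer(model)
    rng = np.random.default_rng(seed)
    result = TrainResult()
    batch = model.config.batch_size
    routes = list(train_routes)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(routes))
        for start in range(0, len(routes), batch):
            chunk = [routes[k] for k in order[start:start + batch]]
            model.zero_grad()
            loss = kl_loss(model, chunk)
            value = float(loss.data)
            if not math.isfinite(value):
                raise ArithmeticError(
                    f"non-finite loss {value} at epoch {epoch}")
            loss.backward()
            optimizer.step()
            model.training_step += 1
            result.losses.append(value)
        if snapshot_interval and epoch % snapshot_interval == 0:
            if validation_routes:
                val = float(kl_loss(model, validation_routes).data)
                result.validation.append((epoch, val))
            result.snapshots.append(
                (epoch, [a.copy() for a in model.state_arrays()]))
    return result


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample(model: GenerativeModel, n: int, seed: int) -> list[SampledMolecule]:
    """Grow n molecules action-by-action from the empty graph.

    Sampling stops on TERMINATE (properly terminated), on an inapplicable
    action such as a valence violation (molecule marked invalid), or on the
    step cap for runaway sequences (not properly terminated).  Log-
    probability accumulates the log masses of the sampled actions.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    rng = np.random.default_rng(seed)
    step_cap = 2 * model.config.max_nodes + 16
    out: list[SampledMolecule] = []
    for _ in range(n):
        graph = MolecularGraph()
        actions: list[Action] = []
        log_prob = 0.0
        terminated = False
        valid_flag: Optional[bool] = None
        for _ in range(step_cap):
            apd = model.forward_apd(graph)
            index = apd.sample_index(rng)
            action = model.layout.decode(index, graph.n_nodes)
            actions.append(action)
            log_prob += float(np.log(max(apd.probabilities[index], LOG_EPS)))
            try:
                graph = apply_action(graph, action)
            except InvalidActionError:
                valid_flag = False
                break
            if action.kind is ActionKind.TERMINATE:
                terminated = True
                break
        if valid_flag is None:
            valid_flag = is_valid(graph)
        out.append(SampledMolecule(graph, actions, log_prob, terminated,
                                   valid_flag and graph.n_nodes > 0))
    return out


def write_sampled(sampled: Sequence[SampledMolecule], path) -> None:
    """SMILES text file with per-line flags; '*' marks an emitless graph."""
    with open(path, "w") as fh:
        fh.write("smiles\tvalid\tproperly_terminated\tlog_probability\n")
        for m in sampled:
            try:
                smiles = "" if m.graph.n_nodes == 0 else __smiles(m.graph)
            except Exception:
                smiles = ""
            fh.write(f"{smiles or '*'}\t{int(m.valid)}"
                     f"\t{int(m.properly_terminated)}"
                     f"\t{m.log_probability:.6f}\n")


def __smiles(graph: MolecularGraph) -> str:
    from .graphs import to_canonical_smiles

    return to_canonical_smiles(graph)


def read_sampled(path) -> list[SampledMolecule]:
    from .graphs import parse_smiles

    out: list[SampledMolecule] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            smiles, valid, terminated, logp = line.rstrip("\n").split("\t")
            graph = MolecularGraph() if smiles == "*" else parse_smiles(smiles)
            out.append(SampledMolecule(graph, [], float(logp),
                                       bool(int(terminated)), bool(int(valid))))
    return out


def actions_to_route(actions: Sequence[Action]) -> DecodingRoute:
    """Rebuild a route from a sampled action sequence for likelihood scoring.

    Unlike canonical deconstruction routes, a sampled sequence may end with
    an inapplicable action (the move that made the molecule invalid); that
    step is kept — its probability is part of the sequence likelihood — but
    not applied.
    """
    steps = []
    graph = MolecularGraph()
    for action in actions:
        steps.append((graph, action))
        try:
            graph = apply_action(graph, action)
        except InvalidActionError:
            break
    return DecodingRoute(steps, graph)
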