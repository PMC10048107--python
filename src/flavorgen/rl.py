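"""Reinforcement-learning fine-tuning with a best-agent memory policy.

The trained generative model becomes the frozen reference; a copy of it is
the agent.  Each batch, the agent samples molecules, the reward stack scores
them, and the agent takes one gradient step on a squared-gap loss between
its own log-likelihood of each action sequence and the score-augmented
reference log-likelihood:

    J_mol = [log P(B|agent) - (log P(B|ref) + sigma * S(B))]^2

so minimization pulls high-scoring sequences above the reference likelihood.
The batch loss mixes the current batch with the best-scoring batch seen so
far (remembered together with the agent snapshot that produced it), weighted
by alpha:

    J = (1-alpha)/N * sum_current J_mol(agent, ref)
      + alpha/N     * sum_best    J_mol(agent, best_agent)

Snapshot selection after fine-tuning minimizes UC-JSD with validity and
uniqueness tie-breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .errors import ConfigError, ContractError
from .graphs import Action
from .metrics import EvalReport, evaluate_set, uc_jsd
from .model import (
    GenerativeModel,
    SampledMolecule,
    _route_nll_tensor,
    actions_to_route,
    make_optimizer,
    route_nll,
    sample,
)
from .scoring import FragmentScoreTable, final_scores


@dataclass
class RLConfig:
    """Fine-tuning hyperparameters: alpha weights the best-agent memory term,
    sigma scales the score's pull on the reference likelihood."""

    alpha: float = 0.50
    sigma: float = 20.0
    epochs: int = 500
    batch_size: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass(frozen=True)
class MoleculeLossInputs:
    """Log-likelihood pair and score for one action sequence B."""

    agent_logp: float      # log P(B | agent)
    reference_logp: float  # log P(B | reference)
    score: float           # S(B) in [0, 1]

    def __post_init__(self) -> None:
        if self.agent_logp > 0 or self.reference_logp > 0:
            raise ContractError("log-probabilities must be <= 0")
        if not 0.0 <= self.score <= 1.0:
            raise ContractError("score must lie in [0, 1]")


@dataclass
class BatchLossInputs:
    current: list[MoleculeLossInputs]
    memory: list[MoleculeLossInputs]

    def __post_init__(self) -> None:
        if not self.current:
            raise ContractError("batch must contain at least one molecule")


def _squared_gap(agent_logp, reference_logp, score, sigma):
    gap = agent_logp - (reference_logp + sigma * score)
    return gap * gap


def molecule_loss(inputs: MoleculeLossInputs, sigma: float) -> float:
    """Squared gap between agent and score-augmented reference likelihoods."""
    for value in (inputs.agent_logp, inputs.reference_logp):
        if not math.isfinite(value):
            raise ArithmeticError("non-finite log-probability")
    return float(_squared_gap(inputs.agent_logp, inputs.reference_logp,
                              inputs.score, sigma))


def batch_loss(inputs: BatchLossInputs, config: RLConfig) -> float:
    """Alpha-weighted mix of current-batch and remembered-batch losses.

    Both terms are normalized by the current batch size N; at alpha = 0 this
    is exactly the mean current-batch molecule loss, at alpha = 1 only the
    remembered term survives.
    """
    n = len(inputs.current)
    current = sum(molecule_loss(m, config.sigma) for m in inputs.current)
    remembered = sum(molecule_loss(m, config.sigma) for m in inputs.memory)
    return (1.0 - config.alpha) / n * current + config.alpha / n * remembered


@dataclass
class AgentMemory:
    """Best-scoring batch so far, with the agent snapshot that produced it."""

    best_state: Optional[list[np.ndarray]] = None
    best_batch: list[tuple[list[Action], float]] = field(default_factory=list)
    best_reference_logps: list[float] = field(default_factory=list)
    best_mean_score: float = -math.inf

    def update(self, state: list[np.ndarray],
               batch: list[tuple[list[Action], float]],
               reference_logps: list[float], mean_score: float) -> bool:
        if mean_score <= self.best_mean_score:
            return False
        self.best_state = [a.copy() for a in state]
        self.best_batch = batch
        self.best_reference_logps = list(reference_logps)
        self.best_mean_score = mean_score
        return True


@dataclass
class FinetuneResult:
    diagnostics: list[dict] = field(default_factory=list)
    snapshots: list[tuple[int, list[np.ndarray]]] = field(default_factory=list)
    memory: AgentMemory = field(default_factory=AgentMemory)


def finetune(prior: GenerativeModel, config: RLConfig,
             sa_table: FragmentScoreTable, np_table: FragmentScoreTable,
             seed: int, n_batches: Optional[int] = None,
             snapshot_interval: int = 0,
             reward_override=None) -> tuple[GenerativeModel, FinetuneResult]:
    """Fine-tune a copy of ``prior`` for ``n_batches`` RL batches.

    Per batch: sample ``batch_size`` molecules from the agent, score them,
    take one Adam step on the memory-mixed squared-gap loss, and update the
    best-batch memory when the batch mean score improves.  The reference
    model stays frozen at ``prior`` throughout.  ``reward_override`` replaces
    the reward stack with a callable SampledMolecule -> score in [0, 1]
    (used for toy shaping experiments).  Deterministic in seed.
    """
    n_batches = config.epochs if n_batches is None else n_batches
    agent = prior.clone()
    reference = prior  # frozen
    optimizer = make_optimizer(agent)
    rng = np.random.default_rng(seed)
    memory = AgentMemory()
    result = FinetuneResult(memory=memory)
    base_epoch = prior.training_step

    for batch_idx in range(1, n_batches + 1):
        batch_seed = int(rng.integers(2 ** 31))
        sampled = sample(agent, config.batch_size, batch_seed)
        if reward_override is not None:
            scores = [float(reward_override(m)) for m in sampled]
        else:
            breakdowns = final_scores(sampled, sa_table, np_table,
                                      agent.config.max_nodes)
            scores = [b.final_score for b in breakdowns]
        mean_score = float(np.mean(scores))

        routes = [actions_to_route(m.actions) for m in sampled]
        ref_logps = [-route_nll(reference, r) for r in routes]
        pre_step_state = [a.copy() for a in agent.state_arrays()]

        # memory term reference: the best-agent snapshot (prior on batch 1)
        if memory.best_state is None:
            memory.update(pre_step_state,
                          [(m.actions, s) for m, s in zip(sampled, scores)],
                          ref_logps, mean_score)

        agent.zero_grad()
        loss = None
        n = len(sampled)
        for route, ref_logp, score in zip(routes, ref_logps, scores):
            agent_logp = -_route_nll_tensor(agent, route)
            term = _squared_gap(agent_logp, ref_logp, score, config.sigma)
            loss = term if loss is None else loss + term
        loss = loss * ((1.0 - config.alpha) / n)
        if config.alpha > 0.0 and memory.best_batch:
            best_agent = agent.clone()
            best_agent.load_state_arrays(memory.best_state)
            mem_term = None
            for (actions, score), cached in zip(memory.best_batch,
                                                memory.best_reference_logps):
                mem_route = actions_to_route(actions)
                best_logp = -route_nll(best_agent, mem_route)
                agent_logp = -_route_nll_tensor(agent, mem_route)
                term = _squared_gap(agent_logp, best_logp, score, config.sigma)
                mem_term = term if mem_term is None else mem_term + term
            loss = loss + mem_term * (config.alpha / n)
        loss_value = float(loss.data)
        if not math.isfinite(loss_value):
            raise ArithmeticError(
                f"non-finite RL loss at batch {batch_idx}; "
                f"scores={scores}, ref_logps={ref_logps}")
        loss.backward()
        optimizer.step()
        agent.training_step += 1

        memory.update(pre_step_state,
                      [(m.actions, s) for m, s in zip(sampled, scores)],
                      ref_logps, mean_score)

        report = evaluate_set(sampled, epoch=base_epoch + batch_idx)
        result.diagnostics.append({
            "epoch": base_epoch + batch_idx,
            "mean_score": mean_score,
            "loss": loss_value,
            "best_mean_score": memory.best_mean_score,
            "PV": report.pv,
            "PU": report.pu,
        })
        if snapshot_interval and batch_idx % snapshot_interval == 0:
            result.snapshots.append((base_epoch + batch_idx,
                                     [a.copy() for a in agent.state_arrays()]))
    return agent, result


def select_agent(reports: Sequence[tuple[int, EvalReport]]) -> int:
    """Pick the snapshot epoch minimizing UC-JSD.

    Ties break toward higher PV, then higher PU, then the lower epoch.
    """
    evaluated = [(epoch, r) for epoch, r in reports if r.uc_jsd is not None]
    if not evaluated:
        raise ContractError("no snapshot carries an evaluation report")
    return min(evaluated,
               key=lambda er: (er[1].uc_jsd, -er[1].pv, -er[1].pu, er[0]))[0]
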