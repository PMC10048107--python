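"""Shared fixtures: synthetic record sets, calibrated score tables, and the
small trained models the heavier behavioural tests reuse."""

import numpy as np
import pytest
from hypothesis import settings

import flavorgen as fg
from flavorgen.graphs import deconstruction_route, parse_smiles
from flavorgen.model import ModelConfig, init_model, train
from flavorgen.scoring import fixture_tables

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

FIXTURE_SEED = 123


@pytest.fixture(scope="session")
def records200():
    return fg.generate_fixtures(200, FIXTURE_SEED)


@pytest.fixture(scope="session")
def records100():
    return fg.generate_fixtures(100, FIXTURE_SEED)


@pytest.fixture(scope="session")
def score_tables(records200):
    return fixture_tables([r.smiles for r in records200])


def tiny_model_config(**overrides) -> ModelConfig:
    base = dict(ggnn_depth=2, ggnn_hidden_dim=32, ggnn_width=32,
                message_passing_layers=2, message_size=32,
                mlp_depth=2, mlp_hidden_dim=64, batch_size=20,
                learning_rate=5e-3, max_nodes=13)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def pentanol_route():
    return deconstruction_route(parse_smiles("CCCCCO"))


@pytest.fixture(scope="session")
def pentanol_overfit(pentanol_route):
    """Minimal model driven to memorize pentan-1-ol's canonical route."""
    model = init_model(tiny_model_config(), ["C", "N", "O", "S"], seed=0)
    result = train(model, [pentanol_route], epochs=300, seed=0)
    return model, result


@pytest.fixture(scope="session")
def small_trained_model():
    """A 16-wide model briefly trained on ten fixture molecules; the prior
    for reinforcement-learning behaviour tests."""
    records = fg.generate_fixtures(10, 3)
    routes = [deconstruction_route(parse_smiles(r.smiles)) for r in records]
    model = init_model(
        tiny_model_config(ggnn_hidden_dim=16, ggnn_width=16, message_size=16,
                          mlp_hidden_dim=32, max_nodes=16),
        ["C", "N", "O", "S"], seed=0)
    train(model, routes, epochs=40, seed=0)
    return model, routes


@pytest.fixture(scope="session")
def size_reward_run(small_trained_model):
    """50 RL batches on a toy size-only reward (the reward-climbing oracle)."""
    from flavorgen.rl import RLConfig, finetune

    model, _ = small_trained_model
    prior = model.clone()
    prior.config.learning_rate = 1e-3

    def size_only(m):
        return float(m.valid and m.properly_terminated
                     and 0 < m.graph.n_nodes <= 16)

    rl = RLConfig(alpha=0.5, sigma=20.0, batch_size=20)
    agent, result = finetune(prior, rl, None, None, seed=7,
                             n_batches=50, reward_override=size_only)
    return agent, result
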