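"""Run configuration: a flat key-value file covering every hyperparameter.

Keys are the framework's parameter names in snake case (``a`` is the
best-agent weight alpha, ``sigma`` the score scale), plus paths and the
global seed.  Lines are ``key value`` or ``key = value``; ``#`` starts a
comment.  Unknown keys raise ConfigError so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .data import SplitSpec
from .errors import ConfigError
from .model import ModelConfig
from .rl import RLConfig


@dataclass
class RunConfig:
    # best-agent policy
    a: float = 0.50
    sigma: float = 20.0
    # schedule
    batch_size: int = 20
    block_size: int = 1000
    epochs: int = 500                # reinforcement-learning epochs
    generative_epochs: int = 1000
    generation_epoch: int = 1040     # chosen agent snapshot (informational)
    # gated graph network
    ggnn_activation_function: str = "SELU"
    ggnn_depth: int = 4
    ggnn_dropout_probability: float = 0.0
    ggnn_hidden_dimension: int = 250
    ggnn_width: int = 100
    message_passing_layers: int = 3
    message_size: int = 100
    # output MLPs
    mlp_activation_function: str = "SoftMax"
    mlp_depth: int = 4
    mlp_dropout_probability: float = 0.0
    mlp_hidden_dimension: int = 500
    # optimization
    loss_function: str = "Kullback-Leibler divergence"
    optimizer: str = "Adam"
    initial_learning_rate: float = 1e-4
    learning_rate_decay_factor: float = 0.99
    learning_rate_decay_interval: int = 10
    maximum_relative_learning_rate: float = 1.0
    minimum_relative_learning_rate: float = 1e-4
    weight_decay: float = 0.0
    weight_initialization: str = "Uniform"
    # sampling / evaluation
    number_of_samples: int = 200
    max_nodes: int = 13
    snapshot_interval: int = 10
    # dataset split
    train_fraction: float = 0.6
    test_fraction: float = 0.2
    validation_fraction: float = 0.2
    # paths and seed
    dataset_csv: str = ""
    sa_table: str = ""
    np_table: str = ""
    output_dir: str = "runs"
    seed: int = 0

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            ggnn_depth=self.ggnn_depth,
            ggnn_hidden_dim=self.ggnn_hidden_dimension,
            ggnn_width=self.ggnn_width,
            message_passing_layers=self.message_passing_layers,
            message_size=self.message_size,
            mlp_depth=self.mlp_depth,
            mlp_hidden_dim=self.mlp_hidden_dimension,
            dropout=self.ggnn_dropout_probability,
            learning_rate=self.initial_learning_rate,
            lr_decay_factor=self.learning_rate_decay_factor,
            lr_decay_interval=self.learning_rate_decay_interval,
            min_rel_lr=self.minimum_relative_learning_rate,
            max_rel_lr=self.maximum_relative_learning_rate,
            batch_size=self.batch_size,
            block_size=self.block_size,
            epochs=self.generative_epochs,
            weight_decay=self.weight_decay,
            max_nodes=self.max_nodes,
        )

    def rl_config(self) -> RLConfig:
        return RLConfig(alpha=self.a, sigma=self.sigma, epochs=self.epochs,
                        batch_size=self.batch_size)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(self.train_fraction, self.test_fraction,
                         self.validation_fraction, self.seed)


_FIELDS = {f.name: f.type for f in fields(RunConfig)}


def _coerce(name: str, raw: str):
    kind = _FIELDS[name]
    if kind in ("int", int):
        return int(raw)
    if kind in ("float", float):
        return float(raw)
    return raw


def load_config(path, **overrides) -> RunConfig:
    """Parse a flat key-value config file; overrides win over file values."""
    values: dict = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, raw = line.partition("=")
        else:
            key, _, raw = line.partition(" ")
        key, raw = key.strip().lower(), raw.strip()
        if key not in _FIELDS:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        if not raw:
            raise ConfigError(f"{path}:{lineno}: missing value for {key!r}")
        try:
            values[key] = _coerce(key, raw)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: {exc}") from exc
    values.update(overrides)
    return RunConfig(**values)
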