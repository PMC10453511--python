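"""Per-gene forecasters ("agents") and their architecture/hyperparameter space.

Each agent is a small regression network h_i mapping the shared state
matrix — the last ``m`` normalized expression values of all ``n`` genes,
flattened gene-major — to its own gene's next value.  Three architecture
families are supported: a fully connected net (FCNN), a 1-D convolutional
net over the time axis (CNN), and an LSTM recurrent net (RNN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .datasets import SupervisedSet
from .errors import DataError, SpecError

__all__ = [
    "ARCHITECTURES",
    "SEARCH_SPACE",
    "AgentSpec",
    "Agent",
    "default_spec",
    "build_model",
    "train_agent",
    "tune_hyperparameters",
    "make_agent",
]

ARCHITECTURES = ("FCNN", "CNN", "RNN")

# Declared hyperparameter search space for random search.
SEARCH_SPACE = {
    "dense_widths": (16, 32, 64, 128),
    "activations": ("relu", "tanh", "sigmoid"),
    "dropout": (0.0, 0.5),            # uniform
    "lstm_units": (16, 32, 64),
    "learning_rate": (1e-4, 1e-2),    # log-uniform
}


@dataclass(frozen=True)
class AgentSpec:
    """Architecture plus hyperparameters of one agent.

    ``dense_widths`` has three entries for FCNN (its three tunable blocks)
    and two for CNN/RNN (the blocks after convolution/recurrence).
    """

    architecture: str
    n_genes: int
    window: int
    dense_widths: tuple[int, ...] = (64, 32, 16)
    activation: str = "relu"
    dropout: float = 0.1
    lstm_units: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SpecError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        n_dense = 3 if self.architecture == "FCNN" else 2
        if len(self.dense_widths) != n_dense:
            raise SpecError(
                f"{self.architecture} needs {n_dense} dense widths, got {self.dense_widths}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise SpecError(f"dropout {self.dropout} outside [0, 1)")

    @property
    def input_dim(self) -> int:
        return self.n_genes * self.window

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Agent:
    """A trained forecaster for one gene."""

    spec: AgentSpec
    gene_index: int
    network: nn.Network
    train_error: float
    test_error: float

    def predict(self, state_values: np.ndarray) -> float:
        """Apply h_i to an (n, m) state matrix; gene-major flattening."""
        state_values = np.asarray(state_values, dtype=float)
        if state_values.shape != (self.spec.n_genes, self.spec.window):
            raise DataError(
                f"state matrix shape {state_values.shape} != "
                f"({self.spec.n_genes}, {self.spec.window})"
            )
        x = state_values.reshape(1, -1)
        return float(self.network.forward(x, train=False)[0, 0])


def default_spec(architecture: str, n_genes: int, window: int) -> AgentSpec:
    """Fixed hyperparameters used when no tuning budget is spent.

    Selected by held-out one-step forecast error on synthetic benchmark
    systems: small layers and a learning rate large enough for full-batch
    Adam to converge within the epoch budget; dropout off by default at
    these sample sizes.
    """
    if architecture == "FCNN":
        return AgentSpec(architecture, n_genes, window, dense_widths=(16, 16, 16),
                         dropout=0.0, learning_rate=1e-2)
    return AgentSpec(architecture, n_genes, window, dense_widths=(16, 16),
                     dropout=0.0, learning_rate=1e-2, lstm_units=16)


def build_model(spec: AgentSpec, seed: int = 0) -> nn.Network:
    """Instantiate the untrained network for a spec.

    FCNN: three dense+activation blocks (dropout after the first) and a
    scalar head.  CNN: Conv1D(64 filters, kernel 2) -> activation ->
    MaxPool1D(2) -> two dense blocks with dropout -> scalar head.  RNN:
    LSTM -> activation -> two dense blocks with dropout -> scalar head.
    CNN/RNN view the input as m timesteps x n channels.
    """
    rng = np.random.default_rng(seed)
    n, m = spec.n_genes, spec.window
    act = spec.activation
    w = spec.dense_widths
    if spec.architecture == "FCNN":
        layers = [
            nn.Dense(n * m, w[0], rng),
            nn.Activation(act),
            nn.Dropout(spec.dropout, rng),
            nn.Dense(w[0], w[1], rng),
            nn.Activation(act),
            nn.Dense(w[1], w[2], rng),
            nn.Activation(act),
            nn.Dense(w[2], 1, rng),
        ]
    elif spec.architecture == "CNN":
        t_pool = m // 2  # same-length conv keeps m timesteps; pool halves
        if t_pool < 1:
            raise SpecError(f"window m={m} too short for conv(kernel 2) + pool(2)")
        layers = [
            nn.Reshape(n, m),
            nn.Conv1D(n, 64, 2, rng),
            nn.Activation(act),
            nn.MaxPool1D(2),
            nn.Flatten(),
            nn.Dense(t_pool * 64, w[0], rng),
            nn.Activation(act),
            nn.Dropout(spec.dropout, rng),
            nn.Dense(w[0], w[1], rng),
            nn.Activation(act),
            nn.Dense(w[1], 1, rng),
        ]
    else:  # RNN
        layers = [
            nn.Reshape(n, m),
            nn.LSTM(n, spec.lstm_units, rng),
            nn.Activation(act),
            nn.Dense(spec.lstm_units, w[0], rng),
            nn.Activation(act),
            nn.Dropout(spec.dropout, rng),
            nn.Dense(w[0], w[1], rng),
            nn.Activation(act),
            nn.Dense(w[1], 1, rng),
        ]
    return nn.Network(layers)


def train_agent(spec: AgentSpec, supervised: SupervisedSet, seed: int = 0) -> Agent:
    """Train one agent with a chronological 80/20 train/test split.

    Minimizes MSE with Adam and early stopping; the recorded test error is
    the held-out MSE at the best-validation epoch.  Deterministic given
    (spec, data, seed).
    """
    n_rows = len(supervised)
    if n_rows < 2:
        raise DataError("supervised set needs at least 2 rows")
    split = max(1, int(round(0.8 * n_rows)))
    if split == n_rows:
        split = n_rows - 1
    x_tr, y_tr = supervised.inputs[:split], supervised.targets[:split]
    x_te, y_te = supervised.inputs[split:], supervised.targets[split:]
    net = build_model(spec, seed=seed)
    train_err, test_err = nn.train_network(
        net, x_tr, y_tr, x_te, y_te,
        learning_rate=spec.learning_rate,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        seed=seed,
    )
    return Agent(
        spec=spec,
        gene_index=supervised.gene_index,
        network=net,
        train_error=train_err,
        test_error=test_err,
    )


def _sample_spec(architecture: str, n: int, m: int, rng: np.random.Generator) -> AgentSpec:
    sp = SEARCH_SPACE
    n_dense = 3 if architecture == "FCNN" else 2
    widths = tuple(int(rng.choice(sp["dense_widths"])) for _ in range(n_dense))
    lo, hi = sp["learning_rate"]
    return AgentSpec(
        architecture=architecture,
        n_genes=n,
        window=m,
        dense_widths=widths,
        activation=str(rng.choice(sp["activations"])),
        dropout=float(rng.uniform(*sp["dropout"])),
        lstm_units=int(rng.choice(sp["lstm_units"])),
        learning_rate=float(math.exp(rng.uniform(math.log(lo), math.log(hi)))),
    )


def tune_hyperparameters(
    architecture: str,
    supervised: SupervisedSet,
    budget: int = 10,
    seed: int = 0,
) -> AgentSpec:
    """Random search over :data:`SEARCH_SPACE`; lowest test error wins.

    Ties go to the first-evaluated candidate.  Each candidate is trained
    with a seed derived deterministically from ``seed``.
    """
    if budget < 1:
        raise SpecError("tuning budget must be >= 1")
    n = supervised.inputs.shape[1] // supervised.window
    rng = np.random.default_rng(seed)
    best: AgentSpec | None = None
    best_err = np.inf
    for trial in range(budget):
        spec = _sample_spec(architecture, n, supervised.window, rng)
        agent = train_agent(spec, supervised, seed=seed + trial)
        if agent.test_error < best_err:
            best_err = agent.test_error
            best = spec
    assert best is not None
    return best


def make_agent(
    architecture: str,
    supervised: SupervisedSet,
    tuning_budget: int = 0,
    seed: int = 0,
) -> Agent:
    """Tune (optionally) then train; the one-stop constructor used upstream."""
    n = supervised.inputs.shape[1] // supervised.window
    if tuning_budget and tuning_budget > 1:
        spec = tune_hyperparameters(architecture, supervised, tuning_budget, seed)
    else:
        spec = default_spec(architecture, n, supervised.window)
    return train_agent(spec, supervised, seed=seed)
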