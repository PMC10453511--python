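"""The Artificial Environmental Setting (AES): a closed-loop simulator.

All agents share one state matrix X(t) — the last ``m`` expression values
of every gene, columns oldest to newest.  A synchronous clock advances the
system: each agent reads the *same* pre-step state, their outputs form
x(t+1), the state matrix shifts left one column and appends it.  A manual
perturbation overrides one gene's entry of x(t+1) with a prescribed
function of time, bypassing that gene's agent for the perturbation's
duration while every other gene keeps evolving (and sees the perturbed
history through the shared state matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import ExpressionDataset
from .errors import DataError, NumericError, SpecError

__all__ = [
    "StateMatrix",
    "SimulationTrace",
    "PerturbationSpec",
    "perturbation_value",
    "seed_initial_state",
    "AES",
]


@dataclass
class StateMatrix:
    """n x m matrix of recent expression; ``t`` indexes the newest column."""

    values: np.ndarray
    t: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("state matrix must be 2-D (genes x window)")
        if not np.all(np.isfinite(self.values)):
            raise NumericError("state matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def window(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "StateMatrix":
        return StateMatrix(self.values.copy(), self.t)


@dataclass
class SimulationTrace:
    """Expression over simulated time, shape (n, T); first m columns are the seed."""

    values: np.ndarray
    window: int
    perturbations: list["PerturbationSpec"] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PerturbationSpec:
    """Manual override of one gene for ``duration`` steps.

    ``instant`` jumps to baseline+width immediately and holds; ``trapezium``
    ramps up, holds the peak for ``peak_steps``, and ramps back down.  All
    values stay within [baseline, baseline+width], itself within
    [0, gene_max].
    """

    kind: str
    gene_index: int
    baseline: float
    width: float
    duration: int
    peak_steps: int | None = None
    start: int = 0
    gene_max: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("instant", "trapezium"):
            raise SpecError(f"unknown perturbation kind {self.kind!r}")
        if self.duration < 1:
            raise SpecError("duration must be >= 1")
        if self.width < 0 or self.baseline < 0:
            raise SpecError("baseline and width must be non-negative")
        if self.baseline + self.width > self.gene_max + 1e-9:
            raise SpecError(
                f"baseline+width {self.baseline + self.width:.4g} exceeds "
                f"gene_max {self.gene_max:.4g}"
            )
        if self.kind == "trapezium":
            if self.peak_steps is None or not 1 <= self.peak_steps <= self.duration:
                raise SpecError("trapezium needs 1 <= peak_steps <= duration")

    def active_at(self, t: int) -> bool:
        return self.start <= t < self.start + self.duration


def perturbation_value(spec: PerturbationSpec, s: int) -> float:
    """Override value at step offset ``s`` in [0, duration)."""
    if not 0 <= s < spec.duration:
        raise SpecError(f"step offset {s} outside [0, {spec.duration})")
    if spec.kind == "instant":
        return spec.baseline + spec.width
    ramp = (spec.duration - spec.peak_steps) // 2  # symmetric; remainder to plateau
    if ramp == 0:
        return spec.baseline + spec.width
    if s < ramp:  # rising edge
        return spec.baseline + spec.width * (s + 1) / ramp
    if s >= spec.duration - ramp:  # falling edge
        return spec.baseline + spec.width * (spec.duration - s - 1) / ramp
    return spec.baseline + spec.width


def seed_initial_state(
    trace_source: ExpressionDataset | np.ndarray,
    m: int,
    zeros: bool = False,
) -> StateMatrix:
    """Fill X with the first ``m`` observations (or zeros) of the source.

    The source is an (b, n) observations-by-genes matrix or a dataset whose
    experiment average provides it.
    """
    if isinstance(trace_source, ExpressionDataset):
        obs = trace_source.mean_experiment()
    else:
        obs = np.asarray(trace_source, dtype=float)
    if obs.ndim != 2:
        raise DataError("trace source must be 2-D (observations x genes)")
    n = obs.shape[1]
    if zeros:
        return StateMatrix(np.zeros((n, m)), t=m - 1)
    if obs.shape[0] < m:
        raise DataError(f"need >= {m} observations to seed the state, got {obs.shape[0]}")
    return StateMatrix(obs[:m, :].T.copy(), t=m - 1)


class AES:
    """Agents plus the shared state matrix, advanced by a synchronous clock."""

    def __init__(self, agents: Sequence, clip: tuple[float, float] | None = (0.0, 1.5)):
        if not agents:
            raise DataError("an AES needs at least one agent")
        self.agents = list(agents)
        self.clip = clip

    @property
    def n_genes(self) -> int:
        return len(self.agents)

    def step(
        self,
        state: StateMatrix,
        perturbations: Sequence[PerturbationSpec] = (),
    ) -> tuple[StateMatrix, np.ndarray]:
        """One clock tick: synchronous agent update, then perturbation overrides.

        Every agent reads the same pre-step state matrix; results never
        depend on agent evaluation order.  Active perturbations overwrite
        their gene's entry of x(t+1) regardless of the agent output.
        """
        if state.n_genes != self.n_genes:
            raise DataError("state matrix gene count does not match agent count")
        t_new = state.t + 1
        x_new = np.empty(self.n_genes)
        frozen = state.values.copy()
        frozen.setflags(write=False)  # every agent reads the same pre-step state
        for i, agent in enumerate(self.agents):
            try:
                x_new[i] = agent.predict(frozen)
            except Exception as exc:  # noqa: BLE001 - annotate failing gene
                raise NumericError(f"agent for gene {i} failed at t={t_new}: {exc}") from exc
        if self.clip is not None:
            np.clip(x_new, self.clip[0], self.clip[1], out=x_new)
        for spec in perturbations:
            if spec.active_at(t_new):
                x_new[spec.gene_index] = perturbation_value(spec, t_new - spec.start)
        if not np.all(np.isfinite(x_new)):
            raise NumericError(f"non-finite environment state at t={t_new}")
        values = np.empty_like(state.values)
        values[:, :-1] = state.values[:, 1:]
        values[:, -1] = x_new
        return StateMatrix(values, t_new), x_new

    def simulate(
        self,
        initial: StateMatrix,
        T: int,
        perturbations: Sequence[PerturbationSpec] = (),
    ) -> SimulationTrace:
        """Run for ``T`` total steps; columns 0..m-1 are the seeded state.

        The trace column index equals simulated time, so column ``t`` for
        ``t >= m`` holds x(t) produced by the agents (and any active
        perturbation override).
        """
        m = initial.window
        if T < m:
            raise DataError(f"T={T} must be >= window m={m}")
        trace = np.empty((initial.n_genes, T))
        trace[:, :m] = initial.values
        state = initial.copy()
        for _ in range(T - m):
            state, x_new = self.step(state, perturbations)
            trace[:, state.t] = x_new
        return SimulationTrace(values=trace, window=m, perturbations=list(perturbations))
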