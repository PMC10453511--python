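"""High-level workflows: fit an environment, evaluate it, infer a network.

These functions wire the modules together the way the command-line
interface and the examples use them: normalize with constants from the
training experiments, build one supervised set per gene, train agents
(fixed assignment or GA-selected), simulate against the experiment-averaged
target, and optionally run the perturbation protocol to produce regulatory
and probability matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .agents import ARCHITECTURES, Agent, AgentSpec, make_agent
from .datasets import (
    ExpressionDataset,
    GoldNetwork,
    make_supervised,
    min_max_normalize,
)
from .environment import AES, seed_initial_state
from .errors import DataError, SpecError
from .evaluation import EvaluationReport, evaluate_aes
from .inference import (
    PerturbationConfig,
    SteadyStateResult,
    auc_roc,
    build_probability_matrix,
    build_regulatory_matrix,
    ranked_edges,
    thresholds,
)
from .optimization import FitnessEvaluator, GAConfig, run_ga

__all__ = ["AESFit", "InferenceResult", "fit_aes", "evaluate_fit", "infer_network",
           "save_bundle", "load_bundle"]


@dataclass
class AESFit:
    """A trained environment plus everything needed to rerun it."""

    aes: AES
    agents: list[Agent]
    assignment: tuple[str, ...]
    dataset: ExpressionDataset          # normalized
    eval_target: np.ndarray             # (n, b) experiment average
    m: int
    train_experiments: list[int]
    ga_history: list[dict] = field(default_factory=list)

    @property
    def gene_names(self) -> list[str]:
        return self.dataset.gene_names


def _training_indices(k: int, train_fraction: float) -> list[int]:
    n_train = max(1, int(round(train_fraction * k)))
    return list(range(min(n_train, k)))


def fit_aes(
    dataset: ExpressionDataset,
    m: int = 10,
    train_fraction: float = 0.6,
    architecture: str = "FCNN",
    assignment: tuple[str, ...] | None = None,
    use_ga: bool = False,
    ga_config: GAConfig | None = None,
    tuning_budget: int = 0,
    seed: int = 0,
) -> AESFit:
    """Train one agent per gene and assemble the environment.

    The first ``train_fraction`` of experiments supply both the
    normalization constants and the training windows; the evaluation
    target is the average of all (normalized) experiments.  With
    ``use_ga`` the architecture assignment is optimized by the genetic
    algorithm, its initial population seeded with the three uniform
    single-architecture assignments; otherwise ``assignment`` (or a
    uniform ``architecture``) is used as given.
    """
    if dataset.normalized:
        ds = dataset
        train_idx = _training_indices(ds.n_experiments, train_fraction)
    else:
        train_idx = _training_indices(dataset.n_experiments, train_fraction)
        ds = min_max_normalize(dataset, training_experiments=train_idx)
    n = ds.n_genes
    supervised = [make_supervised(ds, i, m, experiments=train_idx) for i in range(n)]
    eval_target = ds.mean_experiment().T
    ga_history: list[dict] = []

    if use_ga:
        config = ga_config or GAConfig(seed=seed)
        evaluator = FitnessEvaluator(
            supervised, eval_target, m, tuning_budget=tuning_budget, seed=seed
        )
        uniform = [tuple(a for _ in range(n)) for a in ARCHITECTURES]
        best, ga_history = run_ga(config, evaluator, n, initial=uniform)
        assignment = best.assignment
        agents = [evaluator.agent_for(i, a) for i, a in enumerate(assignment)]
    else:
        if assignment is None:
            if architecture not in ARCHITECTURES:
                raise SpecError(f"unknown architecture {architecture!r}")
            assignment = tuple(architecture for _ in range(n))
        if len(assignment) != n:
            raise SpecError("assignment length must equal the number of genes")
        seeds = np.random.SeedSequence(seed).spawn(n)
        agents = [
            make_agent(
                arch,
                supervised[i],
                tuning_budget=tuning_budget,
                seed=int(s.generate_state(1)[0] % (2**31)),
            )
            for i, (arch, s) in enumerate(zip(assignment, seeds))
        ]

    return AESFit(
        aes=AES(agents),
        agents=agents,
        assignment=tuple(assignment),
        dataset=ds,
        eval_target=eval_target,
        m=m,
        train_experiments=train_idx,
        ga_history=ga_history,
    )


def evaluate_fit(fit: AESFit) -> EvaluationReport:
    """Simulate the fitted environment over the target and score fidelity."""
    initial = seed_initial_state(fit.eval_target.T, fit.m)
    trace = fit.aes.simulate(initial, fit.eval_target.shape[1])
    return evaluate_aes(trace, fit.eval_target, fit.m)


@dataclass
class InferenceResult:
    regulatory_matrix: np.ndarray
    probability_matrix: np.ndarray
    gene_names: list[str]
    steady: SteadyStateResult
    auc: float | None = None

    def ranked_edges(self, include_self_loops: bool = False):
        return ranked_edges(self.probability_matrix, self.gene_names, include_self_loops)


def infer_network(
    fit: AESFit,
    kind: str = "trapezium",
    gold: GoldNetwork | None = None,
    config: PerturbationConfig | None = None,
) -> InferenceResult:
    """Run the full perturbation protocol on a fitted environment."""
    if config is None:
        config = PerturbationConfig(kind=kind, gene_max=fit.dataset.gene_max())
    initial = seed_initial_state(fit.eval_target.T, fit.m)
    R, steady = build_regulatory_matrix(fit.aes, initial, config)
    ts = thresholds(R)
    P = build_probability_matrix(R, ts)
    auc = auc_roc(P, gold) if gold is not None else None
    return InferenceResult(
        regulatory_matrix=R,
        probability_matrix=P,
        gene_names=fit.gene_names,
        steady=steady,
        auc=auc,
    )


def save_bundle(fit: AESFit, path: str | Path) -> None:
    """Persist a fitted environment: JSON manifest + native weight arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "gene_names": fit.gene_names,
        "m": fit.m,
        "assignment": list(fit.assignment),
        "train_experiments": fit.train_experiments,
        "norm_min": fit.dataset.norm_min.tolist(),
        "norm_max": fit.dataset.norm_max.tolist(),
        "specs": [a.spec.to_dict() for a in fit.agents],
        "errors": [
            {"train": a.train_error, "test": a.test_error} for a in fit.agents
        ],
        "ga_history": [
            {**h, "solution": list(h["solution"])} for h in fit.ga_history
        ],
        "experiments": [e.tolist() for e in fit.dataset.experiments],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    arrays = {}
    for i, agent in enumerate(fit.agents):
        for j, w in enumerate(agent.network.get_weights()):
            arrays[f"agent{i}_param{j}"] = w
    np.savez(path / "weights.npz", **arrays)


def load_bundle(path: str | Path) -> AESFit:
    """Restore a fitted environment saved by :func:`save_bundle`."""
    from .agents import build_model  # local import to avoid cycle noise

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    weights = np.load(path / "weights.npz")
    ds = ExpressionDataset(
        gene_names=manifest["gene_names"],
        experiments=[np.asarray(e) for e in manifest["experiments"]],
        normalized=True,
        norm_min=np.asarray(manifest["norm_min"]),
        norm_max=np.asarray(manifest["norm_max"]),
    )
    agents = []
    for i, spec_dict in enumerate(manifest["specs"]):
        spec_dict = dict(spec_dict)
        spec_dict["dense_widths"] = tuple(spec_dict["dense_widths"])
        spec = AgentSpec(**spec_dict)
        net = build_model(spec, seed=0)
        params = []
        j = 0
        while f"agent{i}_param{j}" in weights:
            params.append(weights[f"agent{i}_param{j}"])
            j += 1
        net.set_weights(params)
        agents.append(
            Agent(
                spec=spec,
                gene_index=i,
                network=net,
                train_error=manifest["errors"][i]["train"],
                test_error=manifest["errors"][i]["test"],
            )
        )
    return AESFit(
        aes=AES(agents),
        agents=agents,
        assignment=tuple(manifest["assignment"]),
        dataset=ds,
        eval_target=ds.mean_experiment().T,
        m=manifest["m"],
        train_experiments=manifest["train_experiments"],
        ga_history=[
            {**h, "solution": tuple(h["solution"])} for h in manifest["ga_history"]
        ],
    )
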