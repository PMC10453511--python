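"""Network inference by in-silico perturbation of a trained environment.

Protocol, per perturbed gene i (each run independent, restarted from the
same stabilized snapshot):

1. simulate to a steady state (all genes within a tolerance band), time t_f;
2. simulate m further stabilization steps;
3. override gene i with a perturbation function for phi_d steps;
4. simulate m recovery steps;
5. record all genes over the instability interval Delta_t_r = 2m + phi_d;
6. per responding gene j, the regulatory value r_ij = arctan(OLS slope of
   its recorded trajectory against step index).

Column-wise medians of the positive/negative regulatory values give each
gene's activation/inhibition thresholds, which calibrate a piecewise map
from r_ij to an edge probability p_ij (probability that gene i regulates
gene j).  Ranked probabilities are scored against a gold standard with
AUC-ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .datasets import GoldNetwork, ordered_pairs
from .environment import AES, PerturbationSpec, StateMatrix, perturbation_value
from .errors import DataError, NumericError, SpecError

__all__ = [
    "SteadyStateResult",
    "ThresholdSet",
    "run_to_steady_state",
    "perturb_and_record",
    "regulatory_value",
    "build_regulatory_matrix",
    "thresholds",
    "edge_probability",
    "build_probability_matrix",
    "auc_roc",
    "ranked_edges",
    "PerturbationConfig",
]


@dataclass
class SteadyStateResult:
    state: StateMatrix
    t_f: int
    converged: bool


def run_to_steady_state(
    aes: AES,
    seed_state: StateMatrix,
    eps: float = 1e-3,
    window: int | None = None,
    t_max: int = 500,
) -> SteadyStateResult:
    """Simulate until every gene's recent range falls below ``eps``.

    Convergence is declared when, over the last ``window`` produced values
    (default: the state-matrix width m), max - min < eps for all genes; the
    snapshot is taken at that point (t_f).  If ``t_max`` steps pass without
    convergence the last state is returned with ``converged=False`` and a
    warning.
    """
    if eps <= 0:
        raise SpecError("eps must be positive")
    m = seed_state.window
    win = m if window is None else window
    state = seed_state.copy()
    history = [state.values[:, -1].copy()]
    for step_no in range(t_max):
        if len(history) >= win:
            recent = np.asarray(history[-win:])
            if float(np.max(recent.max(axis=0) - recent.min(axis=0))) < eps:
                return SteadyStateResult(state=state, t_f=state.t, converged=True)
        state, x_new = aes.step(state)
        history.append(x_new)
    warnings.warn(
        f"no steady state within {t_max} steps (eps={eps}); using last state",
        stacklevel=2,
    )
    return SteadyStateResult(state=state, t_f=state.t, converged=False)


def perturb_and_record(
    aes: AES,
    snapshot: StateMatrix,
    gene_index: int,
    pert_spec: PerturbationSpec,
) -> np.ndarray:
    """Record the instability interval around one gene's perturbation.

    From the snapshot: m stabilization steps, phi_d perturbed steps, m
    recovery steps.  Returns X_r of shape (2m + phi_d, n): the expression
    of all genes over the steps following t_f.
    """
    m = snapshot.window
    phi_d = pert_spec.duration
    start = snapshot.t + m + 1  # first perturbed time index
    spec = PerturbationSpec(
        kind=pert_spec.kind,
        gene_index=gene_index,
        baseline=pert_spec.baseline,
        width=pert_spec.width,
        duration=phi_d,
        peak_steps=pert_spec.peak_steps,
        start=start,
        gene_max=pert_spec.gene_max,
    )
    n_steps = 2 * m + phi_d
    state = snapshot.copy()
    rows = np.empty((n_steps, aes.n_genes))
    for s in range(n_steps):
        state, x_new = aes.step(state, (spec,))
        rows[s] = x_new
    return rows


def regulatory_value(column: np.ndarray) -> float:
    """arctan of the OLS slope of a response trajectory vs. step index."""
    y = np.asarray(column, float).ravel()
    if y.size < 2:
        raise DataError("regulatory value needs >= 2 points")
    t = np.arange(y.size, dtype=float)
    tc = t - t.mean()
    slope = float(tc @ (y - y.mean()) / (tc @ tc))
    return float(np.arctan(slope))


@dataclass
class PerturbationConfig:
    """Defaults for the inference protocol.

    width defaults to half each gene's maximum observed expression;
    baseline defaults to the gene's value at the stabilized snapshot;
    duration defaults to m.
    """

    kind: str = "trapezium"
    duration: int | None = None
    width: float | None = None
    peak_steps: int = 2
    gene_max: np.ndarray | float = 1.0
    eps: float = 1e-3
    t_max: int = 500


def build_regulatory_matrix(
    aes: AES,
    seed_state: StateMatrix,
    config: PerturbationConfig | None = None,
) -> tuple[np.ndarray, SteadyStateResult]:
    """Perturb each gene in turn; row i holds gene i's effect on every gene.

    All runs restart from the same stabilized snapshot so responses are
    independent.  Signed values are retained.
    """
    config = config or PerturbationConfig()
    n = aes.n_genes
    m = seed_state.window
    phi_d = config.duration if config.duration is not None else m
    steady = run_to_steady_state(
        aes, seed_state, eps=config.eps, window=m, t_max=config.t_max
    )
    gmax = np.broadcast_to(np.asarray(config.gene_max, float), (n,))
    baselines = steady.state.values[:, -1]
    R = np.empty((n, n))
    for i in range(n):
        base = float(np.clip(baselines[i], 0.0, gmax[i]))
        width = config.width if config.width is not None else 0.5 * gmax[i]
        width = float(min(width, gmax[i] - base))
        spec = PerturbationSpec(
            kind=config.kind,
            gene_index=i,
            baseline=base,
            width=width,
            duration=phi_d,
            peak_steps=config.peak_steps if config.kind == "trapezium" else None,
            gene_max=float(gmax[i]),
        )
        try:
            x_r = perturb_and_record(aes, steady.state, i, spec)
        except NumericError as exc:
            raise NumericError(f"perturbation run for gene {i} failed: {exc}") from exc
        R[i, :] = [regulatory_value(x_r[:, j]) for j in range(n)]
    return R, steady


@dataclass
class ThresholdSet:
    """Per-gene calibration constants for the probability transform.

    For responding gene j: tau_pos[j] is the median of the strictly
    positive entries of column j of R, tau_neg[j] the median of the
    strictly negative ones, r_max/r_min the column extrema.  A column with
    no positive (or no negative) entries has that side flagged degenerate.
    """

    tau_pos: np.ndarray
    tau_neg: np.ndarray
    r_max: np.ndarray
    r_min: np.ndarray
    pos_degenerate: np.ndarray = field(default_factory=lambda: np.array([], bool))
    neg_degenerate: np.ndarray = field(default_factory=lambda: np.array([], bool))


def thresholds(R: np.ndarray) -> ThresholdSet:
    """Column-wise activation/inhibition thresholds and extrema of R."""
    R = np.asarray(R, float)
    if not np.all(np.isfinite(R)):
        raise DataError("regulatory matrix contains non-finite entries")
    n = R.shape[1]
    tiny = np.sqrt(np.finfo(float).eps)
    tau_pos = np.empty(n)
    tau_neg = np.empty(n)
    pos_deg = np.zeros(n, bool)
    neg_deg = np.zeros(n, bool)
    for j in range(n):
        col = R[:, j]
        pos = col[col > 0]
        neg = col[col < 0]
        if pos.size:
            tau_pos[j] = float(np.median(pos))
        else:
            tau_pos[j] = tiny
            pos_deg[j] = True
            warnings.warn(f"column {j}: no positive regulatory values", stacklevel=2)
        if neg.size:
            tau_neg[j] = float(np.median(neg))
        else:
            tau_neg[j] = -tiny
            neg_deg[j] = True
            warnings.warn(f"column {j}: no negative regulatory values", stacklevel=2)
    return ThresholdSet(
        tau_pos=tau_pos,
        tau_neg=tau_neg,
        r_max=R.max(axis=0),
        r_min=R.min(axis=0),
        pos_degenerate=pos_deg,
        neg_degenerate=neg_deg,
    )


def edge_probability(
    r: float, tau_p: float, tau_n: float, r_max: float, r_min: float
) -> float:
    """Piecewise map from a regulatory value to an edge probability.

    Linear from 1 at r_min down to 1/2 at tau_n; quadratic through
    (tau_n, 1/2), (0, 0), (tau_p, 1/2) in between; linear from 1/2 at
    tau_p up to 1 at r_max.  Values outside [r_min, r_max] are clamped
    with a warning.  With asymmetric thresholds the interpolating parabola
    dips marginally below zero on one side of the origin; the output is
    floored at 0 to keep a valid probability.
    """
    if not (r_min <= tau_n < 0 < tau_p <= r_max):
        raise SpecError(
            f"need r_min <= tau_n < 0 < tau_p <= r_max, got "
            f"({r_min}, {tau_n}, {tau_p}, {r_max})"
        )
    if r < r_min or r > r_max:
        warnings.warn(f"regulatory value {r} outside [{r_min}, {r_max}]; clamped",
                      stacklevel=2)
        r = float(np.clip(r, r_min, r_max))
    if r <= tau_n:
        if r_min == tau_n:
            return 0.5
        return 0.5 + 0.5 * (r - tau_n) / (r_min - tau_n)
    if r >= tau_p:
        if r_max == tau_p:
            return 0.5
        return 0.5 + 0.5 * (r - tau_p) / (r_max - tau_p)
    quad = -(r * r) / (2 * tau_p * tau_n) + (tau_p + tau_n) * r / (2 * tau_p * tau_n)
    return float(max(0.0, quad))


def _one_sided_probability(r: float, tau: float, r_ext: float) -> float:
    """Collapse of the transform when only one sign of response exists.

    Square law from 0 at r=0 to 1/2 at tau, then the usual linear branch
    to 1 at the extremum; the missing side maps to 0.
    """
    if tau == 0:
        return 0.0
    if (r > 0) != (tau > 0) and r != 0:
        return 0.0
    a = abs(r)
    at = abs(tau)
    if a < at:
        return 0.5 * (a / at) ** 2
    ae = abs(r_ext)
    if ae == at:
        return 0.5
    return 0.5 + 0.5 * (a - at) / (ae - at)


def build_probability_matrix(R: np.ndarray, ts: ThresholdSet) -> np.ndarray:
    """Element-wise probability transform; p[i, j] = P(gene i regulates gene j)."""
    R = np.asarray(R, float)
    n_rows, n_cols = R.shape
    P = np.empty_like(R)
    for j in range(n_cols):
        pos_deg = bool(ts.pos_degenerate[j]) if ts.pos_degenerate.size else False
        neg_deg = bool(ts.neg_degenerate[j]) if ts.neg_degenerate.size else False
        for i in range(n_rows):
            r = R[i, j]
            if pos_deg and neg_deg:
                P[i, j] = 0.0
            elif pos_deg:
                P[i, j] = _one_sided_probability(r, ts.tau_neg[j], ts.r_min[j]) if r <= 0 else 0.0
            elif neg_deg:
                P[i, j] = _one_sided_probability(r, ts.tau_pos[j], ts.r_max[j]) if r >= 0 else 0.0
            else:
                P[i, j] = edge_probability(
                    r, ts.tau_pos[j], ts.tau_neg[j], ts.r_max[j], ts.r_min[j]
                )
    return np.clip(P, 0.0, 1.0)


def auc_roc(
    P: np.ndarray, gold: GoldNetwork, include_self_loops: bool | None = None
) -> float:
    """Probability that a random true edge outranks a random non-edge.

    Scores are the flattened probability matrix over ordered (regulator,
    target) pairs, the diagonal excluded unless self-loops are requested.
    """
    include = gold.include_self_loops if include_self_loops is None else include_self_loops
    names = gold.gene_names
    n = len(names)
    P = np.asarray(P, float)
    if P.shape != (n, n):
        raise DataError(f"probability matrix shape {P.shape} != ({n}, {n})")
    pairs = ordered_pairs(names, include)
    index = {g: i for i, g in enumerate(names)}
    scores = np.array([P[index[r], index[t]] for r, t in pairs])
    labels = np.array([gold.label(r, t) for r, t in pairs])
    if labels.min() == labels.max():
        raise DataError("gold standard has a single class; AUC undefined")
    return float(roc_auc_score(labels, scores))


def ranked_edges(
    P: np.ndarray, gene_names: list[str], include_self_loops: bool = False
) -> list[tuple[str, str, float]]:
    """(regulator, target, probability) sorted by descending probability."""
    pairs = ordered_pairs(gene_names, include_self_loops)
    index = {g: i for i, g in enumerate(gene_names)}
    rows = [(r, t, float(P[index[r], index[t]])) for r, t in pairs]
    return sorted(rows, key=lambda row: -row[2])
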