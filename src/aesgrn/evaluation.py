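"""Fidelity metrics between a simulated trace and a target dataset.

Reliability is the gene-averaged Pearson correlation (R_rho) or cosine
similarity (R_eta) between each gene's simulated and target trajectories;
error is the gene-averaged MSE / MAE.  The first ``m`` columns are the
shared initial conditions and are excluded from every metric, so all
comparisons run over (b - m) points.  The target trajectory is the
element-wise average over all experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset
from .environment import SimulationTrace
from .errors import DataError

__all__ = ["EvaluationReport", "pearson", "cosine", "mse", "mae", "evaluate_aes"]


def pearson(dx: np.ndarray, dy: np.ndarray) -> float:
    """Centered correlation in [-1, 1]; 0 with a warning if either is constant."""
    dx = np.asarray(dx, float).ravel()
    dy = np.asarray(dy, float).ravel()
    if dx.size != dy.size or dx.size < 2:
        raise DataError("pearson needs two equal-length vectors of size >= 2")
    cx = dx - dx.mean()
    cy = dy - dy.mean()
    denom = np.sqrt((cx * cx).sum() * (cy * cy).sum())
    if denom == 0.0:
        warnings.warn("zero variance in correlation input; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip((cx * cy).sum() / denom, -1.0, 1.0))


def cosine(dx: np.ndarray, dy: np.ndarray) -> float:
    """Cosine similarity; 0 with a warning if either vector has zero norm."""
    dx = np.asarray(dx, float).ravel()
    dy = np.asarray(dy, float).ravel()
    if dx.size != dy.size:
        raise DataError("cosine needs two equal-length vectors")
    denom = np.linalg.norm(dx) * np.linalg.norm(dy)
    if denom == 0.0:
        warnings.warn("zero-norm vector in cosine input; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(dx, dy) / denom, -1.0, 1.0))


def mse(dx: np.ndarray, dy: np.ndarray) -> float:
    dx, dy = np.asarray(dx, float).ravel(), np.asarray(dy, float).ravel()
    if dx.size != dy.size or dx.size < 1:
        raise DataError("mse needs two equal-length non-empty vectors")
    return float(np.mean((dx - dy) ** 2))


def mae(dx: np.ndarray, dy: np.ndarray) -> float:
    dx, dy = np.asarray(dx, float).ravel(), np.asarray(dy, float).ravel()
    if dx.size != dy.size or dx.size < 1:
        raise DataError("mae needs two equal-length non-empty vectors")
    return float(np.mean(np.abs(dx - dy)))


@dataclass
class EvaluationReport:
    """Per-gene and aggregate reliability/error of a simulated environment."""

    r_rho: float
    r_eta: float
    err_mse: float
    err_mae: float
    per_gene_rho: np.ndarray
    per_gene_eta: np.ndarray
    per_gene_mse: np.ndarray
    per_gene_mae: np.ndarray
    n_points: int

    def as_dict(self) -> dict:
        return {
            "R_rho": self.r_rho,
            "R_eta": self.r_eta,
            "R_rho_pct": 100.0 * self.r_rho,
            "R_eta_pct": 100.0 * self.r_eta,
            "Err_MSE": self.err_mse,
            "Err_MAE": self.err_mae,
            "n_points": self.n_points,
        }


def evaluate_aes(
    trace: SimulationTrace | np.ndarray,
    target: ExpressionDataset | np.ndarray,
    m: int,
) -> EvaluationReport:
    """Compare a simulation against the experiment-averaged target.

    ``trace`` is (n, T) over simulated time; ``target`` is a dataset (whose
    experiment average is used) or an (n, b) matrix.  Requires T == b; only
    columns m..b-1 enter the metrics.
    """
    dx = trace.values if isinstance(trace, SimulationTrace) else np.asarray(trace, float)
    if isinstance(target, ExpressionDataset):
        dy = target.mean_experiment().T
    else:
        dy = np.asarray(target, float)
    if dx.shape != dy.shape:
        raise DataError(f"trace shape {dx.shape} != target shape {dy.shape}")
    n, b = dx.shape
    if not 0 <= m < b:
        raise DataError(f"window m={m} incompatible with length b={b}")
    dxs, dys = dx[:, m:], dy[:, m:]
    rho = np.array([pearson(dxs[i], dys[i]) for i in range(n)])
    eta = np.array([cosine(dxs[i], dys[i]) for i in range(n)])
    mses = np.array([mse(dxs[i], dys[i]) for i in range(n)])
    maes = np.array([mae(dxs[i], dys[i]) for i in range(n)])
    return EvaluationReport(
        r_rho=float(rho.mean()),
        r_eta=float(eta.mean()),
        err_mse=float(mses.mean()),
        err_mae=float(maes.mean()),
        per_gene_rho=rho,
        per_gene_eta=eta,
        per_gene_mse=mses,
        per_gene_mae=maes,
        n_points=b - m,
    )
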