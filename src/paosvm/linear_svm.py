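"""Soft-margin linear support vector machine, solved in the dual.

The primal problem with slack variables xi_i and penalty C,

    min  1/2 ||w||^2 + C * sum_i xi_i
    s.t. y_i (w . x_i + b) >= 1 - xi_i,   xi_i >= 0,

is solved through its Lagrangian dual,

    max  sum_i lam_i - 1/2 sum_ij lam_i lam_j y_i y_j K(x_i, x_j)
    s.t. 0 <= lam_i <= C,   sum_i lam_i y_i = 0,

with the linear kernel K(a, b) = a . b. The solver is an SMO-style
maximal-violating-pair coordinate ascent: at each step the most
KKT-violating pair (i from the "up" set, j from the "down" set) is
updated analytically subject to the box and equality constraints, until
the duality gap proxy m - M falls below ``tol``. This keeps exact
support-vector bookkeeping and needs no external optimizer; an
independent quadratic-programming solution is used as a cross-check in
the test suite, never here.

External labels {0, 1} map to internal {-1, +1} as 0 -> -1, 1 -> +1.
A decision value of exactly 0 is assigned to class 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import TrainingSet

__all__ = [
    "SVMConfig",
    "SVMModel",
    "ConvergenceError",
    "linear_kernel",
    "fit",
    "decision_value",
    "decision_values",
    "predict_label",
    "save_model",
    "load_model",
]

_SV_EPS = 1e-9  # lambda below this is treated as zero when listing support vectors


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SVMConfig:
    """Penalty C, KKT tolerance and iteration cap of the dual solver."""

    C: float = 1.0
    tol: float = 1e-3
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


@dataclass
class SVMModel:
    """A fitted hyperplane w . x + b = 0 with its dual certificates.

    ``dual_coefs`` are the multipliers lam_i in [0, C] for every training
    point; ``support_indices`` those with lam_i > 0; ``slack`` the hinge
    residuals xi_i = max(0, 1 - y_i (w . x_i + b)).
    """

    weight_vector: np.ndarray
    bias: float
    dual_coefs: np.ndarray
    support_indices: np.ndarray
    slack: np.ndarray
    internal_labels: np.ndarray  # y_i in {-1, +1}
    support_vectors: np.ndarray
    config: SVMConfig
    dual_objective: float
    n_iter: int
    panel_ids: list[str] | None = None

    @property
    def support_dual(self) -> np.ndarray:
        return self.dual_coefs[self.support_indices]

    @property
    def support_labels(self) -> np.ndarray:
        return self.internal_labels[self.support_indices]


def linear_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """Inner product kernel K(a, b) = a . b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"kernel arguments differ in length: {a.shape} vs {b.shape}")
    return float(a @ b)


def fit(data: TrainingSet, config: SVMConfig | None = None) -> SVMModel:
    """Solve the dual by maximal-violating-pair SMO.

    Raises ``ValueError`` on single-class input and
    :class:`ConvergenceError` if the KKT violation has not dropped below
    ``tol`` within ``max_iter`` pair updates.
    """
    config = config or SVMConfig()
    X = np.asarray(data.X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y01 = np.asarray(data.y, dtype=int)
    if len(set(y01.tolist())) < 2:
        raise ValueError("training set contains a single class; need both 0 and 1")
    y = np.where(y01 == 1, 1.0, -1.0)
    n = len(y)
    C = config.C
    K = X @ X.T
    Q = (y[:, None] * y[None, :]) * K

    lam = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 lam Q lam - sum lam
    box_eps = 1e-12 * max(C, 1.0)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        gy = -y * grad  # equals y_i - w . x_i
        up = ((y > 0) & (lam < C - box_eps)) | ((y < 0) & (lam > box_eps))
        low = ((y < 0) & (lam < C - box_eps)) | ((y > 0) & (lam > box_eps))
        if not up.any() or not low.any():
            converged = True
            break
        i = int(np.flatnonzero(up)[np.argmax(gy[up])])
        j = int(np.flatnonzero(low)[np.argmin(gy[low])])
        m, M = gy[i], gy[j]
        if m - M <= config.tol:
            converged = True
            break
        # analytic two-variable update on the violating pair
        s = y[i] * y[j]
        if s < 0:
            L = max(0.0, lam[j] - lam[i])
            H = min(C, C + lam[j] - lam[i])
        else:
            L = max(0.0, lam[i] + lam[j] - C)
            H = min(C, lam[i] + lam[j])
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 0:
            eta = 1e-12
        lam_j_new = np.clip(lam[j] + y[j] * (M - m) / eta, L, H)
        d_j = lam_j_new - lam[j]
        if abs(d_j) < 1e-15:
            converged = True  # box-bound stall: no feasible descent direction left
            break
        d_i = s * -d_j
        grad += Q[:, i] * d_i + Q[:, j] * d_j
        lam[i] += d_i
        lam[j] = lam_j_new
    if not converged:
        gy = -y * grad
        up = ((y > 0) & (lam < C - box_eps)) | ((y < 0) & (lam > box_eps))
        low = ((y < 0) & (lam < C - box_eps)) | ((y > 0) & (lam > box_eps))
        violation = float(gy[up].max() - gy[low].min()) if up.any() and low.any() else 0.0
        raise ConvergenceError(
            f"SMO did not converge in {config.max_iter} iterations "
            f"(final KKT violation {violation:.3g} > tol {config.tol})"
        )

    w = X.T @ (lam * y)
    fx = X @ w
    free = (lam > _SV_EPS * max(C, 1.0)) & (lam < C - _SV_EPS * max(C, 1.0))
    if free.any():
        bias = float(np.mean(y[free] - fx[free]))
    else:
        gy = y - fx
        up = ((y > 0) & (lam < C - box_eps)) | ((y < 0) & (lam > box_eps))
        low = ((y < 0) & (lam < C - box_eps)) | ((y > 0) & (lam > box_eps))
        hi = gy[up].max() if up.any() else gy[low].min()
        lo = gy[low].min() if low.any() else gy[up].max()
        bias = float((hi + lo) / 2.0)  # margin midpoint when no multiplier is free
    slack = np.maximum(0.0, 1.0 - y * (fx + bias))
    support = np.flatnonzero(lam > _SV_EPS * max(C, 1.0))
    dual_obj = float(lam.sum() - 0.5 * lam @ (Q @ lam))
    return SVMModel(
        weight_vector=w,
        bias=bias,
        dual_coefs=lam,
        support_indices=support,
        slack=slack,
        internal_labels=y,
        support_vectors=X[support],
        config=config,
        dual_objective=dual_obj,
        n_iter=it,
        panel_ids=None,
    )


def decision_value(model: SVMModel, x: np.ndarray) -> float:
    """Dual-form decision value sum_i lam_i y_i K(x_i, x) + b.

    Equals the primal w . x + b for the linear kernel.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != model.weight_vector.shape:
        raise ValueError(
            f"input dimension {x.shape} does not match model dimension "
            f"{model.weight_vector.shape}"
        )
    coef = model.support_dual * model.support_labels
    return float(coef @ (model.support_vectors @ x) + model.bias)


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decision_value` over rows of X."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.weight_vector.shape[0]:
        raise ValueError("input dimension does not match model dimension")
    coef = model.support_dual * model.support_labels
    return (X @ model.support_vectors.T) @ coef + model.bias


def predict_label(model: SVMModel, x: np.ndarray) -> int:
    """1 if the decision value is >= 0, else 0."""
    return 1 if decision_value(model, x) >= 0 else 0


def save_model(model: SVMModel, path: str | Path) -> None:
    """Serialize a model to a self-describing JSON text file."""
    payload = {
        "format": "paosvm-linear-svm/1",
        "weight_vector": model.weight_vector.tolist(),
        "bias": model.bias,
        "dual_coefs": model.dual_coefs.tolist(),
        "support_indices": model.support_indices.tolist(),
        "slack": model.slack.tolist(),
        "internal_labels": model.internal_labels.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "C": model.config.C,
        "tol": model.config.tol,
        "max_iter": model.config.max_iter,
        "dual_objective": model.dual_objective,
        "n_iter": model.n_iter,
        "panel_ids": model.panel_ids,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SVMModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "paosvm-linear-svm/1":
        raise ValueError(f"{path}: not a paosvm linear SVM model file")
    return SVMModel(
        weight_vector=np.array(payload["weight_vector"], dtype=float),
        bias=float(payload["bias"]),
        dual_coefs=np.array(payload["dual_coefs"], dtype=float),
        support_indices=np.array(payload["support_indices"], dtype=int),
        slack=np.array(payload["slack"], dtype=float),
        internal_labels=np.array(payload["internal_labels"], dtype=float),
        support_vectors=np.array(payload["support_vectors"], dtype=float),
        config=SVMConfig(C=payload["C"], tol=payload["tol"], max_iter=payload["max_iter"]),
        dual_objective=float(payload["dual_objective"]),
        n_iter=int(payload["n_iter"]),
        panel_ids=payload.get("panel_ids"),
    )
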