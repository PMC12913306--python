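"""Differentiable building blocks of the constrained linear SEM.

A linear structural equation model over ``d`` variables is parameterised by a
weighted adjacency matrix ``W`` with zero diagonal, where entry ``W[i, j]`` is
the *direct* causal effect of variable ``i`` on variable ``j`` (so that data
generated by the model satisfies ``X ≈ X @ W + Z`` column-wise).  This module
collects the scalar/matrix functions the two-stage fit optimises:

* the penalised least-squares objective ``F(W) = ‖X − XW‖²_F / (2n) + λ‖W‖₁``
  and its (sub)gradient;
* the trace-exponential acyclicity measure ``h(W) = tr(exp(W∘W)) − d``, which
  is nonnegative and vanishes exactly on DAGs, and its gradient
  ``(exp(W∘W))ᵀ ∘ 2W``;
* the total-effect matrix ``T = (I − W)⁻¹ − I`` (direct plus all indirect
  effects along directed paths) and the interventional-constraint function
  ``g(W) = δ·(T_ij − δ)``, positive exactly when the total effect ``T_ij``
  has the sign of ``δ`` and exceeds it in magnitude, plus its Jacobian.

Everything is plain NumPy on square arrays; name handling lives in
:mod:`lincdic.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "InterventionalConstraint",
    "HyperParams",
    "ConstraintRecord",
    "FitResult",
    "total_effects",
    "total_effects_power",
    "acyclicity",
    "acyclicity_gradient",
    "objective",
    "objective_gradient",
    "constraint_value",
    "constraint_jacobian",
    "validate_constraints",
]


def as_weight_matrix(W, *, require_zero_diag: bool = True) -> np.ndarray:
    """Validate and return ``W`` as a float ``(d, d)`` array with ``d >= 2``."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if W.shape[0] < 2:
        raise ValueError("weight matrix needs at least 2 variables")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix contains non-finite entries")
    if require_zero_diag and np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have an exactly zero diagonal")
    return W


@dataclass(frozen=True)
class InterventionalConstraint:
    """Sign/magnitude requirement on a total causal effect.

    The constraint demands ``delta * (T[cause, target] - delta) > 0``: the
    total effect of ``cause`` on ``target`` must share the sign of ``delta``
    and exceed it in magnitude.  ``delta = +0.01`` therefore encodes
    "cause activates target" and ``delta = -0.01`` "cause inhibits target".
    """

    cause: int
    target: int
    delta: float

    def __post_init__(self) -> None:
        if self.cause == self.target:
            raise ValueError("constraint cause and target must differ")
        if self.delta == 0:
            raise ValueError("constraint delta must be nonzero")

    def with_delta(self, delta: float) -> "InterventionalConstraint":
        return InterventionalConstraint(self.cause, self.target, delta)


@dataclass
class HyperParams:
    """Tunable knobs of the two-stage fit.

    lambda1
        L1 penalty weight of the objective (default 0.1).
    omega
        Edge threshold; entries with ``|w| < omega`` are zeroed after
        optimisation (default 0.3).
    epsilon
        Sign-preserving escalation step applied to the ``delta`` of any
        constraint found violated after thresholding (default 0.25).
    tol, max_iter
        Solver tolerance and iteration cap handed to L-BFGS-B/SLSQP
        (defaults 1e-6 and 10,000).
    acyc_tol
        Acyclicity residual accepted as "is a DAG" (default 1e-8).
    max_rounds
        Cap on delta-escalation refit rounds (default 10).
    max_dual_iter, rho_max
        Augmented-Lagrangian schedule of Stage One: at most ``max_dual_iter``
        dual updates, penalty grows tenfold up to ``rho_max``.
    """

    lambda1: float = 0.1
    omega: float = 0.3
    epsilon: float = 0.25
    tol: float = 1e-6
    max_iter: int = 10_000
    acyc_tol: float = 1e-8
    max_rounds: int = 10
    max_dual_iter: int = 100
    rho_max: float = 1e16

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        for name in ("omega", "epsilon", "tol", "acyc_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("max_iter", "max_rounds", "max_dual_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ConstraintRecord:
    """Per-constraint outcome of a fit (values of ``δ(T_ij − δ)``)."""

    constraint: InterventionalConstraint
    value_pre_threshold: float
    value_post_threshold: float
    satisfied: bool
    delta_final: float


@dataclass
class FitResult:
    """Outcome of a two-stage fit.

    ``W_raw`` is the solver iterate before thresholding, ``W_est`` after
    zeroing entries with ``|w| < omega``.  ``constraints`` reports each
    requested constraint evaluated on the pre- and post-threshold total
    effects (the ``satisfied`` flag refers to the post-threshold matrix and
    the originally requested delta).
    """

    W_raw: np.ndarray
    W_est: np.ndarray
    constraints: list[ConstraintRecord] = field(default_factory=list)
    objective_value: float = np.nan
    acyclicity_value: float = np.nan
    stage_two_converged: bool = True
    escalation_rounds: int = 0
    wall_time_s: float = 0.0

    @property
    def deltas_final(self) -> list[float]:
        return [rec.delta_final for rec in self.constraints]

    @property
    def all_satisfied(self) -> bool:
        return all(rec.satisfied for rec in self.constraints)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (matrices as nested lists)."""
        return {
            "W_raw": self.W_raw.tolist(),
            "W_est": self.W_est.tolist(),
            "objective_value": float(self.objective_value),
            "acyclicity_value": float(self.acyclicity_value),
            "stage_two_converged": bool(self.stage_two_converged),
            "escalation_rounds": int(self.escalation_rounds),
            "wall_time_s": float(self.wall_time_s),
            "constraints": [
                {
                    "cause": rec.constraint.cause,
                    "target": rec.constraint.target,
                    "delta": rec.constraint.delta,
                    "delta_final": rec.delta_final,
                    "value_pre_threshold": rec.value_pre_threshold,
                    "value_post_threshold": rec.value_post_threshold,
                    "satisfied": rec.satisfied,
                }
                for rec in self.constraints
            ],
        }


# ---------------------------------------------------------------------------
# total effects


def total_effects_power(W, order: int | None = None) -> np.ndarray:
    """Truncated Neumann sum ``W + W² + … + W^order`` (default ``d − 1``).

    For an acyclic ``W`` this equals ``(I − W)⁻¹ − I`` exactly; it is also the
    fallback when ``I − W`` is numerically singular at a near-cyclic iterate.
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    if order is None:
        order = d - 1
    T = np.zeros_like(W)
    P = np.eye(d)
    for _ in range(order):
        P = P @ W
        T += P
    return T


def total_effects(W, *, fallback: bool = True) -> np.ndarray:
    """Total-effect matrix ``T = (I − W)⁻¹ − I``.

    Entry ``(i, j)`` sums the products of edge weights over every directed
    path from variable ``i`` to variable ``j``.  If ``I − W`` is singular
    (possible for cyclic intermediate iterates) and ``fallback`` is true, the
    truncated power sum is returned instead; with ``fallback=False`` a
    ``LinAlgError`` propagates.
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    eye = np.eye(d)
    try:
        M = np.linalg.solve(eye - W, eye)
    except np.linalg.LinAlgError:
        if not fallback:
            raise
        return total_effects_power(W)
    if not np.all(np.isfinite(M)):
        if not fallback:
            raise np.linalg.LinAlgError("singular I - W")
        return total_effects_power(W)
    return M - eye


# ---------------------------------------------------------------------------
# acyclicity


# Cap on exp(W∘W) entries: line searches can probe iterates whose matrix
# exponential overflows float64; capping keeps h and its gradient finite and
# enormous, so the solver backs off instead of receiving NaNs.
_EXPM_CAP = 1e12


def _safe_expm_hadamard(W: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        E = scipy.linalg.expm(W * W)
    if not np.all(np.isfinite(E)):
        E = np.nan_to_num(E, nan=_EXPM_CAP, posinf=_EXPM_CAP, neginf=-_EXPM_CAP)
    return np.clip(E, -_EXPM_CAP, _EXPM_CAP)


def acyclicity(W) -> float:
    """Trace-exponential acyclicity measure ``h(W) = tr(exp(W∘W)) − d``.

    Nonnegative for every real ``W``; zero exactly when the support of ``W``
    is a DAG (every directed cycle contributes a positive power trace of the
    elementwise square).
    """
    W = np.asarray(W, dtype=float)
    E = _safe_expm_hadamard(W)
    return float(np.trace(E) - W.shape[0])


def acyclicity_gradient(W) -> np.ndarray:
    """Gradient of :func:`acyclicity`: ``(exp(W∘W))ᵀ ∘ 2W``."""
    W = np.asarray(W, dtype=float)
    E = _safe_expm_hadamard(W)
    return E.T * (2.0 * W)


def _acyclicity_and_gradient(W) -> tuple[float, np.ndarray]:
    W = np.asarray(W, dtype=float)
    E = _safe_expm_hadamard(W)
    return float(np.trace(E) - W.shape[0]), E.T * (2.0 * W)


# ---------------------------------------------------------------------------
# objective


def objective(W, X, lambda1: float) -> float:
    """Penalised least squares ``‖X − XW‖²_F / (2n) + λ ‖W‖₁``."""
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} columns but W is {W.shape[0]}x{W.shape[1]}"
        )
    n = X.shape[0]
    R = X - X @ W
    return float(0.5 / n * np.sum(R * R) + lambda1 * np.sum(np.abs(W)))


def objective_gradient(W, X, lambda1: float) -> np.ndarray:
    """(Sub)gradient ``Xᵀ(XW − X)/n + λ·sign(W)`` with ``sign(0) = 0``."""
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} columns but W is {W.shape[0]}x{W.shape[1]}"
        )
    n = X.shape[0]
    return X.T @ (X @ W - X) / n + lambda1 * np.sign(W)


# ---------------------------------------------------------------------------
# interventional constraints


def constraint_value(c: InterventionalConstraint, T) -> float:
    """Constraint function ``g = δ·(T_ij − δ)``; ``g > 0`` iff satisfied."""
    T = np.asarray(T, dtype=float)
    return float(c.delta * (T[c.cause, c.target] - c.delta))


def constraint_jacobian(c: InterventionalConstraint, W) -> np.ndarray:
    """Jacobian of :func:`constraint_value` with respect to ``W``.

    With ``M = (I − W)⁻¹`` the differential of ``T = M − I`` is
    ``dT = M dW M``, hence ``∂T_ij/∂W_kl = M_ik M_lj`` and the constraint
    Jacobian is ``δ · outer(M[i, :], M[:, j])``.  Near-singular ``I − W``
    falls back to the derivative of the truncated power sum.
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    eye = np.eye(d)
    try:
        M = np.linalg.solve(eye - W, eye)
        if not np.all(np.isfinite(M)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return c.delta * _power_sum_sensitivity(W, c.cause, c.target)
    return c.delta * np.outer(M[c.cause, :], M[:, c.target])


def _power_sum_sensitivity(W, i: int, j: int) -> np.ndarray:
    """``∂(Σ_{k≤d−1} W^k)_ij / ∂W`` via cached matrix powers."""
    d = W.shape[0]
    powers = [np.eye(d)]
    for _ in range(d - 1):
        powers.append(powers[-1] @ W)
    J = np.zeros_like(W)
    for k in range(1, d):  # term W^k
        for a in range(k):
            J += np.outer(powers[a][i, :], powers[k - 1 - a][:, j])
    return J


def validate_constraints(
    constraints: Sequence[InterventionalConstraint], d: int
) -> list[InterventionalConstraint]:
    """Check index ranges and reject contradictory sign requirements.

    Two constraints on the same ordered pair with opposite delta signs are
    jointly infeasible by construction and raise ``ValueError``.
    """
    seen: dict[tuple[int, int], float] = {}
    out = []
    for c in constraints:
        if not (0 <= c.cause < d and 0 <= c.target < d):
            raise ValueError(
                f"constraint ({c.cause}, {c.target}) out of range for d={d}"
            )
        key = (c.cause, c.target)
        if key in seen and np.sign(seen[key]) != np.sign(c.delta):
            raise ValueError(
                f"contradictory sign constraints on pair {key}: "
                f"deltas {seen[key]} and {c.delta}"
            )
        seen[key] = c.delta
        out.append(c)
    return out
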