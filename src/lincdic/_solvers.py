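"""Numerical core of the two-stage constrained fit.

Stage One solves the acyclicity-penalised sparse regression (the continuous
DAG-learning warm start): the hard constraint ``h(W) = 0`` is enforced by an
augmented-Lagrangian dual ascent, each subproblem minimised by L-BFGS-B on the
standard ``W = W⁺ − W⁻`` split that turns the L1 penalty into a smooth bound-
constrained problem.  Stage Two refines the warm start with SLSQP under the
equality ``h(W) = 0`` and one inequality per interventional (or path)
constraint, using the analytic Jacobians from :mod:`lincdic.model` and
:mod:`lincdic.reachability`.

These functions are private plumbing; the public surface is the estimator
classes in :mod:`lincdic.estimators` and the thin wrappers in
:mod:`lincdic.optimize`.
"""

from __future__ import annotations

import time
from typing import Sequence

import numpy as np
import scipy.optimize as sopt

from .model import (
    ConstraintRecord,
    FitResult,
    HyperParams,
    InterventionalConstraint,
    _acyclicity_and_gradient,
    acyclicity,
    constraint_jacobian,
    constraint_value,
    objective,
    total_effects,
    validate_constraints,
)
from .reachability import PathConstraint, reachability, reachability_jacobian

__all__ = ["stage_one", "stage_two", "threshold", "fit_two_stage"]


def threshold(W, omega: float) -> np.ndarray:
    """Zero entries with ``|w| < omega`` (entries at the boundary are kept)."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    W = np.asarray(W, dtype=float)
    out = W.copy()
    out[np.abs(out) < omega] = 0.0
    return out


def _split_bounds(d: int) -> list[tuple[float, float]]:
    """Bounds for the (W⁺, W⁻) split: diagonal pinned at zero."""
    bounds = []
    for part in range(2):
        for i in range(d):
            for j in range(d):
                bounds.append((0.0, 0.0) if i == j else (0.0, None))
    return bounds


def stage_one(X, hp: HyperParams) -> np.ndarray:
    """Warm-start fit under the acyclicity constraint alone.

    Deterministic (initialised at ``W = 0``); returns the raw (unthresholded)
    weight matrix with ``h(W) <= hp.acyc_tol`` unless the penalty schedule is
    exhausted first, in which case the best iterate is returned.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    Xn = X  # precompute Gram pieces for the smooth part
    G = Xn.T @ Xn / n

    def func(w):
        W = (w[: d * d] - w[d * d :]).reshape(d, d)
        R = W - np.eye(d)
        # 0.5/n ||X - XW||^2 = 0.5 tr(R^T G R) * n/n  with G = X^T X / n
        loss = 0.5 * float(np.sum(R * (G @ R)))
        g_loss = G @ R
        h, g_h = _acyclicity_and_gradient(W)
        obj = loss + 0.5 * rho * h * h + alpha * h + hp.lambda1 * np.sum(w)
        g_smooth = (g_loss + (rho * h + alpha) * g_h).ravel()
        grad = np.concatenate([g_smooth + hp.lambda1, -g_smooth + hp.lambda1])
        return obj, grad

    w_est = np.zeros(2 * d * d)
    bounds = _split_bounds(d)
    rho, alpha, h_val = 1.0, 0.0, np.inf
    for _ in range(hp.max_dual_iter):
        while rho < hp.rho_max:
            # solver defaults (tight ftol) mirror the reference scheme of the
            # warm-start method; only the iteration cap is adjustable
            sol = sopt.minimize(
                func,
                w_est,
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"maxiter": hp.max_iter},
            )
            w_new = sol.x
            W_new = (w_new[: d * d] - w_new[d * d :]).reshape(d, d)
            h_new = acyclicity(W_new)
            if h_new > 0.25 * h_val:
                rho *= 10
            else:
                break
        w_est, h_val = w_new, h_new
        alpha += rho * h_val
        if h_val <= hp.acyc_tol or rho >= hp.rho_max:
            break
    return (w_est[: d * d] - w_est[d * d :]).reshape(d, d)


def _build_slsqp_constraints(
    d: int,
    hp: HyperParams,
    constraints: Sequence[InterventionalConstraint],
    path_constraints: Sequence[PathConstraint],
    reach_mode: str,
):
    cons = [
        {
            "type": "eq",
            "fun": lambda w: _acyclicity_and_gradient(w.reshape(d, d))[0],
            "jac": lambda w: _acyclicity_and_gradient(w.reshape(d, d))[1].ravel(),
        }
    ]
    for c in constraints:
        cons.append(
            {
                "type": "ineq",
                "fun": lambda w, c=c: constraint_value(
                    c, total_effects(w.reshape(d, d))
                ),
                "jac": lambda w, c=c: constraint_jacobian(c, w.reshape(d, d)).ravel(),
            }
        )
    for p in path_constraints:
        cons.append(
            {
                "type": "ineq",
                "fun": lambda w, p=p: float(
                    reachability(w.reshape(d, d), reach_mode)[p.cause, p.target]
                    - p.margin
                ),
                "jac": lambda w, p=p: reachability_jacobian(
                    w.reshape(d, d), p.cause, p.target, reach_mode
                ).ravel(),
            }
        )
    return cons


def stage_two(
    X,
    W_init,
    constraints: Sequence[InterventionalConstraint] = (),
    hp: HyperParams | None = None,
    *,
    path_constraints: Sequence[PathConstraint] = (),
    reach_mode: str = "surrogate",
) -> tuple[np.ndarray, bool]:
    """SLSQP refinement under acyclicity plus inequality constraints.

    Returns ``(W, converged)`` where ``converged`` requires solver success
    and ``h(W) <= acyc_tol``; on solver failure the last iterate is returned
    flagged.  Contradictory sign constraints on one pair are rejected.
    """
    hp = hp or HyperParams()
    X = np.asarray(X, dtype=float)
    W_init = np.asarray(W_init, dtype=float)
    n, d = X.shape
    validate_constraints(constraints, d)
    G = X.T @ X / n

    def func(w):
        W = w.reshape(d, d)
        R = W - np.eye(d)
        loss = 0.5 * float(np.sum(R * (G @ R)))
        return loss + hp.lambda1 * np.sum(np.abs(W))

    def jac(w):
        W = w.reshape(d, d)
        return (G @ (W - np.eye(d)) + hp.lambda1 * np.sign(W)).ravel()

    bounds = [
        (0.0, 0.0) if i == j else (None, None) for i in range(d) for j in range(d)
    ]
    cons = _build_slsqp_constraints(d, hp, constraints, path_constraints, reach_mode)

    def _feasible(W) -> bool:
        if acyclicity(W) > max(hp.acyc_tol, 10 * hp.tol):
            return False
        slack = -10 * hp.tol
        if constraints:
            T = total_effects(W)
            if any(constraint_value(c, T) < slack for c in constraints):
                return False
        if path_constraints:
            R = reachability(W, reach_mode)
            if any(R[p.cause, p.target] - p.margin < slack for p in path_constraints):
                return False
        return True

    sol = sopt.minimize(
        func,
        W_init.ravel(),
        method="SLSQP",
        jac=jac,
        bounds=bounds,
        constraints=cons,
        options={"maxiter": hp.max_iter, "ftol": hp.tol},
    )
    W = sol.x.reshape(d, d)
    converged = bool(sol.success) and acyclicity(W) <= max(hp.acyc_tol, 10 * hp.tol)
    # the objective must not increase relative to the best feasible iterate:
    # if the warm start already satisfies every constraint and the SLSQP
    # iterate is no better (or infeasible), keep the warm start.
    if _feasible(W_init):
        if not _feasible(W) or func(sol.x) > func(W_init.ravel()):
            return W_init.copy(), True
    return W, converged


def _post_threshold_violations(
    W_est,
    constraints: Sequence[InterventionalConstraint],
    path_constraints: Sequence[PathConstraint],
    reach_mode: str,
) -> tuple[list[int], list[int]]:
    """Indices of constraints violated on the thresholded matrix.

    Violation is judged against the *originally requested* delta/margin: the
    escalated working values are a solver device, not the requirement.
    """
    bad_ic: list[int] = []
    bad_pc: list[int] = []
    if constraints:
        T = total_effects(W_est)
        bad_ic = [
            k for k, c in enumerate(constraints) if constraint_value(c, T) < 0
        ]
    if path_constraints:
        R = reachability(W_est, reach_mode)
        bad_pc = [
            k
            for k, p in enumerate(path_constraints)
            if R[p.cause, p.target] <= 0.0
        ]
    return bad_ic, bad_pc


def fit_two_stage(
    X,
    constraints: Sequence[InterventionalConstraint] = (),
    hp: HyperParams | None = None,
    *,
    path_constraints: Sequence[PathConstraint] = (),
    reach_mode: str = "surrogate",
) -> FitResult:
    """Full pipeline: Stage One → Stage Two → threshold → delta escalation.

    With no constraints of either kind the result is exactly Stage One plus
    thresholding (the unconstrained continuous DAG-learning baseline); Stage
    Two is skipped so the reduction is bit-identical.  Otherwise each refit
    round escalates the working delta (margin) of every constraint still
    violated after thresholding by ``sign(δ)·ε`` (``+ε``) and re-runs SLSQP
    from the current raw iterate, up to ``hp.max_rounds`` rounds.
    """
    hp = hp or HyperParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError(f"data must be n x d with d >= 2, got shape {X.shape}")
    t0 = time.perf_counter()
    d = X.shape[1]
    constraints = validate_constraints(constraints, d)
    path_constraints = list(path_constraints)

    W_raw = stage_one(X, hp)
    converged = True
    rounds = 0
    work_ic = list(constraints)
    work_pc = list(path_constraints)

    if constraints or path_constraints:
        while True:
            W_raw, converged = stage_two(
                X,
                W_raw,
                work_ic,
                hp,
                path_constraints=work_pc,
                reach_mode=reach_mode,
            )
            W_est = threshold(W_raw, hp.omega)
            bad_ic, bad_pc = _post_threshold_violations(
                W_est, constraints, path_constraints, reach_mode
            )
            if (not bad_ic and not bad_pc) or rounds >= hp.max_rounds:
                break
            # escalate every constraint still violated on the thresholded
            # matrix: the typical case is a path severed by thresholding, and
            # the stronger delta also pressures the solver out of local
            # basins when an inequality resisted satisfaction outright
            for k in bad_ic:
                cw = work_ic[k]
                work_ic[k] = cw.with_delta(
                    cw.delta + np.sign(cw.delta) * hp.epsilon
                )
            for k in bad_pc:
                pw = work_pc[k]
                work_pc[k] = pw.with_margin(pw.margin + hp.epsilon)
            rounds += 1
    W_est = threshold(W_raw, hp.omega)

    records: list[ConstraintRecord] = []
    if constraints:
        T_raw = total_effects(W_raw)
        T_est = total_effects(W_est)
        for c, cw in zip(constraints, work_ic):
            post = constraint_value(c, T_est)
            records.append(
                ConstraintRecord(
                    constraint=c,
                    value_pre_threshold=constraint_value(c, T_raw),
                    value_post_threshold=post,
                    satisfied=bool(post >= 0),
                    delta_final=cw.delta,
                )
            )
    return FitResult(
        W_raw=W_raw,
        W_est=W_est,
        constraints=records,
        objective_value=objective(W_raw, X, hp.lambda1),
        acyclicity_value=acyclicity(W_raw),
        stage_two_converged=converged,
        escalation_rounds=rounds,
        wall_time_s=time.perf_counter() - t0,
    )
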