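"""Functional interface over the two-stage fit.

Thin wrappers around :mod:`lincdic._solvers` and the estimator classes for
callers that prefer functions over estimator objects: ``stage_one``,
``stage_two``, ``threshold``, ``fit_lincdic``, ``fit_lincdpath`` and the
feasibility check ``verify_solution``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._solvers import fit_two_stage, stage_one, stage_two, threshold
from .model import (
    FitResult,
    HyperParams,
    InterventionalConstraint,
    acyclicity,
    constraint_value,
    objective,
    total_effects,
)
from .reachability import PathConstraint

__all__ = [
    "stage_one",
    "stage_two",
    "threshold",
    "fit_lincdic",
    "fit_lincdpath",
    "verify_solution",
]


def fit_lincdic(
    X,
    constraints: Sequence[InterventionalConstraint] = (),
    hp: HyperParams | None = None,
) -> FitResult:
    """Two-stage fit under interventional constraints (see ``LinCDIC``)."""
    return fit_two_stage(X, constraints, hp)


def fit_lincdpath(
    X,
    path_constraints: Sequence[PathConstraint] = (),
    hp: HyperParams | None = None,
    *,
    reach_mode: str = "surrogate",
) -> FitResult:
    """Two-stage fit under path constraints (see ``LinCDPath``)."""
    return fit_two_stage(
        X, (), hp, path_constraints=path_constraints, reach_mode=reach_mode
    )


def verify_solution(
    W,
    constraints: Sequence[InterventionalConstraint] = (),
    hp: HyperParams | None = None,
    X=None,
) -> dict:
    """Feasibility report for a candidate solution.

    Checks the two conditions a converged fit must satisfy — acyclicity
    ``h(W) = 0`` (within ``acyc_tol``) and every interventional margin
    ``δ(T_ij − δ) >= 0`` — and reports the residuals; the objective value is
    included when data is supplied.
    """
    hp = hp or HyperParams()
    W = np.asarray(W, dtype=float)
    h = acyclicity(W)
    T = total_effects(W)
    cons = []
    for c in constraints:
        margin = constraint_value(c, T)
        cons.append(
            {
                "cause": c.cause,
                "target": c.target,
                "delta": c.delta,
                "margin": margin,
                "satisfied": bool(margin >= 0),
            }
        )
    report = {
        "acyclicity_residual": h,
        "acyclic": bool(h <= hp.acyc_tol),
        "constraints": cons,
        "all_satisfied": bool(h <= hp.acyc_tol and all(c["satisfied"] for c in cons)),
    }
    if X is not None:
        report["objective_value"] = objective(W, X, hp.lambda1)
    return report
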