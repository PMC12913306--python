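"""Scikit-learn style estimators for constrained linear causal discovery.

Three estimators share the two-stage machinery:

``NotearsLinear``
    the unconstrained baseline — continuous DAG learning by acyclicity-
    penalised sparse least squares, then hard thresholding;
``LinCDIC``
    adds interventional constraints ``δ(T_ij − δ) > 0`` on total causal
    effects (sign and minimum magnitude), refined by SLSQP with delta
    escalation when thresholding breaks a constraint;
``LinCDPath``
    the path-constraint baseline: the same machinery with the total-effect
    predicate replaced by reachability ``R_ij > 0`` (sign-agnostic).

All follow the usual contract: hyperparameters in ``__init__``, data in
``fit(X)``, fitted attributes with trailing underscores (``W_``, ``W_raw_``,
``total_effects_``, ``fit_result_``), so they compose with sklearn model
selection and pipelines (as transformers they are not useful; the product is
the weighted DAG itself).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._solvers import fit_two_stage
from .model import HyperParams, InterventionalConstraint, total_effects
from .reachability import PathConstraint, reachability

__all__ = ["NotearsLinear", "LinCDIC", "LinCDPath"]


def _coerce_interventional(constraints) -> list[InterventionalConstraint]:
    out = []
    for c in constraints or ():
        if isinstance(c, InterventionalConstraint):
            out.append(c)
        else:
            i, j, delta = c
            out.append(InterventionalConstraint(int(i), int(j), float(delta)))
    return out


def _coerce_path(constraints, default_margin: float) -> list[PathConstraint]:
    out = []
    for c in constraints or ():
        if isinstance(c, PathConstraint):
            out.append(c)
        elif len(c) == 3:
            i, j, r = c
            out.append(PathConstraint(int(i), int(j), float(r)))
        else:
            i, j = c
            out.append(PathConstraint(int(i), int(j), default_margin))
    return out


class _TwoStageDAG(BaseEstimator):
    """Shared fit plumbing; subclasses define which constraints they carry."""

    def _hyperparams(self) -> HyperParams:
        return HyperParams(
            lambda1=self.lambda1,
            omega=self.omega,
            epsilon=getattr(self, "epsilon", 0.25),
            tol=self.tol,
            max_iter=self.max_iter,
            acyc_tol=self.acyc_tol,
            max_rounds=getattr(self, "max_rounds", 10),
        )

    def _fit_constraints(self):
        return [], [], "surrogate"

    def fit(self, X, y=None):
        """Estimate the weighted DAG from an ``(n, d)`` data matrix."""
        X = check_array(X, ensure_min_features=2, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        ic, pc, mode = self._fit_constraints()
        result = fit_two_stage(
            X,
            ic,
            self._hyperparams(),
            path_constraints=pc,
            reach_mode=mode,
        )
        self.fit_result_ = result
        self.W_raw_ = result.W_raw
        self.W_ = result.W_est
        self.total_effects_ = total_effects(result.W_est)
        self.n_iter_ = result.escalation_rounds
        return self

    def predict(self, X):
        """Reconstruct each variable from the others: ``X @ W_``."""
        check_is_fitted(self, "W_")
        X = check_array(X)
        return X @ self.W_

    def score(self, X, y=None):
        """Negative mean squared reconstruction residual (higher is better)."""
        check_is_fitted(self, "W_")
        X = check_array(X)
        R = X - X @ self.W_
        return -float(np.mean(R * R))


class NotearsLinear(_TwoStageDAG):
    """Unconstrained continuous DAG learning (warm-start stage + threshold).

    Parameters
    ----------
    lambda1 : float, default 0.1
        L1 penalty weight.
    omega : float, default 0.3
        Edge threshold applied to the raw estimate.
    tol, max_iter, acyc_tol : solver settings (see ``HyperParams``).
    """

    def __init__(self, lambda1=0.1, omega=0.3, tol=1e-6, max_iter=10_000,
                 acyc_tol=1e-8):
        self.lambda1 = lambda1
        self.omega = omega
        self.tol = tol
        self.max_iter = max_iter
        self.acyc_tol = acyc_tol


class LinCDIC(_TwoStageDAG):
    """Two-stage causal discovery under interventional constraints.

    Parameters
    ----------
    constraints : sequence of ``InterventionalConstraint`` or ``(i, j, delta)``
        Each encodes ``delta * (T_ij - delta) > 0``: the total effect of
        variable ``i`` on variable ``j`` must share the sign of ``delta`` and
        exceed it in magnitude.  ``delta=+0.01`` is the conventional "i
        activates j" prior.
    epsilon : float, default 0.25
        Escalation step added to ``|delta|`` of any constraint violated after
        thresholding before refitting.
    max_rounds : int, default 10
        Cap on escalation-refit rounds.
    Other parameters as in :class:`NotearsLinear`.
    """

    def __init__(self, constraints=None, lambda1=0.1, omega=0.3, epsilon=0.25,
                 max_rounds=10, tol=1e-6, max_iter=10_000, acyc_tol=1e-8):
        self.constraints = constraints
        self.lambda1 = lambda1
        self.omega = omega
        self.epsilon = epsilon
        self.max_rounds = max_rounds
        self.tol = tol
        self.max_iter = max_iter
        self.acyc_tol = acyc_tol

    def _fit_constraints(self):
        return _coerce_interventional(self.constraints), [], "surrogate"


class LinCDPath(_TwoStageDAG):
    """Two-stage causal discovery under path (reachability) constraints.

    Parameters
    ----------
    path_constraints : sequence of ``PathConstraint``, ``(i, j)`` or
        ``(i, j, margin)`` — each demands a directed path ``i → … → j`` in
        the learned graph via ``R_ij >= margin``.
    margin : float, default 0.01
        Default margin for pairs given without one.
    reach_mode : {"surrogate", "signed"}, default "surrogate"
        ``surrogate`` evaluates reachability on ``tanh(|W|)`` so path
        contributions cannot cancel; ``signed`` uses ``tanh(W)`` verbatim.
    Other parameters as in :class:`LinCDIC`.
    """

    def __init__(self, path_constraints=None, margin=0.01,
                 reach_mode="surrogate", lambda1=0.1, omega=0.3, epsilon=0.25,
                 max_rounds=10, tol=1e-6, max_iter=10_000, acyc_tol=1e-8):
        self.path_constraints = path_constraints
        self.margin = margin
        self.reach_mode = reach_mode
        self.lambda1 = lambda1
        self.omega = omega
        self.epsilon = epsilon
        self.max_rounds = max_rounds
        self.tol = tol
        self.max_iter = max_iter
        self.acyc_tol = acyc_tol

    def _fit_constraints(self):
        return [], _coerce_path(self.path_constraints, self.margin), self.reach_mode

    def fit(self, X, y=None):
        super().fit(X, y)
        self.reachability_ = reachability(self.W_, self.reach_mode)
        return self
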