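"""Reachability matrix and path constraints (the sign-agnostic baseline).

A path constraint only demands that *some* directed path lead from a cause to
a target; it says nothing about the sign or size of the effect.  Reachability
is made differentiable through the matrix

    R = (I + A / d)^d,      A = tanh(|W|)   (surrogate, default)
                            A = tanh(W)     (signed mode)

Expanding the power shows ``R_ij`` sums, over all directed walks from ``i``
to ``j`` of length up to ``d``, products of the (squashed) edge weights.  In
the surrogate mode every factor is nonnegative, so for an acyclic ``W`` the
off-diagonal entry ``R_ij`` is strictly positive exactly when a directed path
``i → … → j`` with nonzero weights exists.  The signed mode keeps the raw
formula; with negative weights, walk contributions can cancel, which is why
the surrogate is the default for expressing "a path exists".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PathConstraint", "reachability", "reachability_jacobian"]


@dataclass(frozen=True)
class PathConstraint:
    """Requirement ``R[cause, target] >= margin`` (a directed path exists)."""

    cause: int
    target: int
    margin: float = 0.01

    def __post_init__(self) -> None:
        if self.cause == self.target:
            raise ValueError("path constraint cause and target must differ")
        if self.margin <= 0:
            raise ValueError("path constraint margin must be > 0")

    def with_margin(self, margin: float) -> "PathConstraint":
        return PathConstraint(self.cause, self.target, margin)


def _squashed(W, mode: str) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if mode == "surrogate":
        return np.tanh(np.abs(W))
    if mode == "signed":
        return np.tanh(W)
    raise ValueError(f"unknown reachability mode {mode!r}")


def reachability(W, mode: str = "surrogate") -> np.ndarray:
    """Reachability matrix ``R = (I + tanh(·)/d)^d``.

    ``mode="surrogate"`` (default) squashes ``|W|`` so entries are
    nonnegative and ``R_ij > 0`` for ``i ≠ j`` iff ``j`` is reachable from
    ``i`` in the support digraph of an acyclic ``W``; ``mode="signed"``
    evaluates the formula on ``tanh(W)`` as printed, where contributions of
    different paths may cancel.
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    B = np.eye(d) + _squashed(W, mode) / d
    return np.linalg.matrix_power(B, d)


def reachability_jacobian(W, cause: int, target: int, mode: str = "surrogate") -> np.ndarray:
    """``∂R[cause, target] / ∂W`` for SQP consumption.

    With ``B = I + A/d`` and ``R = B^d``, the product rule gives
    ``∂R_ij/∂B_kl = Σ_{m=0}^{d−1} (B^m)_ik (B^{d−1−m})_lj`` which is chained
    with ``∂A_kl/∂W_kl`` (``sech²`` of the squashed argument, times
    ``sign(W_kl)`` in surrogate mode, with the subgradient 0 at exactly-zero
    entries).
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    A = _squashed(W, mode)
    B = np.eye(d) + A / d
    powers = [np.eye(d)]
    for _ in range(d - 1):
        powers.append(powers[-1] @ B)
    # dR/dB for the (cause, target) entry
    dRdB = np.zeros_like(W)
    for m in range(d):
        dRdB += np.outer(powers[m][cause, :], powers[d - 1 - m][:, target])
    if mode == "surrogate":
        inner = (1.0 - A * A) * np.sign(W)
    else:
        inner = 1.0 - A * A
    return dRdB * inner / d
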