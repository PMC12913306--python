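"""Real-data harness for the flow-cytometry signaling benchmark.

Runs the three methods on a user-supplied 853 × 11 observational matrix,
reports the total causal effects of the eight curated protein interactions,
and scores the learned graphs against the packaged 20-edge consensus
network.  The cross-validation harness enumerates every 3-of-8 subset of the
curated constraints (56 combinations) as training sets.

The data file itself is not redistributed; see ``expected_sachs_layout``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import LinCDIC, LinCDPath, NotearsLinear
from .io import (
    load_sachs_dataset,
    read_constraints,
    sachs_benchmark_graph,
    sachs_constraints_path,
    training_subsets,
    SACHS_VARIABLES,
)
from .metrics import evaluate
from .model import total_effects

__all__ = ["SachsRun", "load_curated_constraints", "run_sachs", "crossval_subsets"]

#: the three constraints the headline real-data experiment trains on
DEFAULT_TRAINING = (("PKC", "Jnk"), ("PKC", "P38"), ("PIP3", "Akt"))


@dataclass
class SachsRun:
    mode: str
    W_est: np.ndarray
    effects: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def load_curated_constraints():
    """The eight literature-curated interventional constraints, by index."""
    ic, _ = read_constraints(sachs_constraints_path(), SACHS_VARIABLES)
    return ic


def crossval_subsets(k: int = 3):
    """All C(8, k) training subsets of the curated constraints."""
    return training_subsets(load_curated_constraints(), k)


def _named_pairs(constraints):
    return [
        (SACHS_VARIABLES[c.cause], SACHS_VARIABLES[c.target]) for c in constraints
    ]


def run_sachs(
    data_path,
    mode: str = "lincdic",
    training=DEFAULT_TRAINING,
    epsilon: float = 0.25,
    lambda1: float = 0.1,
) -> SachsRun:
    """Fit one method on the observational data and score it.

    ``training`` selects which curated interactions are enforced (by name
    pairs); the remaining interactions are held out and only reported via
    their total effects.
    """
    ds = load_sachs_dataset(data_path)
    curated = load_curated_constraints()
    train = [
        c for c in curated if (_named_pairs([c])[0] in tuple(map(tuple, training)))
    ]
    if mode == "notears":
        est = NotearsLinear(lambda1=lambda1)
    elif mode == "lincdic":
        est = LinCDIC(constraints=train, epsilon=epsilon, lambda1=lambda1)
    elif mode == "lincdpath":
        est = LinCDPath(
            path_constraints=[(c.cause, c.target) for c in train],
            epsilon=epsilon,
            lambda1=lambda1,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    est.fit(ds.X)
    T = total_effects(est.W_)
    effects = {
        f"T({SACHS_VARIABLES[c.cause]},{SACHS_VARIABLES[c.target]})": float(
            T[c.cause, c.target]
        )
        for c in curated
    }
    A, _ = sachs_benchmark_graph()
    report = evaluate(est.W_, A)
    return SachsRun(
        mode=mode, W_est=est.W_, effects=effects, metrics=report.to_dict()
    )
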