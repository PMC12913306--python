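"""Ground-truth models, observational data, and sampled constraints.

The generator emulates the synthetic study design the package is evaluated
on: sparse scale-free DAGs whose edge count is drawn uniformly from
``[8, min(d(d−1)/2, 10)]``, edge weights uniform on ``±[0.5, 2.0]`` (no
near-zero edges), independent Gaussian noise with *unequal* standard
deviations uniform on ``[0.5, 2.0]``, ancestral sampling of observations,
and constraint sampling restricted to variable pairs whose true total effect
exceeds 0.1 in magnitude (weak effects are treated as potentially spurious
and never asserted as prior knowledge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InterventionalConstraint, total_effects

__all__ = ["GroundTruth", "generate_dag", "simulate", "sample_constraints"]

#: default |delta| assigned to sampled constraints
DEFAULT_DELTA = 0.01
#: minimum |total effect| for a pair to be eligible as prior knowledge
EFFECT_ELIGIBILITY = 0.1

_WEIGHT_RANGE = (0.5, 2.0)
_NOISE_RANGE = (0.5, 2.0)
_EDGE_RANGE = (8, 10)


@dataclass
class GroundTruth:
    """A true weighted DAG plus its noise scales."""

    W_true: np.ndarray
    noise_scales: np.ndarray
    graph_type: str = "scale_free"
    variable_names: list[str] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W_true))


def _edge_bounds(d: int) -> tuple[int, int]:
    lo = _EDGE_RANGE[0]
    hi = min(d * (d - 1) // 2, _EDGE_RANGE[1])
    if hi < lo:
        raise ValueError(
            f"d={d} supports at most {d * (d - 1) // 2} edges, "
            f"fewer than the required minimum of {lo}"
        )
    return lo, hi


def generate_dag(d: int, seed: int) -> GroundTruth:
    """Draw a random scale-free ground-truth model.

    The undirected skeleton is grown one edge at a time with preferential
    (degree-proportional) endpoint selection, which concentrates connections
    on hubs; a uniformly random topological order then orients every edge
    forward, so the result is acyclic by construction with exactly the drawn
    edge count.  Weights avoid the ``(−0.5, 0.5)`` band so no true edge sits
    near the detection threshold; noise scales differ per variable.
    """
    if d < 4:
        raise ValueError("need d >= 4 variables")
    lo, hi = _edge_bounds(d)
    rng = np.random.default_rng(seed)
    n_edges = int(rng.integers(lo, hi + 1))

    degree = np.ones(d)
    edges: set[tuple[int, int]] = set()
    while len(edges) < n_edges:
        p = degree / degree.sum()
        a, b = rng.choice(d, size=2, replace=False, p=p)
        key = (min(a, b), max(a, b))
        if key in edges:
            continue
        edges.add(key)
        degree[a] += 1
        degree[b] += 1

    order = rng.permutation(d)
    rank = np.empty(d, dtype=int)
    rank[order] = np.arange(d)
    W = np.zeros((d, d))
    for a, b in sorted(edges):
        i, j = (a, b) if rank[a] < rank[b] else (b, a)
        w = rng.uniform(*_WEIGHT_RANGE) * rng.choice([-1.0, 1.0])
        W[i, j] = w
    noise = rng.uniform(*_NOISE_RANGE, size=d)
    return GroundTruth(W_true=W, noise_scales=noise)


def simulate(gt: GroundTruth, n: int, seed: int) -> np.ndarray:
    """Ancestral sampling of ``n`` observations from the linear SEM.

    Variables are visited in a topological order of ``W_true``; each column
    is the weighted sum of its parents plus an independent Gaussian draw with
    the variable's own noise scale.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    W = gt.W_true
    d = gt.d
    # topological order by repeatedly removing in-degree-zero nodes
    remaining = set(range(d))
    in_deg = {j: int(np.count_nonzero(W[:, j])) for j in range(d)}
    topo: list[int] = []
    ready = [j for j in range(d) if in_deg[j] == 0]
    while ready:
        j = ready.pop()
        topo.append(j)
        remaining.discard(j)
        for k in np.flatnonzero(W[j, :]):
            in_deg[int(k)] -= 1
            if in_deg[int(k)] == 0:
                ready.append(int(k))
    if remaining:
        raise ValueError("ground-truth weight matrix is not acyclic")
    X = np.zeros((n, d))
    Z = rng.normal(size=(n, d)) * gt.noise_scales
    for j in topo:
        X[:, j] = X @ W[:, j] + Z[:, j]
    return X


def sample_constraints(
    gt: GroundTruth, m: int, seed: int
) -> list[InterventionalConstraint]:
    """Draw ``m`` interventional constraints consistent with the truth.

    Eligible pairs are the ordered ``(i, j)`` with ``|T_true[i, j]| > 0.1``;
    ``m`` of them are drawn uniformly without replacement and each receives
    ``delta = sign(T_true[i, j]) * 0.01``, so every sampled constraint holds
    in the generating model with margin.
    """
    rng = np.random.default_rng(seed)
    T = total_effects(gt.W_true)
    pairs = [
        (i, j)
        for i in range(gt.d)
        for j in range(gt.d)
        if i != j and abs(T[i, j]) > EFFECT_ELIGIBILITY
    ]
    if m > len(pairs):
        raise ValueError(
            f"requested {m} constraints but only {len(pairs)} eligible pairs "
            f"(|total effect| > {EFFECT_ELIGIBILITY})"
        )
    chosen = rng.choice(len(pairs), size=m, replace=False)
    return [
        InterventionalConstraint(
            pairs[k][0], pairs[k][1], float(np.sign(T[pairs[k]]) * DEFAULT_DELTA)
        )
        for k in sorted(chosen)
    ]
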