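"""Evaluation of an estimated weighted DAG against a reference.

Structure metrics follow the conventions of the continuous DAG-learning
literature so numbers are comparable across papers:

* a predicted directed edge is a true positive only if the *same* directed
  edge exists in the reference; a reversed edge counts as a false discovery
  and a missed true edge;
* the FPR denominator is the number of absent edges in the true skeleton,
  ``d(d−1)/2 − (#true edges)``;
* SHD charges one edit for an addition, a deletion, or a reversal;
* SID counts ordered pairs ``(i, j)`` whose single-intervention distribution
  would be mis-estimated by adjusting for the estimated graph's parents of
  ``i`` in the true graph (parent-adjustment validity via the generalized
  adjustment criterion);
* SCS counts all ``d²`` positions where the two matrices agree in sign
  (``{−1, 0, +1}``), diagonal and zero–zero agreements included.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "shd",
    "sid",
    "scs",
    "evaluate",
]


@dataclass
class EvaluationReport:
    fdr: float
    tpr: float
    fpr: float
    shd: int
    sid: int
    nnz: int
    scs: int

    def to_dict(self) -> dict:
        return asdict(self)


def _edge_set(W) -> set[tuple[int, int]]:
    W = np.asarray(W)
    return {
        (int(i), int(j))
        for i, j in zip(*np.nonzero(W))
        if i != j
    }


def confusion_metrics(W_est, W_true) -> tuple[float, float, float]:
    """(FDR, TPR, FPR) of the directed edge sets.

    Degenerate conventions: FDR is 0 when no edge is predicted and TPR is 0
    when the reference has no edges.
    """
    W_est = np.asarray(W_est)
    W_true = np.asarray(W_true)
    if W_est.shape != W_true.shape:
        raise ValueError("shape mismatch between estimate and reference")
    d = W_est.shape[0]
    pred = _edge_set(W_est)
    cond = _edge_set(W_true)
    tp = len(pred & cond)
    n_pred = len(pred)
    n_cond = len(cond)
    fdr = 0.0 if n_pred == 0 else (n_pred - tp) / n_pred
    tpr = 0.0 if n_cond == 0 else tp / n_cond
    denom = d * (d - 1) // 2 - n_cond
    fpr = 0.0 if denom <= 0 else (n_pred - tp) / denom
    return fdr, tpr, fpr


def shd(W_est, W_true) -> int:
    """Structural Hamming distance with reversals costing one edit.

    Per unordered pair the cost is the smallest number of additions,
    deletions, or reversals turning the estimated pattern into the true one.
    """
    W_est = np.asarray(W_est)
    W_true = np.asarray(W_true)
    if W_est.shape != W_true.shape:
        raise ValueError("shape mismatch between estimate and reference")
    pred = _edge_set(W_est)
    cond = _edge_set(W_true)
    d = W_est.shape[0]
    total = 0
    for i in range(d):
        for j in range(i + 1, d):
            a = {e for e in ((i, j), (j, i)) if e in pred}
            b = {e for e in ((i, j), (j, i)) if e in cond}
            total += max(len(a - b), len(b - a))
    return total


def scs(W_est, W_true) -> int:
    """Sign consistency sum: positions (of all ``d²``) with equal sign."""
    W_est = np.asarray(W_est)
    W_true = np.asarray(W_true)
    if W_est.shape != W_true.shape:
        raise ValueError("shape mismatch between estimate and reference")
    return int(np.sum(np.sign(W_est) == np.sign(W_true)))


# ---------------------------------------------------------------------------
# structural intervention distance


def _digraph(W) -> nx.DiGraph:
    W = np.asarray(W)
    G = nx.DiGraph()
    G.add_nodes_from(range(W.shape[0]))
    G.add_edges_from(_edge_set(W))
    return G


def sid(W_est, W_true) -> int:
    """Structural intervention distance of the estimate from the truth.

    For each ordered pair ``(i, j)`` the estimated graph proposes the
    adjustment set ``Z = Pa_est(i)`` for the effect of ``i`` on ``j``.  The
    pair counts as a mistake when that proposal fails in the true graph:

    * if ``j ∈ Z`` the estimate claims no effect, wrong iff ``j`` is in fact
      a descendant of ``i``;
    * otherwise ``Z`` must be a valid adjustment set: it may contain no node
      on (or downstream of) a directed ``i → … → j`` path, and it must
      d-separate ``i`` from ``j`` in the proper back-door graph (the true
      graph with the first edge of every such directed path removed).

    Both inputs must be DAGs.
    """
    G = _digraph(W_true)
    H = _digraph(W_est)
    if not nx.is_directed_acyclic_graph(G) or not nx.is_directed_acyclic_graph(H):
        raise ValueError("SID is defined for acyclic graphs only")
    d = G.number_of_nodes()
    desc = {v: nx.descendants(G, v) for v in G.nodes}
    mistakes = 0
    for i in range(d):
        Z = set(H.predecessors(i))
        for j in range(d):
            if i == j:
                continue
            if j in Z:
                if j in desc[i]:
                    mistakes += 1
                continue
            # nodes (other than i) on a directed path i -> ... -> j
            cn = {k for k in desc[i] if k == j or j in desc[k]}
            forbidden = set(cn)
            for k in cn:
                forbidden |= desc[k]
            if Z & forbidden:
                mistakes += 1
                continue
            Gpbd = G.copy()
            Gpbd.remove_edges_from([(i, k) for k in cn if G.has_edge(i, k)])
            if not nx.is_d_separator(Gpbd, {i}, {j}, Z):
                mistakes += 1
    return mistakes


def evaluate(W_est, W_true) -> EvaluationReport:
    """Full report: FDR, TPR, FPR, SHD, SID, NNZ, SCS."""
    fdr, tpr, fpr = confusion_metrics(W_est, W_true)
    return EvaluationReport(
        fdr=fdr,
        tpr=tpr,
        fpr=fpr,
        shd=shd(W_est, W_true),
        sid=sid(W_est, W_true),
        nnz=int(np.count_nonzero(np.asarray(W_est))),
        scs=scs(W_est, W_true),
    )
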