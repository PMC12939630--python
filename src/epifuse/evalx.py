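"""Reconstruction evaluation (TPR / FPR) and the co-infection baseline.

Evaluation is over unordered off-diagonal node pairs: each of the
N (N - 1) / 2 pairs is a true or false positive/negative depending on
whether the pair is an edge in the ground truth and in the prediction.

TPR = TP / (TP + FN) is the fraction of true edges recovered;
FPR = FP / (TN + FP) is the fraction of non-edges falsely predicted.
When a denominator is zero (edgeless or complete truth) the ratio is
reported as None with a warning rather than coerced to 0.

The baseline ("co-infection counting", NRA) predicts an edge whenever two
nodes are simultaneously infectious at least tau times across all
recorded time steps.  It cannot distinguish direct transmission from
independent co-infection, which is exactly the failure mode the belief
fusion pipeline is designed to avoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .graphio import Graph
from .sir import TimeStateMatrix

__all__ = ["ConfusionReport", "confusion", "nra_baseline", "coinfection_counts"]


@dataclass(frozen=True)
class ConfusionReport:
    """Pair-level confusion counts and rates for one reconstruction."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float | None
    fpr: float | None
    n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(true_g: Graph, predicted: np.ndarray | Graph) -> ConfusionReport:
    """Compare a predicted adjacency against the ground-truth graph.

    ``predicted`` is either a Graph on the same node set or a symmetric
    zero-diagonal 0/1 matrix in ``true_g``'s node order.
    """
    if isinstance(predicted, Graph):
        if set(predicted.nodes) != set(true_g.nodes):
            raise ValueError("predicted graph has a different node set than the truth")
        order = [predicted.index_of(n) for n in true_g.nodes]
        pred = predicted.adjacency_matrix()[np.ix_(order, order)]
    else:
        pred = np.asarray(predicted)
        if pred.shape != (true_g.n_nodes, true_g.n_nodes):
            raise ValueError(
                f"predicted adjacency shape {pred.shape} does not match "
                f"{true_g.n_nodes} nodes"
            )
        if not np.array_equal(pred, pred.T) or np.diag(pred).any():
            raise ValueError("predicted adjacency must be symmetric with zero diagonal")
    truth = true_g.adjacency_matrix()
    iu = np.triu_indices(true_g.n_nodes, k=1)
    t, p = truth[iu].astype(bool), pred[iu].astype(bool)
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))

    tpr: float | None
    fpr: float | None
    if tp + fn > 0:
        tpr = tp / (tp + fn)
    else:
        warnings.warn("truth has no edges: TPR undefined", UserWarning, stacklevel=2)
        tpr = None
    if tn + fp > 0:
        fpr = fp / (tn + fp)
    else:
        warnings.warn("truth is complete: FPR undefined", UserWarning, stacklevel=2)
        fpr = None
    return ConfusionReport(tp, fp, tn, fn, tpr, fpr, n_pairs=len(t))


def coinfection_counts(batches: Sequence[TimeStateMatrix]) -> np.ndarray:
    """n(i, j): number of time steps (over all runs) with i and j co-infectious."""
    if not batches:
        raise ValueError("empty batch list")
    nodes = batches[0].nodes
    n = len(nodes)
    counts = np.zeros((n, n), dtype=np.int64)
    for ts in batches:
        if ts.nodes != nodes:
            raise ValueError("inconsistent node order across batches")
        x = ts.values.astype(np.int64)
        counts += x.T @ x
    np.fill_diagonal(counts, 0)
    return counts


def nra_baseline(batches: Sequence[TimeStateMatrix], tau: int = 1) -> np.ndarray:
    """Co-infection-counting edge prediction: edge iff n(i, j) >= tau.

    The count matrix is symmetric by construction, so the predicted
    adjacency is too.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    counts = coinfection_counts(batches)
    return (counts >= tau).astype(np.int64)
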