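"""Precision-recall evaluation, MCMC convergence distortion, run stability.

Precision is TP / (TP + FP) and recall is TP / (total true positives),
swept over a descending threshold schedule on the prediction scores (for
sampled-network tallies the threshold starts at the maximum count and
decrements by 1 down to the minimum).  The area under the curve is the
trapezoid over recall.  Distortion between two sampling intervals is the
mean absolute difference of edge frequencies over the universe of all
possible edges; stability summarizes how many of five independent runs
agree on each consensus edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrCurve",
    "pr_curve",
    "recall_at_precision",
    "distortion",
    "stability",
]


@dataclass
class PrCurve:
    """Ordered (threshold, tp, fp, precision, recall) points plus AUC."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def pr_curve(
    score_map: dict,
    truth_set: set,
    threshold_schedule: np.ndarray | None = None,
) -> PrCurve:
    """Precision-recall curve of scored predictions against a truth set.

    ``score_map`` maps items (e.g. directed edges or linkage pairs) to
    scores; items absent from the map count as score 0 and are never
    predicted.  The default schedule sweeps the unique observed scores in
    descending order (for integer tallies this is the decrement-by-1 sweep
    restricted to occupied levels, which touches the same curve points).
    """
    if not truth_set:
        raise ValueError("truth set must be nonempty")
    try:  # deterministic tie-breaking regardless of dict construction order
        items = sorted(score_map)
    except TypeError:
        items = list(score_map)
    scores = np.array([score_map[k] for k in items], dtype=float)
    truth = np.array([k in truth_set for k in items], dtype=bool)
    if threshold_schedule is None:
        threshold_schedule = np.unique(scores)[::-1]
    thresholds = np.asarray(threshold_schedule, dtype=float)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    cum_tp = np.cumsum(sorted_truth)
    cum_fp = np.cumsum(~sorted_truth)

    n_true = len(truth_set)
    tp_list, fp_list, prec, rec, kept = [], [], [], [], []
    for tau in thresholds:
        k = int(np.searchsorted(-sorted_scores, -tau, side="right"))
        if k == 0:
            continue  # no predictions at this threshold
        tp = int(cum_tp[k - 1])
        fp = int(cum_fp[k - 1])
        tp_list.append(tp)
        fp_list.append(fp)
        prec.append(tp / (tp + fp))
        rec.append(tp / n_true)
        kept.append(tau)

    if not kept:
        raise ValueError("no predictions above any threshold")
    recall = np.asarray(rec)
    precision = np.asarray(prec)
    # anchor at recall 0 with the first point's precision for the trapezoid
    r_ext = np.concatenate([[0.0], recall])
    p_ext = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(p_ext, r_ext))
    return PrCurve(
        thresholds=np.asarray(kept),
        tp=np.asarray(tp_list),
        fp=np.asarray(fp_list),
        precision=precision,
        recall=recall,
        auc=auc,
    )


def recall_at_precision(curve: PrCurve, precision_level: float) -> float:
    """Best recall among curve points with precision at or above the level.

    Returns 0 when the level is unattained (no interpolation).
    """
    ok = curve.precision >= precision_level
    if not ok.any():
        return 0.0
    return float(curve.recall[ok].max())


def distortion(
    freqs_a: dict,
    freqs_b: dict,
    universe: list | None = None,
) -> float:
    """Mean absolute edge-frequency difference over the edge universe.

    ``universe`` defaults to the union of keys; for graph diagnostics pass
    the full set of edges legal under the head-node constraints so that
    edges absent from both intervals dilute the average as zeros.
    """
    keys = universe if universe is not None else sorted(set(freqs_a) | set(freqs_b))
    if not keys:
        raise ValueError("empty edge universe")
    total = 0.0
    for k in keys:
        total += abs(freqs_a.get(k, 0.0) - freqs_b.get(k, 0.0))
    return total / len(keys)


def stability(consensus_edge_sets: list[set], threshold: float | None = None) -> dict[int, float]:
    """Fractions count(x)/T of edges present in exactly x of the runs.

    ``T`` is the size of the union of the consensus sets; the returned
    fractions over x = 1..n_runs sum to 1.  ``threshold`` is recorded by
    callers only; the sets are assumed already thresholded.
    """
    n_runs = len(consensus_edge_sets)
    if n_runs == 0:
        raise ValueError("need at least one edge set")
    union: dict = {}
    for s in consensus_edge_sets:
        for e in s:
            union[e] = union.get(e, 0) + 1
    total = len(union)
    out = {x: 0.0 for x in range(1, n_runs + 1)}
    if total == 0:
        return out
    for count in union.values():
        out[count] += 1
    return {x: v / total for x, v in out.items()}


def plot_pr_curves(curves: dict[str, PrCurve], path, title: str = "Precision-recall") -> None:
    """Plot one or more precision-recall curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(curve.recall, curve.precision, label=f"{label} (AUC {curve.auc:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
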