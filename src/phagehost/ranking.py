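"""Turning score tables into host predictions and evaluating them.

Predictions follow the ties-count-as-correct rule: every host attaining
a phage's row-optimal score is predicted, and the phage counts correct
at a taxonomic rank if any predicted host shares the true host's lineage
name at that rank.  Because an all-tied row is trivially "correct", the
mean prediction-set size is always reported alongside accuracies so
degenerate tables are visible.

ROC curves sweep the score cutoff from its maximum to its minimum value;
pairs tied at a threshold enter together.  The x=y diagonal is the
reference random predictor, and a closed-form/simulated random baseline
(each phage assigned 1-4 uniformly random hosts) anchors what "better
than chance" means for the rank accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoretable import ScoreTable
from .taxonomy import RANKS, Lineage, ranks_shared

__all__ = [
    "RocCurve",
    "top_hosts",
    "accuracy_at_rank",
    "accuracy_by_rank",
    "mean_prediction_set_size",
    "roc_curve",
    "roc_from_table",
    "random_baseline",
    "expected_random_accuracy",
]


def top_hosts(table: ScoreTable, phage_id: str) -> set[str]:
    """Hosts tied at the row-optimal score; empty set for no-evidence rows."""
    return table.top_hosts(phage_id)


def _check_truth(table: ScoreTable, truth: dict[str, str]):
    missing = [p for p in table.phage_ids if p not in truth]
    if missing:
        raise KeyError(f"phages missing from truth: {missing[:5]}")


def accuracy_at_rank(
    table: ScoreTable,
    truth: dict[str, str],
    lineages: dict[str, Lineage],
    rank: str,
) -> float:
    """Fraction of phages whose prediction set contains a host matching
    the true host's lineage at ``rank``.

    Phages with an empty prediction set count as incorrect.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    _check_truth(table, truth)
    n_correct = 0
    for pid in table.phage_ids:
        true_lin = lineages[truth[pid]]
        for hid in table.top_hosts(pid):
            if rank in ranks_shared(lineages[hid], true_lin):
                n_correct += 1
                break
    return n_correct / len(table.phage_ids)


def accuracy_by_rank(
    table: ScoreTable, truth: dict[str, str], lineages: dict[str, Lineage]
) -> dict[str, float]:
    return {rank: accuracy_at_rank(table, truth, lineages, rank) for rank in RANKS}


def mean_prediction_set_size(table: ScoreTable) -> float:
    """Mean size of non-empty prediction sets (degeneracy safeguard);
    0.0 when no phage has evidence."""
    sizes = [len(table.top_hosts(p)) for p in table.phage_ids]
    sizes = [s for s in sizes if s > 0]
    return float(np.mean(sizes)) if sizes else 0.0


@dataclass
class RocCurve:
    """ROC points with the threshold attained at each point.

    ``fpr``/``tpr`` include the initial (0, 0); ``thresholds`` aligns with
    the remaining points (the score value at which each was reached).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    """Build an ROC curve from (score, is_true_pair) data.

    Scores are treated as higher-is-better.  The cutoff sweeps from the
    maximum score down; pairs with equal scores enter together.  The
    curve starts at (0, 0) and, with no external cutoff, ends at (1, 1).
    Area is trapezoidal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_true = int(labels.sum())
    n_false = labels.size - n_true
    if n_true == 0 or n_false == 0:
        raise ValueError("ROC requires at least one true and one false pair")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a threshold (distinct score value) ends
    last = np.flatnonzero(np.diff(s)) if s.size > 1 else np.empty(0, dtype=int)
    last = np.concatenate((last, [s.size - 1]))
    cum_tp = np.cumsum(y)[last]
    cum_fp = np.cumsum(~y)[last]
    tpr = np.concatenate(([0.0], cum_tp / n_true))
    fpr = np.concatenate(([0.0], cum_fp / n_false))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=s[last], auc=float(np.trapezoid(tpr, fpr)))


def roc_from_table(
    table: ScoreTable, truth: dict[str, str], impute_missing_worst: bool = False
) -> RocCurve:
    """ROC over all numeric (phage, host) pairs of a table.

    No-evidence pairs are excluded by default (a pair a signal cannot
    assess never enters the sweep); ``impute_missing_worst=True`` instead
    assigns them a score below the observed minimum for sensitivity
    analysis.
    """
    scores, labels = table.oriented_pairs(truth)
    if impute_missing_worst:
        vals = table.scores.to_numpy(dtype=float)
        if not table.higher_is_better:
            vals = -vals
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            worst = np.nanmin(vals) - 1.0 if scores.size else 0.0
            hosts = np.asarray(table.scores.columns)
            miss_labels = []
            for i, pid in enumerate(table.scores.index):
                row = np.isnan(vals[i])
                miss_labels.append((hosts[row] == truth.get(pid)))
            miss_labels = np.concatenate(miss_labels)
            scores = np.concatenate((scores, np.full(n_missing, worst)))
            labels = np.concatenate((labels, miss_labels))
    return roc_curve(scores, labels)


def roc_to_tsv(curve: RocCurve, path) -> None:
    import pandas as pd

    thr = np.concatenate(([np.inf], curve.thresholds))
    pd.DataFrame({"fp_rate": curve.fpr, "tp_rate": curve.tpr, "threshold": thr}).to_csv(
        path, sep="\t", index=False
    )


def expected_random_accuracy(n_hosts: int, picks=(1, 2, 3, 4)) -> float:
    """Closed-form species accuracy of uniform random host sets: E[k]/H."""
    return float(np.mean(picks)) / n_hosts


def random_baseline(
    truth: dict[str, str],
    host_pool: list[str],
    picks=(1, 2, 3, 4),
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Species-level accuracy distribution of random host assignment.

    Each phage gets k hosts (k uniform over ``picks``) drawn uniformly
    without replacement; the prediction is correct if the true host is in
    the set.  Sampling uses the fact that the true host lands in a
    uniform k-subset exactly when its position in a random permutation is
    below k.  Returns per-replicate accuracies.
    """
    H = len(host_pool)
    picks = tuple(picks)
    if max(picks) > H:
        raise ValueError(f"cannot pick {max(picks)} hosts from a pool of {H}")
    pool = set(host_pool)
    for pid, hid in truth.items():
        if hid not in pool:
            raise ValueError(f"true host {hid!r} of {pid!r} not in host pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(truth)
    ks = rng.choice(picks, size=(n_reps, n))
    position = rng.integers(0, H, size=(n_reps, n))
    correct = position < ks
    return correct.mean(axis=1)
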