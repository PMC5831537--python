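"""Phage x candidate-host score matrix shared by every signal.

A :class:`ScoreTable` records one signal's scores together with its
orientation (higher- or lower-is-better) and keeps "no evidence" (NaN)
distinct from any numeric score: a pair for which a signal cannot be
computed (no CRISPR array, too few shared samples) is not a low score.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

NA_MARKER = "NA"


@dataclass
class ScoreTable:
    scores: pd.DataFrame  # index = phage ids, columns = host ids; NaN = no evidence
    higher_is_better: bool = True
    name: str = ""

    def __post_init__(self):
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("score table ids must be unique")

    @property
    def phage_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def host_ids(self) -> list[str]:
        return list(self.scores.columns)

    def top_hosts(self, phage_id: str) -> set[str]:
        """All hosts attaining the row-optimal score (ties kept).

        Rows with no numeric score (all no-evidence) return an empty set.
        """
        if phage_id not in self.scores.index:
            raise KeyError(f"unknown phage id {phage_id!r}")
        row = self.scores.loc[phage_id].dropna()
        if row.empty:
            return set()
        opt = row.max() if self.higher_is_better else row.min()
        return set(row.index[row == opt])

    def oriented_pairs(self, truth: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
        """(score, is_true_pair) arrays for ROC sweeps, no-evidence excluded.

        Scores are negated for lower-is-better tables so that higher
        always means a stronger prediction.
        """
        vals = self.scores.to_numpy(dtype=float)
        if not self.higher_is_better:
            vals = -vals
        hosts = np.asarray(self.scores.columns)
        labels = np.zeros(vals.shape, dtype=bool)
        for i, pid in enumerate(self.scores.index):
            if pid in truth:
                labels[i] = hosts == truth[pid]
        keep = ~np.isnan(vals)
        return vals[keep], labels[keep]

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.scores.copy()
        df.index.name = "phage"
        df.to_csv(path, sep="\t", na_rep=NA_MARKER)

    @classmethod
    def read_tsv(cls, path: str | os.PathLike, higher_is_better: bool = True, name: str = "") -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_MARKER])
        return cls(scores=df.astype(float), higher_is_better=higher_is_better, name=name)
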