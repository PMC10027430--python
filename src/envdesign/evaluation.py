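"""Evaluation of designs and of the environment classifier.

Covers the method-internal metrics: positional sequence identity between
a design and the native sequence, confidence-sorted top-K accuracy
curves (prediction accuracy over the most confident fraction of
environments), per-ground-truth-type accuracy with a 20×20 confusion
matrix, and a Pearson-correlation hook for externally computed
per-residue solvent accessibility versus prediction confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import alphabet
from .model import confidence_score
from .structure_io import SequenceRecord

TOP_KS = (1, 2, 3, 4, 5)
DEFAULT_COVERAGE_GRID = (0.1, 0.25, 0.5, 0.75, 1.0)

Prediction = tuple[np.ndarray, int]  # (20-way distribution, true type index)


def sequence_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Fraction of equal letters at aligned positions (no alignment step:
    design preserves length, so identity is positional)."""
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    if not sa:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(sa.upper(), sb.upper())) / len(sa)


@dataclass(frozen=True)
class AccuracyCurve:
    """Top-K accuracy over the most confident fraction of predictions."""

    coverages: tuple[float, ...]
    counts: tuple[int, ...]
    accuracy: dict[int, tuple[float, ...]]  # K -> accuracy per coverage

    def to_frame(self) -> pd.DataFrame:
        data = {"coverage": self.coverages, "n": self.counts}
        for k in sorted(self.accuracy):
            data[f"top{k}"] = self.accuracy[k]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _topk_hits(dist: np.ndarray, true_idx: int, ks: Sequence[int]) -> list[bool]:
    order = np.argsort(-dist, kind="stable")
    rank = int(np.where(order == true_idx)[0][0])
    return [rank < k for k in ks]


def confidence_sorted_accuracy(
    predictions: Sequence[Prediction],
    coverage_grid: Sequence[float] = DEFAULT_COVERAGE_GRID,
) -> AccuracyCurve:
    """Sort by negative-entropy confidence (descending, ties by input
    order) and report top-K accuracy over each retained head fraction.

    A coverage of 0.1 keeps the ceil(0.1·N) most confident predictions.
    """
    if not predictions:
        raise ValueError("no predictions to evaluate")
    for f in coverage_grid:
        if not (0.0 < f <= 1.0):
            raise ValueError("coverage fractions must lie in (0, 1]")
    conf = np.array([confidence_score(d) for d, _ in predictions])
    order = np.argsort(-conf, kind="stable")
    hits = np.array(
        [_topk_hits(predictions[i][0], predictions[i][1], TOP_KS) for i in order]
    )
    counts, acc = [], {k: [] for k in TOP_KS}
    for f in coverage_grid:
        m = max(1, math.ceil(f * len(predictions)))
        counts.append(m)
        head = hits[:m]
        for j, k in enumerate(TOP_KS):
            acc[k].append(float(head[:, j].mean()))
    return AccuracyCurve(
        coverages=tuple(coverage_grid),
        counts=tuple(counts),
        accuracy={k: tuple(v) for k, v in acc.items()},
    )


def per_type_accuracy(
    predictions: Sequence[Prediction],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-1 accuracy grouped by ground-truth type, plus confusion matrix.

    Confusion rows are ground truth, columns predicted (argmax); row sums
    equal the per-type counts.
    """
    if not predictions:
        raise ValueError("no predictions to evaluate")
    confusion = np.zeros((alphabet.N_TYPES, alphabet.N_TYPES), dtype=int)
    for dist, true_idx in predictions:
        confusion[true_idx, int(np.argmax(dist))] += 1
    counts = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        acc = np.where(counts > 0, np.diag(confusion) / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "type": list(alphabet.ONE_LETTER),
            "top1_accuracy": acc,
            "count": counts,
        }
    )
    return table, confusion


def confusion_to_csv(confusion: np.ndarray, path: str | Path) -> None:
    """Labeled 20×20 confusion matrix (rows true, columns predicted)."""
    pd.DataFrame(
        confusion,
        index=list(alphabet.ONE_LETTER),
        columns=list(alphabet.ONE_LETTER),
    ).to_csv(path, index_label="true\\pred")


def accessibility_confidence_correlation(
    confidences: Sequence[float], accessibilities: Sequence[float]
) -> float:
    """Pearson correlation between prediction confidence and externally
    computed per-residue solvent accessibility values."""
    c = np.asarray(confidences, dtype=float)
    a = np.asarray(accessibilities, dtype=float)
    if c.shape != a.shape or c.size < 2:
        raise ValueError("need two equal-length series of length ≥ 2")
    return float(stats.pearsonr(c, a).statistic)
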