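"""Data splitting, pre-training grid search, AUROC, and model comparison.

The experimental protocol: each library's reads and their shuffled
negatives are split class-balanced into 75% training / 25% held-out test
(50/50 for oversized libraries); 25% of the training rows form the
*pre-training* subset on which forest hyperparameters are grid-searched;
the final model is retrained on the full training set with the chosen
configuration.  Models are compared by test-set AUROC per library and,
across libraries, by median AUROC with paired two-sided Wilcoxon
signed-rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitSpec",
    "DatasetSplit",
    "EvaluationResult",
    "split_dataset",
    "grid_search",
    "GridSearchResult",
    "auroc",
    "wilcoxon_signed_rank",
    "compare_models",
    "ComparisonReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Split fractions: 0.75 train (0.50 for oversized libraries), and the
    fraction of training rows held aside for hyperparameter pre-training."""

    train_fraction: float = 0.75
    pretrain_fraction_of_train: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_fraction, self.pretrain_fraction_of_train):
            if not 0 < f < 1:
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass(frozen=True)
class DatasetSplit:
    """Index arrays into the original read list; pretrain is a subset of train."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    pretrain_idx: np.ndarray


@dataclass(frozen=True)
class EvaluationResult:
    model_name: str
    auroc: float
    n_pos: int
    n_neg: int


def split_dataset(labels: Sequence[int], spec: SplitSpec) -> DatasetSplit:
    """Class-balanced random train/test/pretrain split by index.

    Within each class independently, floor(train_fraction x n) rows go to
    training (the remainder, the larger share of any rounding, to test) and
    floor(pretrain_fraction x n_train) of those to pre-training.  Seed
    reproducible; raises if any subset would be empty.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts, pre_parts = [], [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        n_pre = int(np.floor(spec.pretrain_fraction_of_train * n_train))
        if n_train == 0 or n_pre == 0 or n_train == len(idx):
            raise ValueError(
                f"split fractions yield an empty subset for class {c} "
                f"(n={len(idx)})"
            )
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
        pre_parts.append(idx[:n_pre])
    return DatasetSplit(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        pretrain_idx=np.sort(np.concatenate(pre_parts)),
    )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals U / (n1 * n0): the probability that a random positive outscores
    a random negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes")
    ranks = stats.rankdata(scores)
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]
                         ) -> Tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; the statistic is the smaller of the
    positive- and negative-rank sums.  The p-value uses the exact null
    distribution for n <= 25 surviving pairs and the normal approximation
    with continuity correction beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    statistic = float(min(w_plus, w_minus))
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return statistic, float(res.pvalue)


#: a trainer consumes (train_reads, train_labels, eval_reads, eval_labels,
#: config) and returns scores for the eval reads
Trainer = Callable[..., np.ndarray]


@dataclass(frozen=True)
class GridSearchResult:
    best: "ForestConfig"  # noqa: F821 - forward ref, models imports lazily
    table: pd.DataFrame   # columns: min_node_size, mtry_fraction, auroc


def grid_search(
    reads: Sequence,
    labels: Sequence[int],
    trainer: Trainer,
    grid: Optional[Sequence] = None,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> GridSearchResult:
    """Hyperparameter search on the pre-training subset.

    The subset is split once, class-balanced, into an internal fit part and
    a hold-out part (``holdout_fraction``); every grid cell trains on the
    fit part and is scored by hold-out AUROC.  The default grid is the
    4 x 5 (min node size x mtry fraction) table.  Ties break to the smaller
    node size, then the smaller mtry fraction, so the result is invariant
    to grid enumeration order.  Cells whose training fails are logged and
    skipped; if every cell fails, an error is raised.
    """
    if grid is None:
        from .models import default_grid

        grid = default_grid(seed=seed)
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    labels = np.asarray(labels, dtype=int)
    inner = split_dataset(labels, SplitSpec(1.0 - holdout_fraction, 0.5, seed))
    fit_idx, val_idx = inner.train_idx, inner.test_idx
    fit_reads = [reads[i] for i in fit_idx]
    val_reads = [reads[i] for i in val_idx]
    fit_y, val_y = labels[fit_idx], labels[val_idx]

    rows = []
    for cfg in grid:
        try:
            scores = trainer(fit_reads, fit_y, val_reads, val_y, cfg)
            cell_auc = auroc(scores, val_y)
        except Exception:  # pragma: no cover - defensive per-cell logging
            logger.exception(
                "grid cell failed (min_node_size=%s, mtry_fraction=%s)",
                cfg.min_node_size, cfg.mtry_fraction,
            )
            continue
        rows.append({"min_node_size": cfg.min_node_size,
                     "mtry_fraction": cfg.mtry_fraction,
                     "auroc": cell_auc, "config": cfg})
    if not rows:
        raise RuntimeError("every grid cell failed")
    table = pd.DataFrame(rows)
    ordered = table.sort_values(
        ["auroc", "min_node_size", "mtry_fraction"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.iloc[0]["config"]
    return GridSearchResult(best, table.drop(columns="config"))


@dataclass(frozen=True)
class ComparisonReport:
    medians: pd.Series          # per-model median AUROC
    pairwise_p: pd.DataFrame    # two-sided Wilcoxon p-values (NaN on diagonal)
    table: pd.DataFrame         # the input per-library AUROC table

    def summary(self) -> str:
        lines = ["Median AUROC per model:"]
        for name, med in self.medians.items():
            lines.append(f"  {name}: {med:.3f}")
        lines.append("Pairwise Wilcoxon signed-rank p-values (two-sided):")
        for m1 in self.pairwise_p.index:
            for m2 in self.pairwise_p.columns:
                if m1 < m2:
                    p = self.pairwise_p.loc[m1, m2]
                    txt = "no difference" if pd.isna(p) else f"p = {p:.3g}"
                    lines.append(f"  {m1} vs {m2}: {txt}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def compare_models(results: pd.DataFrame) -> ComparisonReport:
    """Compare models across libraries by median AUROC and paired Wilcoxon.

    ``results`` has one row per library (index = library id) and one AUROC
    column per model; at least two models, no missing cells (a missing cell
    means the library ids are misaligned across models).
    """
    if results.shape[1] < 2:
        raise ValueError("need at least two model columns to compare")
    if results.isna().any().any():
        bad = results.index[results.isna().any(axis=1)].tolist()
        raise ValueError(f"misaligned library ids (missing AUROCs) for {bad}")
    medians = results.median(axis=0)
    models = list(results.columns)
    pmat = pd.DataFrame(np.nan, index=models, columns=models)
    for i, m1 in enumerate(models):
        for m2 in models[i + 1:]:
            try:
                _, p = wilcoxon_signed_rank(results[m1].to_numpy(),
                                            results[m2].to_numpy())
            except ValueError:
                p = np.nan  # identical columns: no detectable difference
            pmat.loc[m1, m2] = p
            pmat.loc[m2, m1] = p
    return ComparisonReport(medians, pmat, results)
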