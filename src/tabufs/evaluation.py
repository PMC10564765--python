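"""Cross-validated evaluation protocol: fold-wise selection, test metrics,
and paired t-tests between methods.

All four metrics are computed from a single 2x2 confusion table:

    ACC   = (TP + TN) / (TP + FP + TN + FN)
    AUC   = (1 + TP/(TP+FN) - FP/(TN+FP)) / 2
    Gmean = sqrt( TP/(TP+FN) * TN/(TN+FP) )
    F1    = 2*TP / (2*TP + FP + FN)

Note that AUC here is the balanced-accuracy form (1 + TPR - FPR)/2 computed
from the thresholded predictions of one confusion table; it is deliberately
NOT the threshold-free ROC integral, which would not be comparable.  When a
test fold has no positives or no negatives the affected metric is undefined
and reported as NaN (with a warning), and that fold is excluded from t-test
pairing rather than silently scored zero.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import classifiers
from .data_io import Dataset, normalize, stratified_kfold
from .objective import EvaluationCache, FeatureSubset, ObjectiveConfig
from .search import SearchParams, multistart_tabu

METRICS = ("acc", "auc", "gmean", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldRecord:
    """Everything recorded for one cross-validation fold."""

    fold: int
    subset: FeatureSubset
    train_f: float
    train_rat: float
    counts: ConfusionCounts
    metrics: dict[str, float]
    wall_time: float


@dataclass(frozen=True)
class ComparisonVerdict:
    """Outcome of a paired two-tailed t test between two per-fold score lists.

    ``verdict`` is "+" when the difference is significant in favor of the
    first method, "-" in favor of the second, "=" otherwise.
    """

    t: float
    p: float
    verdict: str
    degenerate: bool = False


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
) -> ConfusionCounts:
    """Standard 2x2 tally of predictions against truth."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    t_pos = yt == positive
    p_pos = yp == positive
    return ConfusionCounts(
        tp=int((t_pos & p_pos).sum()),
        tn=int((~t_pos & ~p_pos).sum()),
        fp=int((~t_pos & p_pos).sum()),
        fn=int((t_pos & ~p_pos).sum()),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined: zero denominator", stacklevel=3)
        return float("nan")
    return num / den


def metric_acc(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "ACC")


def metric_auc(c: ConfusionCounts) -> float:
    tpr = _ratio(c.tp, c.tp + c.fn, "AUC (TPR)")
    fpr = _ratio(c.fp, c.tn + c.fp, "AUC (FPR)")
    return (1.0 + tpr - fpr) / 2.0


def metric_gmean(c: ConfusionCounts) -> float:
    tpr = _ratio(c.tp, c.tp + c.fn, "Gmean (TPR)")
    tnr = _ratio(c.tn, c.tn + c.fp, "Gmean (TNR)")
    return math.sqrt(tpr * tnr) if not (math.isnan(tpr) or math.isnan(tnr)) else float("nan")


def metric_f1(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1")


_METRIC_FNS = {
    "acc": metric_acc,
    "auc": metric_auc,
    "gmean": metric_gmean,
    "f1": metric_f1,
}


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {name: fn(c) for name, fn in _METRIC_FNS.items()}


def paired_t_test(
    a: Sequence[float], b: Sequence[float], level: float = 0.05
) -> ComparisonVerdict:
    """Classical paired two-tailed t test on per-fold score differences.

    Pairs where either score is NaN (undefined metric on that fold) are
    dropped.  Zero variance of the differences is degenerate: all-zero
    differences give "=", otherwise the sign verdict with p = 0.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("score lists must be aligned by fold")
    keep = ~(np.isnan(av) | np.isnan(bv))
    d = av[keep] - bv[keep]
    k = d.size
    if k < 2:
        raise ValueError("need at least two valid pairs")
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        if mean_d == 0.0:
            return ComparisonVerdict(t=0.0, p=1.0, verdict="=", degenerate=True)
        t = math.inf if mean_d > 0 else -math.inf
        return ComparisonVerdict(
            t=t, p=0.0, verdict="+" if mean_d > 0 else "-", degenerate=True
        )
    t = mean_d / (sd_d / math.sqrt(k))
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    if p < level:
        verdict = "+" if mean_d > 0 else "-"
    else:
        verdict = "="
    return ComparisonVerdict(t=float(t), p=float(p), verdict=verdict)


def run_cv_experiment(
    ds: Dataset,
    cfg: ObjectiveConfig | None = None,
    params: SearchParams | None = None,
    k: int = 10,
    seed: int = 0,
    normalize_method: str = "zscore",
) -> tuple[list[FoldRecord], dict[str, tuple[float, float]]]:
    """Fold-wise selection and held-out scoring.

    For each of the k stratified folds: normalize the training fold (and
    apply its transform to the test fold), run the multistart tabu search
    on the training fold, refit the final classifier on the training fold
    restricted to the selected subset, and score the held-out fold.
    Returns the per-fold records and a ``{metric: (mean, sd)}`` summary
    (NaN-aware, sample sd).  Deterministic given ``seed`` for the DA
    classifier: fold assignment and each fold's search seed derive from it.
    """
    cfg = cfg or ObjectiveConfig()
    params = params or SearchParams()
    plan = stratified_kfold(ds, k=k, seed=seed)
    seed_rng = np.random.default_rng(seed)
    fold_seeds = [int(s) for s in seed_rng.integers(2**31, size=k)]

    records: list[FoldRecord] = []
    for fold, (train_idx, test_idx) in enumerate(plan.splits()):
        t0 = time.perf_counter()
        train, (test,) = normalize(
            ds.take(train_idx), [ds.take(test_idx)], method=normalize_method
        )
        fold_params = SearchParams(
            alpha=params.alpha,
            tenure=params.tenure,
            max_iter_ts=params.max_iter_ts,
            max_iter_ms=params.max_iter_ms,
            seed=fold_seeds[fold],
        )
        result = multistart_tabu(train, cfg, fold_params, cache=EvaluationCache())
        model = classifiers.fit(cfg.classifier, train, result.best_subset)
        y_pred = classifiers.predict(model, test)
        counts = confusion_counts(test.labels, y_pred, positive=1)
        records.append(
            FoldRecord(
                fold=fold,
                subset=result.best_subset,
                train_f=result.best_f,
                train_rat=result.best_rat,
                counts=counts,
                metrics=compute_metrics(counts),
                wall_time=time.perf_counter() - t0,
            )
        )
    return records, summarize(records)


def summarize(records: Sequence[FoldRecord]) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample sd) across folds, ignoring undefined folds."""
    out: dict[str, tuple[float, float]] = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*(empty slice|[Dd]egrees of freedom).*")
        for name in METRICS:
            vals = np.array([r.metrics[name] for r in records], dtype=float)
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
    return out


def format_summary(summary: dict[str, tuple[float, float]]) -> str:
    """Render a summary as percentage "mean ± sd" rows with 2 decimals."""
    lines = []
    for name in METRICS:
        mean, sd = summary[name]
        lines.append(f"{name.upper():>5}: {100 * mean:.2f} ± {100 * sd:.2f}")
    return "\n".join(lines)
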