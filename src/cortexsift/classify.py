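"""Binary classification experiments over ROI pairs and b-value conditions.

Each experiment trains a 15-tree random forest under leave-one-out cross
validation on the per-vertex feature vectors of two cortical ROIs and
records the confusion counts, accuracy and per-ROI F1.  A condition is a
named combination of acquisitions — e.g. three repeats of the middle b-value
(``R3``) against one acquisition of each b-value (``M3``) — and conditions
are compared across the grid of ROI pairs with a one-sided Wilcoxon rank-sum
test on the per-pair accuracies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ExperimentResult",
    "ConditionComparison",
    "loo_rf_binary",
    "aggregate_f1",
    "compare_conditions",
    "run_condition_grid",
    "CONDITION_TAGS",
]

N_ESTIMATORS = 15

# condition tag -> acquisition selector over sorted unique b-values
# L/M/H = lowest/middle/highest shell, digit = repeat index within that shell
CONDITION_TAGS = {
    "R3": ("M0", "M1", "M2"),
    "M3": ("L0", "M0", "H0"),
    "R2": ("M0", "M1"),
    "LM": ("L0", "M0"),
    "MH": ("M0", "H0"),
    "LH": ("L0", "H0"),
}


@dataclass
class ExperimentResult:
    """Outcome of one leave-one-out binary classification experiment."""

    roi_pair: tuple[str, str]
    condition: str
    n_vertices: dict[str, int]
    confusion: dict[str, int]  # TP/FP/TN/FN with roi_pair[1] as "positive"
    accuracy: float
    f1_per_roi: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.confusion[k] for k in ("TP", "FP", "TN", "FN"))
        if total != sum(self.n_vertices.values()):
            raise ValueError("confusion counts do not sum to the number of vertices")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [0, 1]")


@dataclass
class ConditionComparison:
    """One-sided rank-sum comparison of two conditions across ROI pairs."""

    condition_a: str
    condition_b: str
    accuracies_a: np.ndarray
    accuracies_b: np.ndarray
    mean_difference: float  # percentage points, a - b
    sd_difference: float
    p_value: float
    test: str = "ranksum"

    def summary(self) -> str:
        return (
            f"{self.condition_a} - {self.condition_b}: "
            f"{self.mean_difference:.1f}% ± {self.sd_difference:.1f}% "
            f"(one-sided {self.test} p = {self.p_value:.3g})"
        )


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def loo_rf_binary(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    condition: str = "",
    roi_pair: tuple[str, str] | None = None,
) -> ExperimentResult:
    """Leave-one-out random-forest classification of two ROIs.

    A fresh 15-tree forest (scikit-learn defaults otherwise) is trained for
    every held-out vertex; the ``seed`` fixes every forest's randomness so
    the experiment is reproducible.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("feature/label length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    counts = {str(c): int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("each class needs at least 2 vertices for leave-one-out")
    if roi_pair is None:
        roi_pair = (str(classes[0]), str(classes[1]))

    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = RandomForestClassifier(n_estimators=N_ESTIMATORS, random_state=seed)
        clf.fit(X[train], y[train])
        pred[i] = clf.predict(X[i : i + 1])[0]

    pos = classes[1]  # "positive" class = second label alphabetically
    tp = int(np.sum((pred == pos) & (y == pos)))
    fp = int(np.sum((pred == pos) & (y != pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    tn = int(np.sum((pred != pos) & (y != pos)))
    acc = (tp + tn) / n
    # per-ROI F1: each ROI in turn as the positive class
    f1_pos = _f1(tp, fp, fn)
    f1_neg = _f1(tn, fn, fp)
    return ExperimentResult(
        roi_pair=roi_pair,
        condition=condition,
        n_vertices=counts,
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        accuracy=acc,
        f1_per_roi={str(classes[0]): f1_neg, str(classes[1]): f1_pos},
        seed=seed,
    )


def aggregate_f1(results: list[ExperimentResult], roi: str) -> float:
    """Mean F1 of one ROI across every binary test it took part in."""
    scores = [r.f1_per_roi[roi] for r in results if roi in r.f1_per_roi]
    if not scores:
        raise ValueError(f"ROI {roi!r} appears in no result")
    return float(np.mean(scores))


def compare_conditions(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    condition_a: str = "a",
    condition_b: str = "b",
    test: str = "ranksum",
) -> ConditionComparison:
    """One-sided test that condition a's per-pair accuracies exceed b's.

    The default is the Wilcoxon rank-sum (Mann-Whitney U) test, exact when
    both groups have at most 25 entries and no ties, otherwise the normal
    approximation with tie correction.  ``test="signed_rank"`` switches to
    the paired Wilcoxon signed-rank test.
    """
    a = np.asarray(acc_a, dtype=float).ravel()
    b = np.asarray(acc_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("accuracy vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired experiments")
    diffs = a - b
    if test == "ranksum":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue
    elif test == "signed_rank":
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = stats.wilcoxon(a, b, alternative="greater").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return ConditionComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        accuracies_a=a,
        accuracies_b=b,
        mean_difference=float(diffs.mean() * 100.0),
        sd_difference=float(diffs.std(ddof=1) * 100.0),
        p_value=float(p),
        test=test,
    )


def _pair_seed(master_seed: int, roi_a: str, roi_b: str, condition: str) -> int:
    """Stable per-(pair, condition) forest seed derived from the master seed."""
    tag = f"{roi_a}|{roi_b}|{condition}".encode()
    return int((zlib.crc32(tag) ^ (master_seed * 2654435761)) % (2**31 - 1))


def run_condition_grid(
    dataset: dict[str, dict],
    rois: list[str],
    conditions: list[str],
    seed: int = 0,
) -> tuple[list[ExperimentResult], pd.DataFrame]:
    """Run every (ROI pair x condition) binary experiment.

    ``dataset`` maps a condition tag to ``{"features": (n, 9k) array,
    "labels": (n,) array}`` with features already concatenated in ascending-b
    order (same-b repeats in acquisition order).  Returns the result list
    and a tidy DataFrame (one row per pair x condition).
    """
    for cond in conditions:
        if cond not in dataset:
            raise ValueError(f"condition {cond!r} not present in dataset")
    pairs = [(rois[i], rois[j]) for i in range(len(rois)) for j in range(i + 1, len(rois))]
    results: list[ExperimentResult] = []
    rows = []
    for cond in conditions:
        X = np.asarray(dataset[cond]["features"], dtype=float)
        y = np.asarray(dataset[cond]["labels"])
        for ra, rb in pairs:
            mask = (y == ra) | (y == rb)
            res = loo_rf_binary(
                X[mask],
                y[mask],
                seed=_pair_seed(seed, ra, rb, cond),
                condition=cond,
                roi_pair=(ra, rb),
            )
            results.append(res)
            rows.append(
                {
                    "roi_a": ra,
                    "roi_b": rb,
                    "condition": cond,
                    "n_a": res.n_vertices[ra],
                    "n_b": res.n_vertices[rb],
                    "TP": res.confusion["TP"],
                    "FP": res.confusion["FP"],
                    "TN": res.confusion["TN"],
                    "FN": res.confusion["FN"],
                    "accuracy": res.accuracy,
                    "f1_a": res.f1_per_roi[ra],
                    "f1_b": res.f1_per_roi[rb],
                    "seed": res.seed,
                }
            )
    return results, pd.DataFrame(rows)
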