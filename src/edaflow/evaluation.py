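"""Statistical screening and single-feature threshold classification.

Each feature is screened with a two-group one-way ANOVA (calm vs
distress), then assessed as a stand-alone classifier: on every training
split an ROC scan picks the threshold (and direction) with the highest
training accuracy, and the held-out fold is scored with it.  Folds are
stratified 10-fold, the whole procedure repeated 5 times, and
sensitivity / specificity / accuracy (distress = positive class) are
averaged separately for the learning and test phases.

The two segments of one subject are treated as independent samples by
default, matching an unpaired screening analysis; ``group_by_subject``
keeps both segments of a subject in the same fold to rule out
subject-level leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "anova_screen",
    "roc_optimal_threshold",
    "confusion_metrics",
    "stratified_fold_indices",
    "stratified_cv",
    "ThresholdRule",
]

POSITIVE = "distress"
NEGATIVE = "calm"


@dataclass(frozen=True)
class ThresholdRule:
    """Single-feature decision rule: predict distress on one side of a cut.

    ``direction`` is ``">="`` (scores at or above the threshold are called
    distress) or ``"<="``.
    """

    threshold: float
    direction: str

    def predict(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, float)
        pos = scores >= self.threshold if self.direction == ">=" else scores <= self.threshold
        return np.where(pos, POSITIVE, NEGATIVE)


def _check_labels(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    return labels


def confusion_metrics(predictions: Sequence[str], labels: Sequence[str]) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy in percent (distress positive)."""
    labels = _check_labels(labels)
    predictions = _check_labels(predictions)
    if len(labels) == 0:
        raise ValueError("empty input")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    pos = labels == POSITIVE
    tp = np.sum((predictions == POSITIVE) & pos)
    fn = np.sum((predictions == NEGATIVE) & pos)
    tn = np.sum((predictions == NEGATIVE) & ~pos)
    fp = np.sum((predictions == POSITIVE) & ~pos)
    se = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    sp = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    acc = 100.0 * (tp + tn) / len(labels)
    return float(se), float(sp), float(acc)


def anova_screen(table: pd.DataFrame, alpha: float = 0.05,
                 features: Iterable[str] = FEATURE_NAMES) -> pd.DataFrame:
    """Per-feature one-way ANOVA between the calm and distress groups.

    Returns a frame indexed by feature with columns F, p, significant, plus
    advisory Shapiro-Wilk (per group) and Levene p-values.  These advisory
    checks never gate the ANOVA.  Degenerate data (both groups constant
    with equal means) is reported as F=0, p=1.
    """
    g1 = table.loc[table["condition"] == NEGATIVE]
    g2 = table.loc[table["condition"] == POSITIVE]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 samples per class")
    rows = {}
    for feat in features:
        a, b = g1[feat].to_numpy(float), g2[feat].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            f, p = (0.0, 1.0)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                f, p = stats.f_oneway(a, b)
            if not np.isfinite(p):
                f, p = (0.0, 1.0)
        sw_calm = stats.shapiro(a).pvalue if np.ptp(a) > 0 else np.nan
        sw_dist = stats.shapiro(b).pvalue if np.ptp(b) > 0 else np.nan
        lev = stats.levene(a, b).pvalue if np.ptp(np.r_[a, b]) > 0 else np.nan
        rows[feat] = {"F": float(f), "p": float(p), "significant": bool(p < alpha),
                      "shapiro_calm_p": sw_calm, "shapiro_distress_p": sw_dist,
                      "levene_p": lev}
    return pd.DataFrame.from_dict(rows, orient="index")


def roc_optimal_threshold(scores: Sequence[float], labels: Sequence[str]) -> tuple[ThresholdRule, tuple[float, float, float]]:
    """Accuracy-optimal threshold over the ROC candidate set.

    Candidates are the midpoints between consecutive sorted unique scores
    plus sentinels below and above all scores; both directions are scanned.
    Ties are broken toward higher sensitivity, then toward the lower
    threshold, then toward the ``">="`` direction, so the rule is
    deterministic.  Returns the rule and its training (Se, Sp, Acc).
    """
    scores = np.asarray(scores, float)
    labels = _check_labels(labels)
    classes = set(labels)
    if classes != {POSITIVE, NEGATIVE}:
        raise ValueError("both classes must be present to build an ROC")
    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate([[uniq[0] - span], (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + span]])
    best: Optional[tuple] = None
    for direction in (">=", "<="):
        for thr in candidates:
            rule = ThresholdRule(float(thr), direction)
            se, sp, acc = confusion_metrics(rule.predict(scores), labels)
            key = (acc, se, -thr, direction == ">=")
            if best is None or key > best[0]:
                best = (key, rule, (se, sp, acc))
    return best[1], best[2]


def stratified_fold_indices(
    table: pd.DataFrame,
    k: int,
    rng: np.random.Generator,
    group_by_subject: bool = False,
) -> np.ndarray:
    """Fold label per row (0..k-1), stratified by condition.

    Rows are processed in sorted (subject_id, condition) order so the fold
    assignment depends only on the identities, not on the incoming row
    order.  Within each class the rows are shuffled and dealt round-robin,
    which keeps per-fold class counts within one sample of each other.
    With ``group_by_subject`` whole subjects are dealt to folds instead.
    """
    order = np.lexsort((table["condition"].to_numpy(), table["subject_id"].to_numpy()))
    folds = np.empty(len(table), dtype=int)
    if group_by_subject:
        subjects = np.unique(table["subject_id"].to_numpy()[order])
        rng.shuffle(subjects)
        assign = {s: i % k for i, s in enumerate(subjects)}
        folds[:] = [assign[s] for s in table["subject_id"]]
        return folds
    for cond in (NEGATIVE, POSITIVE):
        idx = order[table["condition"].to_numpy()[order] == cond]
        if len(idx) < k:
            raise ValueError(f"class '{cond}' has fewer than k={k} samples")
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


def stratified_cv(
    table: pd.DataFrame,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    features: Iterable[str] = FEATURE_NAMES,
    group_by_subject: bool = False,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV of every single-feature ROC classifier.

    Returns one row per feature with learning- and test-phase Se/Sp/Acc in
    percent, averaged over all folds and repeats, plus the per-fold
    thresholds (as a list) for inspection.  Fold assignment is a pure
    function of (seed, repeat).
    """
    features = list(features)
    sums = {f: np.zeros(6) for f in features}
    thresholds: dict[str, list[float]] = {f: [] for f in features}
    n_eval = 0
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(rep,)))
        folds = stratified_fold_indices(table, k, rng, group_by_subject)
        for fold in range(k):
            train = table.loc[folds != fold]
            test = table.loc[folds == fold]
            if test.empty:
                continue
            n_eval += 1
            for feat in features:
                rule, (se_l, sp_l, acc_l) = roc_optimal_threshold(
                    train[feat].to_numpy(float), train["condition"].to_numpy())
                se_t, sp_t, acc_t = confusion_metrics(
                    rule.predict(test[feat].to_numpy(float)), test["condition"].to_numpy())
                sums[feat] += [se_l, sp_l, acc_l,
                               np.nan_to_num(se_t), np.nan_to_num(sp_t), acc_t]
                thresholds[feat].append(rule.threshold)
    cols = ["learn_se", "learn_sp", "learn_acc", "test_se", "test_sp", "test_acc"]
    out = pd.DataFrame({f: sums[f] / n_eval for f in features}, index=cols).T
    out.index.name = "feature"
    out["thresholds"] = [thresholds[f] for f in features]
    out.attrs["seed"] = seed
    out.attrs["k"] = k
    out.attrs["repeats"] = repeats
    return out
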