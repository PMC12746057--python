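"""Discrimination, calibration, decision-analytic and feature-level
evaluation of out-of-fold growth predictions.

All metrics operate on out-of-fold probabilities (every patient predicted
by a model that never saw them), matching internal-validation practice for
small clinical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "confusion_metrics", "roc_auc", "pr_auc", "calibration_metrics",
    "net_benefit", "operating_point", "paired_bootstrap_auc",
    "permutation_importance", "stable_feature_set", "cohens_d",
    "group_features", "FeatureEffect", "evaluate_predictions",
    "default_feature_grouping",
]


def _cells(probs, labels, cutoff):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = probs >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return tp, fp, fn, tn


def confusion_metrics(probs, labels, cutoff) -> dict:
    """Accuracy, sensitivity, specificity, FPR, FNR and diagnostic odds
    ratio at ``prob >= cutoff -> positive``.

    The DOR uses the Haldane-Anscombe 0.5 correction when any cell is
    empty (flagged in the output)."""
    tp, fp, fn, tn = _cells(probs, labels, cutoff)
    n = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    corrected = min(tp, fp, fn, tn) == 0
    if corrected:
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        dor = (tp * tn) / (fp * fn)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "fpr": 1.0 - spec,
        "fnr": 1.0 - sens,
        "dor": float(dor),
        "dor_corrected": corrected,
    }


def roc_auc(probs, labels) -> float:
    """Rank-based AUC (ties count one half)."""
    return float(roc_auc_score(np.asarray(labels).astype(int), probs))


def pr_auc(probs, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    return float(average_precision_score(np.asarray(labels).astype(int),
                                         probs))


def calibration_metrics(probs, labels, n_bins: int = 10) -> dict:
    """Calibration-in-the-large, Brier score and a binned reliability
    curve.

    Calibration-in-the-large is the observed event rate minus the mean
    predicted probability; the curve uses ``n_bins`` equal-width bins with
    per-bin counts."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    cil = float(labels.mean() - probs.mean())
    brier = float(np.mean((probs - labels) ** 2))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append({
            "bin": b, "lo": edges[b], "hi": edges[b + 1],
            "count": int(m.sum()),
            "mean_prob": float(probs[m].mean()) if m.any() else np.nan,
            "event_rate": float(labels[m].mean()) if m.any() else np.nan,
        })
    return {"calibration_in_the_large": cil, "brier": brier,
            "curve": pd.DataFrame(rows)}


def net_benefit(probs, labels, thresholds) -> pd.DataFrame:
    """Decision-curve net benefit with treat-all / treat-none references.

    ``NB(t) = TP/N - (FP/N) * t/(1-t)`` classifying at cutoff t;
    treat-all: ``pi - (1-pi) t/(1-t)``; treat-none: 0."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    labels = np.asarray(labels).astype(int)
    n = labels.size
    pi = labels.mean()
    rows = []
    for t in thresholds:
        tp, fp, _, _ = _cells(probs, labels, t)
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp / n - (fp / n) * odds,
            "treat_all": pi - (1.0 - pi) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def operating_point(probs, labels, mode: str, constraint: float) -> dict:
    """Post-hoc rule-in / rule-out operating points.

    rule_out: maximise specificity subject to sensitivity >= constraint;
    rule_in: maximise sensitivity subject to specificity >= constraint;
    the search runs over observed probabilities."""
    if mode not in ("rule_in", "rule_out"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < constraint < 1:
        raise ValueError("constraint must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    candidates = np.concatenate([np.sort(np.unique(probs)),
                                 [np.nextafter(probs.min(), -np.inf)]])
    best = None
    for c in candidates:
        tp, fp, fn, tn = _cells(probs, labels, c)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if mode == "rule_out" and sens >= constraint:
            if best is None or spec > best["specificity"]:
                best = {"cutoff": float(c), "sensitivity": sens,
                        "specificity": spec}
        if mode == "rule_in" and spec >= constraint:
            if best is None or sens > best["sensitivity"]:
                best = {"cutoff": float(c), "sensitivity": sens,
                        "specificity": spec}
    if best is None:
        return {"feasible": False, "mode": mode, "constraint": constraint}
    best.update({"feasible": True, "mode": mode, "constraint": constraint})
    return best


def paired_bootstrap_auc(probs_a, probs_b, labels, n_boot: int = 1000,
                         seed: int = 2024) -> dict:
    """Paired bootstrap comparison of two models' AUCs on the same
    patients.

    Patients are resampled with replacement; replicates with a single
    class are redrawn (counted in the output).  The two-sided p-value is
    ``2 * min(frac <= 0, frac >= 0)`` bounded below by 1/N."""
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (probs_a.size == probs_b.size == labels.size):
        raise ValueError("paired comparison needs identical patients")
    rng = np.random.default_rng(seed)
    n = labels.size
    diffs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size == 2:
                break
            redraws += 1
        diffs[b] = (roc_auc_score(labels[idx], probs_a[idx])
                    - roc_auc_score(labels[idx], probs_b[idx]))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    p = float(np.clip(p, 1.0 / n_boot, 1.0))
    return {"mean_diff": float(diffs.mean()), "ci95": (float(lo), float(hi)),
            "p_value": p, "n_boot": n_boot, "redraws": redraws}


def permutation_importance(model, components, labels, seed: int = 2024,
                           n_repeats: int = 20) -> np.ndarray:
    """Signed permutation importance of each principal component.

    Magnitude is the mean AUC drop over ``n_repeats`` permutations of one
    column; the sign is that of the rank correlation between the component
    and the predicted probability (negative association marks components
    pointing toward stability/regression)."""
    x = np.asarray(components, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    base_prob = model.predict_proba(x)[:, 1]
    base_auc = roc_auc_score(labels, base_prob)
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            drops.append(base_auc
                         - roc_auc_score(labels,
                                         model.predict_proba(xp)[:, 1]))
        rho = spearmanr(x[:, j], base_prob).statistic
        sign = 1.0 if (np.isnan(rho) or rho >= 0) else -1.0
        out[j] = sign * float(np.mean(drops))
    return out


def stable_feature_set(per_fold_top_k) -> list:
    """Exact intersection of the per-fold top-k feature-name sets, ordered
    by each feature's best (earliest) rank across folds."""
    sets = [list(s) for s in per_fold_top_k]
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    # order by mean rank across folds (proxy for mean F statistic ordering)
    def mean_rank(name):
        return np.mean([s.index(name) for s in sets])

    return sorted(common, key=mean_rank)


def cohens_d(values, labels) -> float:
    """Standardised mean difference (growing minus nongrowing) with pooled
    SD; NaN (flagged) when the pooled SD is zero."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    g1, g0 = values[labels == 1], values[labels == 0]
    if g1.size < 2 or g0.size < 2:
        raise ValueError("Cohen's d needs >= 2 samples per class")
    s1, s0 = g1.var(ddof=1), g0.var(ddof=1)
    pooled = np.sqrt(((g1.size - 1) * s1 + (g0.size - 1) * s0)
                     / (g1.size + g0.size - 2))
    if pooled == 0:
        return float("nan")
    return float((g1.mean() - g0.mean()) / pooled)


@dataclass
class FeatureEffect:
    feature: str
    group: str
    mean_growing: float
    sd_growing: float
    mean_nongrowing: float
    sd_nongrowing: float
    d: float


_VALUE_PAT = ("Mean", "Median", "Minimum", "Maximum", "Percentile10",
              "Percentile90", "RootMeanSquared", "Energy", "TotalEnergy",
              "Autocorrelation", "JointAverage", "SumAverage")
_VARIANCE_PAT = ("Variance", "MeanAbsoluteDeviation",
                 "RobustMeanAbsoluteDeviation", "InterquartileRange",
                 "Range", "Skewness", "Kurtosis", "SumSquares",
                 "DifferenceVariance")
_CLUSTER_PAT = ("ClusterProminence", "ClusterShade", "ClusterTendency",
                "Correlation", "Imc1", "Imc2", "MCC")
_LOW_GRAY_PAT = ("LowGray", "SmallAreaLow", "SmallDependenceLow",
                 "ShortRunLow", "LongRunLow", "LargeAreaLow",
                 "LargeDependenceLow")
_HIGH_GRAY_PAT = ("HighGray", "SmallAreaHigh", "SmallDependenceHigh",
                  "ShortRunHigh", "LongRunHigh", "LargeAreaHigh",
                  "LargeDependenceHigh")


def default_feature_grouping(feature_names) -> dict:
    """Map feature names to per-channel representation groups.

    Groups follow the representation a feature conveys (value level,
    dispersion, spatial clustering, heterogeneity, prominence of low/high
    gray values, texture extent, shape), prefixed by channel."""
    out = {}
    for name in feature_names:
        channel, family, feat = name.split("_", 2)
        if family == "shape":
            rep = "shape"
        elif any(feat.startswith(p) or p in feat for p in _LOW_GRAY_PAT):
            rep = "prominence of low gray values"
        elif any(feat.startswith(p) or p in feat for p in _HIGH_GRAY_PAT):
            rep = "prominence of high gray values"
        elif family == "firstorder" and feat in _VALUE_PAT:
            rep = "value"
        elif feat in _VARIANCE_PAT:
            rep = "variance"
        elif feat in _CLUSTER_PAT:
            rep = "clustering"
        elif family == "glcm" and feat in _VALUE_PAT:
            rep = "value"
        elif feat in ("Entropy", "Uniformity", "JointEntropy", "JointEnergy",
                      "SumEntropy", "DifferenceEntropy", "RunEntropy",
                      "ZoneEntropy", "DependenceEntropy", "Busyness",
                      "Complexity", "Contrast", "DifferenceAverage",
                      "Coarseness", "Strength", "Id", "Idm", "Idmn", "Idn",
                      "InverseVariance", "MaximumProbability") or \
                "NonUniformity" in feat:
            rep = "heterogeneity"
        else:
            rep = "texture extent"
        out[name] = f"{channel}:{rep}"
    return out


def group_features(feature_names, values_df: pd.DataFrame, labels,
                   grouping: dict | None = None) -> list[FeatureEffect]:
    """Group selected features and report each group's most discriminative
    member by |Cohen's d| with class-stratified means and SDs."""
    if grouping is None:
        grouping = default_feature_grouping(feature_names)
    missing = [f for f in feature_names if f not in grouping]
    if missing:
        raise ValueError(f"features without a group mapping: {missing}")
    labels = np.asarray(labels).astype(int)
    by_group: dict[str, list] = {}
    for f in feature_names:
        by_group.setdefault(grouping[f], []).append(f)
    effects = []
    for group, members in by_group.items():
        best, best_d = None, -np.inf
        for f in members:
            d = cohens_d(values_df[f].values, labels)
            if np.isfinite(d) and abs(d) > best_d:
                best, best_d = f, abs(d)
        if best is None:
            continue
        vals = values_df[best].values
        g1, g0 = vals[labels == 1], vals[labels == 0]
        effects.append(FeatureEffect(
            feature=best, group=group,
            mean_growing=float(g1.mean()), sd_growing=float(g1.std(ddof=1)),
            mean_nongrowing=float(g0.mean()),
            sd_nongrowing=float(g0.std(ddof=1)),
            d=cohens_d(vals, labels)))
    effects.sort(key=lambda e: -abs(e.d))
    return effects


def evaluate_predictions(oof: pd.DataFrame, fold_metrics: pd.DataFrame,
                         rule_out_sens: float = 0.95,
                         rule_in_spec: float = 0.95) -> dict:
    """Assemble the full evaluation report from out-of-fold predictions.

    Fold-level discrimination metrics are aggregated as mean +/- SD; the
    confusion-cell metrics (FPR/FNR/DOR), calibration and decision curves
    are pooled over all out-of-fold samples."""
    probs = oof["prob"].values
    labels = oof["label"].values
    preds = oof["pred"].values
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    corrected = min(tp, fp, fn, tn) == 0
    dor = (((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
           if corrected else (tp * tn) / (fp * fn))
    cal = calibration_metrics(probs, labels)
    report = {
        "fold_summary": {c: {"mean": float(fold_metrics[c].mean()),
                             "sd": float(fold_metrics[c].std(ddof=1))}
                         for c in ("auc", "aucpr", "accuracy",
                                   "sensitivity", "specificity", "cutoff")},
        "pooled": {
            "auc": roc_auc(probs, labels),
            "aucpr": pr_auc(probs, labels),
            "accuracy": (tp + tn) / len(labels),
            "fpr": fp / (fp + tn),
            "fnr": fn / (fn + tp),
            "dor": float(dor),
            "dor_corrected": corrected,
            "calibration_in_the_large": cal["calibration_in_the_large"],
            "brier": cal["brier"],
        },
        "calibration_curve": cal["curve"],
        "decision_curve": net_benefit(probs, labels,
                                      np.arange(0.05, 0.95, 0.05)),
        "rule_out": operating_point(probs, labels, "rule_out",
                                    rule_out_sens),
        "rule_in": operating_point(probs, labels, "rule_in", rule_in_spec),
    }
    return report
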