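"""Nested cross-validated radiomics classifier for tumour-growth prediction.

The modelling chain per training fold is: fixed-bin-width discretization
(bin widths fitted on the training patients only) -> feature extraction ->
Z-score standardization -> ANOVA F-test top-k selection -> PCA to n
components -> class-weighted SVM with Platt-calibrated probabilities ->
Youden-J probability cutoff.  Hyper-parameters (kernel, C, gamma, N_bins,
k, n) are chosen per outer training set by inner stratified cross-
validation; every fitted statistic applied to a validation patient derives
exclusively from that fold's training patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import radiomics
from .roi import RoiMask, erode_cross, remove_cysts

__all__ = [
    "PipelineConfig", "FoldResult", "NestedCVResult", "CohortFeatureSource",
    "make_folds", "standardize", "select_top_k", "pca_reduce", "train_svm",
    "youden_cutoff", "run_nested_cv", "run_baseline", "default_grid",
    "compact_grid", "FEATURE_SUBSETS",
]

FEATURE_SUBSETS = ("full", "volume_only", "t2_only", "fos_dce_only")

DCE_CHANNELS = ("ktrans", "ve", "vp")


@dataclass(frozen=True)
class PipelineConfig:
    """One hyper-parameter combination of the classification pipeline."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"  # rbf bandwidth; ignored for linear
    n_bins: int = 32
    k: int = 100
    n: int = 25

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 1 <= self.n < self.k:
            raise ValueError("require 1 <= n < k")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def describe(self) -> str:
        g = f", gamma={self.gamma}" if self.kernel == "rbf" else ""
        return (f"SVM({self.kernel}, C={self.C}{g}) "
                f"N_bins={self.n_bins}, k={self.k}, n={self.n}")


def default_grid() -> list[PipelineConfig]:
    """The full default hyper-parameter grid (includes the reference
    study's selected triple N_bins=32, k=100, n=25 with a Gaussian
    kernel)."""
    grid = []
    pairs = [(k, n) for k in (20, 30, 100) for n in (2, 5, 25) if n < k]
    for n_bins in (16, 32, 64):
        for k, n in pairs:
            for C in (0.1, 1.0, 10.0):
                grid.append(PipelineConfig("linear", C, "scale", n_bins, k, n))
                for gscale in (0.5, 1.0, 2.0):
                    grid.append(PipelineConfig("rbf", C, gscale, n_bins, k, n))
    return grid


def compact_grid() -> list[PipelineConfig]:
    """A desk-scale grid around the reference configuration, used by the
    worked examples and the acceptance run."""
    out = []
    for k, n in ((100, 25), (30, 5)):
        out.append(PipelineConfig("rbf", 1.0, "scale", 32, k, n))
        out.append(PipelineConfig("rbf", 10.0, "scale", 32, k, n))
        out.append(PipelineConfig("linear", 1.0, "scale", 32, k, n))
        out.append(PipelineConfig("linear", 0.1, "scale", 32, k, n))
    return out


# ---------------------------------------------------------------------------
# Feature source with strict training-fold discretization
# ---------------------------------------------------------------------------

class CohortFeatureSource:
    """Per-patient channel data with fold-aware feature extraction.

    ROI conditioning (cyst removal, in-plane cross erosion) happens once at
    construction; discretization bin widths are fitted per request on a
    stated list of training patients, so feature tables are leakage-free by
    construction.  Width-independent statistics (shape, most first-order
    features) are cached per patient, width-dependent ones per
    (patient, channel, width).
    """

    def __init__(self, patients, erosion_mode: str = "2d",
                 min_roi_voxels: int = 8):
        self.ids: list[str] = []
        self.labels = {}
        self.baseline_volume = {}
        self._values = {}   # id -> channel -> 1D ROI values
        self._images = {}   # id -> channel -> cropped 3D image
        self._masks = {}    # id -> cropped conditioned mask
        self._spacing = {}
        self._static = {}   # id -> width-independent named features
        self._wcache = {}   # (id, channel, width) -> dict
        self._width_names = None

        for p in patients:
            roi = RoiMask(p.roi_mask, spacing=p.spacing_mm)
            conditioned = remove_cysts(roi, RoiMask(p.cyst_mask,
                                                    spacing=p.spacing_mm))
            if not conditioned.data.any():
                conditioned = roi
            eroded = erode_cross(conditioned, mode=erosion_mode)
            mask = (eroded.data if eroded.voxel_count >= min_roi_voxels
                    else conditioned.data)

            sl = tuple(slice(max(0, s.start - 1), s.stop + 1)
                       for s in ndimage_find_objects(mask))
            cmask = mask[sl]
            channels = {"t2": p.t2_image, "ktrans": p.maps.ktrans,
                        "ve": p.maps.ve, "vp": p.maps.vp}
            self.ids.append(p.id)
            self.labels[p.id] = 1 if p.is_growing else 0
            self.baseline_volume[p.id] = p.baseline_volume_cm3
            self._masks[p.id] = cmask
            self._spacing[p.id] = p.spacing_mm
            self._images[p.id] = {ch: np.asarray(img, float)[sl]
                                  for ch, img in channels.items()}
            self._values[p.id] = {ch: self._images[p.id][ch][cmask]
                                  for ch in channels}
            self._static[p.id] = self._static_features(p.id)

    # -- static (width-independent) part ---------------------------------
    def _static_features(self, pid):
        shape = radiomics.shape_features(self._masks[pid],
                                         self._spacing[pid])
        voxvol = float(np.prod(self._spacing[pid]))
        out = {}
        for ch in radiomics.CHANNELS:
            vals = self._values[pid][ch]
            fo = radiomics.first_order_features(vals, np.ones(vals.size,
                                                              dtype=int),
                                                voxvol)
            for name in radiomics.FIRST_ORDER_NAMES:
                if name not in ("Entropy", "Uniformity"):
                    out[f"{ch}_firstorder_{name}"] = fo[name]
            for name in radiomics.SHAPE_NAMES:
                out[f"{ch}_shape_{name}"] = shape[name]
        return out

    # -- width-dependent part --------------------------------------------
    def _width_features(self, pid, ch, width):
        key = (pid, ch, width)
        cached = self._wcache.get(key)
        if cached is not None:
            return cached
        img = self._images[pid][ch]
        mask = self._masks[pid]
        disc = radiomics.discretize(img, mask, width)
        levels = disc[mask]
        counts = np.bincount(levels)[1:]
        pr = counts[counts > 0] / levels.size
        out = {f"{ch}_firstorder_Entropy": float(-np.sum(pr * np.log2(pr))),
               f"{ch}_firstorder_Uniformity": float(np.sum(pr**2))}
        for fam, func in (("glcm", radiomics.glcm_features),
                          ("glrlm", radiomics.glrlm_features),
                          ("glszm", radiomics.glszm_features),
                          ("ngtdm", radiomics.ngtdm_features),
                          ("gldm", radiomics.gldm_features)):
            try:
                vals = func(disc, mask)
            except ValueError:  # degenerate ROI (e.g. single voxel)
                vals = {name: 0.0 for name in dict(radiomics.FAMILIES)[fam]}
            for name, v in vals.items():
                out[f"{ch}_{fam}_{name}"] = float(v)
        self._wcache[key] = out
        return out

    def fit_rule(self, train_ids, n_bins) -> radiomics.DiscretizationRule:
        return radiomics.fit_bin_widths(
            {ch: [self._values[i][ch] for i in train_ids]
             for ch in radiomics.CHANNELS}, n_bins)

    def feature_table(self, train_ids, n_bins, rows=None):
        """404-column feature table (id-indexed), with bin widths fitted on
        ``train_ids`` only.  ``rows`` restricts which patients get a row
        (default: the whole cohort).  Returns (DataFrame, rule)."""
        rule = self.fit_rule(train_ids, n_bins)
        row_ids = list(rows) if rows is not None else list(self.ids)
        recs = []
        for pid in row_ids:
            row = dict(self._static[pid])
            for ch in radiomics.CHANNELS:
                row.update(self._width_features(pid, ch, rule.widths[ch]))
            recs.append(row)
        df = pd.DataFrame(recs, index=row_ids)
        return df[radiomics.feature_names()], rule

    def volume_table(self) -> pd.DataFrame:
        return pd.DataFrame({"baseline_volume_cm3":
                             [self.baseline_volume[i] for i in self.ids]},
                            index=self.ids)

    def label_vector(self) -> np.ndarray:
        return np.array([self.labels[i] for i in self.ids])


def ndimage_find_objects(mask):
    """Bounding-box slices of a binary mask."""
    from scipy import ndimage

    obj = ndimage.find_objects(mask.astype(np.int8))[0]
    return obj


def subset_columns(columns, subset: str) -> list[str]:
    """Feature-name subset for the ablation baselines."""
    if subset == "full":
        return list(columns)
    if subset == "t2_only":
        return [c for c in columns if c.startswith("t2_")]
    if subset == "fos_dce_only":
        return [c for c in columns
                if any(c.startswith(f"{ch}_firstorder_")
                       for ch in DCE_CHANNELS)]
    raise ValueError(f"unknown feature subset {subset!r}")


# ---------------------------------------------------------------------------
# Elementary fold operations
# ---------------------------------------------------------------------------

def make_folds(labels, outer_folds: int = 5, seed: int = 2024):
    """Deterministic stratified fold assignment.

    Returns a list of (train_indices, validation_indices) pairs; per-fold
    class proportions are within one patient of the global proportions.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < outer_folds:
        raise ValueError("each class needs at least as many patients as "
                         "folds")
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                          random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def standardize(train: pd.DataFrame, apply_to: pd.DataFrame):
    """Z-score using training statistics only; zero-variance training
    columns are dropped (returned in the drop log)."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(train.columns[~keep])
    cols = train.columns[keep]
    z_train = (train[cols] - mean[cols]) / sd[cols]
    z_apply = (apply_to[cols] - mean[cols]) / sd[cols]
    return z_train, z_apply, {"mean": mean[cols], "sd": sd[cols],
                              "dropped": dropped}


def select_top_k(z_train: pd.DataFrame, labels, k: int):
    """Indices (column names) of the k largest ANOVA F statistics; ties
    broken by fixed column order."""
    if k > z_train.shape[1]:
        k = z_train.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(z_train.values, np.asarray(labels))
    f_stat = np.where(np.isfinite(f_stat), f_stat, np.inf)  # perfect sep
    order = np.argsort(-f_stat, kind="stable")
    chosen = order[:k]
    return [z_train.columns[i] for i in chosen], f_stat


def pca_reduce(z_train: pd.DataFrame, z_apply: pd.DataFrame, n: int):
    """PCA basis from the training covariance; validation data are
    projected with the training basis.  Returns (train scores, apply
    scores, fitted PCA, retained variance fraction)."""
    rank = min(z_train.shape)
    if n > rank:
        raise ValueError(f"n={n} exceeds the training matrix rank {rank}")
    pca = PCA(n_components=n, svd_solver="full")
    s_train = pca.fit_transform(z_train.values)
    s_apply = pca.transform(z_apply.values)
    retained = float(np.sum(pca.explained_variance_ratio_))
    return s_train, s_apply, pca, retained


def train_svm(components, labels, config: PipelineConfig, seed: int = 2024,
              calibrate: bool = True):
    """Class-weighted SVM with Platt-calibrated probability outputs.

    Balanced class weights give each class weight N/(2 N_class); the
    probability mapping is a sigmoid fitted on internal cross-validated
    decision values (``ensemble=False`` keeps a single SVM fitted on the
    full training fold).  ``calibrate=False`` returns the bare margin
    classifier."""
    from sklearn.calibration import CalibratedClassifierCV

    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int), minlength=2)
    if (counts > 0).sum() < 2:
        raise ValueError("training requires both classes")
    gamma = config.gamma
    if config.kernel == "rbf" and not isinstance(gamma, str):
        # interpret numeric gamma as a multiple of the scale heuristic
        x = np.asarray(components)
        scale = 1.0 / (x.shape[1] * x.var()) if x.var() > 0 else 1.0
        gamma = float(gamma) * scale
    svm = SVC(kernel=config.kernel, C=config.C,
              gamma=gamma if config.kernel == "rbf" else "scale",
              class_weight="balanced", random_state=seed)
    if not calibrate:
        svm.fit(components, labels)
        return svm
    cv = int(min(5, counts[counts > 0].min()))
    if cv < 2:
        raise ValueError("calibration needs >= 2 samples per class")
    clf = CalibratedClassifierCV(svm, method="sigmoid", cv=cv,
                                 ensemble=False)
    clf.fit(components, labels)
    return clf


def youden_cutoff(probs, labels):
    """Probability cutoff maximising J = sensitivity + specificity - 1.

    Candidates are the observed probabilities; classification convention is
    ``prob >= cutoff -> positive``; among maximisers the lowest cutoff is
    returned."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_j, best_c = -np.inf, None
    for c in np.sort(np.unique(probs)):
        pred = probs >= c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c, float(best_j)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_index: int
    train_ids: list
    val_ids: list
    config: PipelineConfig
    selected_features: list
    retained_variance: float
    cutoff: float
    val_probs: np.ndarray
    val_labels: np.ndarray
    bin_widths: dict | None = None
    dropped_features: list = field(default_factory=list)


@dataclass
class NestedCVResult:
    subset: str
    folds: list
    oof: pd.DataFrame            # id, label, prob, pred
    fold_metrics: pd.DataFrame   # one row per fold
    summary: dict                # mean/sd per metric + pooled


def _fit_predict(table, labels_by_id, train_ids, val_ids,
                 config: PipelineConfig, seed, volume_only=False,
                 leaky=False):
    """Fit the standardize->select->PCA->SVM chain on the training rows and
    return (train probs, val probs, details).  ``leaky`` deliberately fits
    the standardization on all rows (a bug mode used to prove the leakage
    guard detects it)."""
    df_train = table.loc[train_ids]
    df_val = table.loc[val_ids]
    if leaky:
        mean = table.mean(axis=0)
        sd = table.std(axis=0, ddof=0)
        keep = sd > 0
        cols = table.columns[keep]
        z_train = (df_train[cols] - mean[cols]) / sd[cols]
        z_val = (df_val[cols] - mean[cols]) / sd[cols]
        dropped = list(table.columns[~keep])
    else:
        z_train, z_val, stats = standardize(df_train, df_val)
        dropped = stats["dropped"]
    y_train = labels_by_id.loc[train_ids].values

    if volume_only:
        selected = list(z_train.columns)
        s_train, s_val = z_train.values, z_val.values
        retained = 1.0
    else:
        selected, _ = select_top_k(z_train, y_train, config.k)
        n = min(config.n, len(selected), len(train_ids) - 1)
        s_train, s_val, _, retained = pca_reduce(z_train[selected],
                                                 z_val[selected], n)
    clf = train_svm(s_train, y_train, config, seed=seed)
    p_train = clf.predict_proba(s_train)[:, 1]
    p_val = clf.predict_proba(s_val)[:, 1]
    return p_train, p_val, {"selected": selected, "retained": retained,
                            "dropped": dropped, "model": clf}


def run_nested_cv(source: CohortFeatureSource, grid=None, subset="full",
                  outer_folds=5, inner_folds=5, seed=2024,
                  labels=None, cutoff_mode="oof",
                  leaky=False) -> NestedCVResult:
    """Nested stratified cross-validation over a hyper-parameter grid.

    Per outer fold the best configuration is the one with the highest mean
    inner-fold AUC (ties: first in grid order); discretization widths,
    standardization, F-test ranking, PCA basis, SVM and Youden cutoff are
    all fitted strictly inside the training patients of the fold in
    question.  ``labels`` overrides the cohort's own labels (used for
    permutation analyses).
    """
    if grid is None:
        grid = compact_grid()
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    if subset not in FEATURE_SUBSETS:
        raise ValueError(f"unknown feature subset {subset!r}")
    ids = np.array(source.ids)
    y = np.asarray(labels if labels is not None else source.label_vector())
    volume_only = subset == "volume_only"
    if volume_only:
        # kernel/C only; n_bins/k/n are irrelevant for a 1-feature model
        seen, vgrid = set(), []
        for cfg in grid:
            key = (cfg.kernel, cfg.C, cfg.gamma)
            if key not in seen:
                seen.add(key)
                vgrid.append(cfg)
        grid = vgrid

    y_ser = pd.Series(y, index=ids)

    def get_table(train_idx, n_bins, rows=None):
        if volume_only:
            return source.volume_table(), None
        fit_ids = list(ids) if leaky else list(ids[train_idx])
        df, rule = source.feature_table(fit_ids, n_bins, rows=rows)
        cols = subset_columns(df.columns, subset)
        return df[cols], rule

    outer = make_folds(y, outer_folds, seed)
    folds, oof_rows, metric_rows = [], [], []
    for f_idx, (tr, va) in enumerate(outer):
        # ----- inner model selection -----
        scores = {i: [] for i in range(len(grid))}
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=seed + 1)
        inner_splits = list(inner.split(np.zeros(len(tr)), y[tr]))
        inner_oof = {i: np.empty(len(tr)) for i in range(len(grid))}
        for itr, iva in inner_splits:
            g_tr, g_va = tr[itr], tr[iva]
            by_bins = {}
            for ci, cfg in enumerate(grid):
                nb = cfg.n_bins
                if nb not in by_bins:
                    by_bins[nb] = get_table(g_tr, nb, rows=ids[tr])[0]
                table = by_bins[nb]
                p_tr, p_va, _ = _fit_predict(table, y_ser, ids[g_tr],
                                             ids[g_va], cfg, seed,
                                             volume_only, leaky)
                try:
                    scores[ci].append(roc_auc_score(y[g_va], p_va))
                except ValueError:
                    scores[ci].append(0.5)
                inner_oof[ci][iva] = p_va
        best_ci = int(np.argmax([np.mean(scores[i]) for i in range(len(grid))]))
        best = grid[best_ci]

        # ----- outer refit -----
        table, rule = get_table(tr, best.n_bins)
        p_tr, p_va, info = _fit_predict(table, y_ser, ids[tr], ids[va],
                                        best, seed, volume_only, leaky)
        if cutoff_mode == "oof":
            cutoff, _ = youden_cutoff(inner_oof[best_ci], y[tr])
        else:  # refit-predictions mode
            cutoff, _ = youden_cutoff(p_tr, y[tr])

        pred = (p_va >= cutoff).astype(int)
        folds.append(FoldResult(
            fold_index=f_idx, train_ids=list(ids[tr]), val_ids=list(ids[va]),
            config=best, selected_features=info["selected"],
            retained_variance=info["retained"], cutoff=cutoff,
            val_probs=p_va, val_labels=y[va],
            bin_widths=None if rule is None else dict(rule.widths),
            dropped_features=info["dropped"]))
        for pid, lab, prob, prd in zip(ids[va], y[va], p_va, pred):
            oof_rows.append({"id": pid, "label": int(lab),
                             "prob": float(prob), "pred": int(prd),
                             "fold": f_idx})
        tp = int(((pred == 1) & (y[va] == 1)).sum())
        tn = int(((pred == 0) & (y[va] == 0)).sum())
        npos, nneg = int((y[va] == 1).sum()), int((y[va] == 0).sum())
        metric_rows.append({
            "fold": f_idx,
            "auc": roc_auc_score(y[va], p_va),
            "aucpr": average_precision_score(y[va], p_va),
            "accuracy": (tp + tn) / len(va),
            "sensitivity": tp / npos if npos else np.nan,
            "specificity": tn / nneg if nneg else np.nan,
            "cutoff": cutoff,
            "retained_variance": info["retained"],
        })

    oof = pd.DataFrame(oof_rows).set_index("id").loc[ids].reset_index()
    fm = pd.DataFrame(metric_rows)
    summary = {}
    for col in ("auc", "aucpr", "accuracy", "sensitivity", "specificity",
                "cutoff", "retained_variance"):
        summary[f"{col}_mean"] = float(fm[col].mean())
        summary[f"{col}_sd"] = float(fm[col].std(ddof=1))
    summary["pooled_auc"] = float(roc_auc_score(oof["label"], oof["prob"]))
    return NestedCVResult(subset=subset, folds=folds, oof=oof,
                          fold_metrics=fm, summary=summary)


def run_baseline(source: CohortFeatureSource, subset: str, grid=None,
                 **kwargs) -> NestedCVResult:
    """Ablation baselines: volume only, T2 radiomics only, or first-order
    statistics of the DCE-derived maps only."""
    if subset not in ("volume_only", "t2_only", "fos_dce_only"):
        raise ValueError(f"unknown baseline subset {subset!r}")
    if grid is None:
        grid = compact_grid()
    if subset == "fos_dce_only":
        # only 54 features exist; keep k below that
        grid = [PipelineConfig(c.kernel, c.C, c.gamma, c.n_bins,
                               min(c.k, 20), min(c.n, 5)) for c in grid]
        grid = list(dict.fromkeys(grid))
    return run_nested_cv(source, grid=grid, subset=subset, **kwargs)
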