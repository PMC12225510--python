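"""Random-forest prediction of CIMP class from progenitor chromatin features.

Nine predictors per CGI — progenitor DNA methylation, six histone-mark
signals (H3K27ac, H3K4me1, H3K4me3, H3K27me3, H3K9me3, H3K36me3), CGI
length and distance to the nearest TSS — are used to discriminate
IDH-CIMP from RTK2-CIMP CGIs (or either class from non-CIMP CGIs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "HISTONE_MARKS",
    "FEATURE_COLUMNS",
    "ClassifierReport",
    "build_feature_table",
    "train_cimp_classifier",
    "roc_auc",
    "feature_ecdf",
]

HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3", "H3K36me3")
FEATURE_COLUMNS = ("DNAme",) + HISTONE_MARKS + ("cgi_length", "tss_distance")


@dataclass
class ClassifierReport:
    auc: float
    importances: pd.Series          # percent, sums to 100
    test_scores: pd.Series          # per test CGI: P(positive class)
    test_labels: pd.Series
    positive_class: str
    best_max_features: int
    cv_results: pd.DataFrame
    n_train: int
    n_test: int
    n_trees: int
    seed: int


def build_feature_table(
    signal_np: pd.DataFrame,
    beta_np: pd.Series,
    annotations: dict,
    labels: pd.Series,
    cgis: dict | None = None,
    exclude_labels: tuple[str, ...] = ("both",),
) -> pd.DataFrame:
    """Assemble the 9-predictor feature table for labelled CGIs.

    ``signal_np`` holds the six progenitor histone-mark signals (columns
    named by mark), ``beta_np`` the progenitor DNA methylation. CGIs
    labelled with both phenotypes are excluded, as are rows with any
    missing predictor (both with logged counts). ``cgis`` (id -> CGI)
    supplies lengths; if omitted the column 'cgi_length' must already be
    in ``signal_np``.
    """
    labels = labels[~labels.isin(exclude_labels)]
    n_excluded = 0
    rows = []
    for cgi_id, label in labels.items():
        if cgi_id not in signal_np.index or cgi_id not in beta_np.index:
            n_excluded += 1
            continue
        ann = annotations.get(cgi_id)
        row = {"DNAme": beta_np[cgi_id]}
        for mark in HISTONE_MARKS:
            row[mark] = signal_np.loc[cgi_id, mark] if mark in signal_np.columns else np.nan
        if cgis is not None:
            row["cgi_length"] = cgis[cgi_id].length
        else:
            row["cgi_length"] = signal_np.loc[cgi_id].get("cgi_length", np.nan)
        row["tss_distance"] = ann.tss_distance if ann is not None else np.nan
        row["label"] = label
        rows.append(pd.Series(row, name=cgi_id))
    if not rows:
        raise ValueError("no labelled CGIs with features")
    table = pd.DataFrame(rows)
    complete = table[list(FEATURE_COLUMNS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped or n_excluded:
        logger.info("build_feature_table: dropped %d rows with missing predictors, "
                    "%d without features", n_dropped, n_excluded)
    return table[complete]


def _downsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Downsample the majority class to the minority class size."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        if len(idx) > n_min:
            idx = rng.choice(idx, n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


def train_cimp_classifier(
    features: pd.DataFrame,
    split: float = 0.7,
    n_trees: int = 2000,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    downsample: bool = True,
    max_features_grid: tuple[int, ...] = (2, 3, 5),
    importance: str = "impurity",
    seed: int = 0,
) -> ClassifierReport:
    """Train and evaluate the random-forest CIMP-class classifier.

    Stratified ``split``/(1-split) train/test partition; repeated
    stratified cross-validation on the training portion selects the
    per-split candidate-feature count (``max_features``); class imbalance
    is handled by downsampling the majority class, re-drawn per CV
    resample from the run seed. The final ``n_trees``-tree forest is
    evaluated once on the untouched test split; importances are
    normalized to percent.
    """
    y_all = features["label"]
    classes = sorted(y_all.unique())
    if len(classes) < 2:
        raise ValueError("need two classes to train a classifier")
    if (y_all.value_counts() < cv_folds).any():
        raise ValueError("each class needs at least cv_folds members")
    positive = classes[-1]

    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = (y_all == positive).to_numpy().astype(int)
    rng = np.random.default_rng(seed)

    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=1 - split, stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    X_tr, y_tr = X[idx_train], y[idx_train]

    cv_rows = []
    for mf in max_features_grid:
        aucs = []
        for rep in range(cv_repeats):
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            for fold_tr, fold_va in skf.split(X_tr, y_tr):
                Xf, yf = X_tr[fold_tr], y_tr[fold_tr]
                if downsample:
                    Xf, yf = _downsample(Xf, yf, rng)
                clf = RandomForestClassifier(
                    n_estimators=max(100, n_trees // 10),
                    max_features=min(mf, X.shape[1]),
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                )
                clf.fit(Xf, yf)
                scores = clf.predict_proba(X_tr[fold_va])[:, 1]
                if len(np.unique(y_tr[fold_va])) == 2:
                    aucs.append(roc_auc(scores, y_tr[fold_va]))
        cv_rows.append({"max_features": mf, "cv_auc": float(np.mean(aucs))})
    cv_results = pd.DataFrame(cv_rows)
    best_mf = int(cv_results.loc[cv_results["cv_auc"].idxmax(), "max_features"])

    X_fit, y_fit = (X_tr, y_tr)
    if downsample:
        X_fit, y_fit = _downsample(X_tr, y_tr, rng)
    final = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(best_mf, X.shape[1]),
        random_state=int(rng.integers(2**31)),
        n_jobs=1,
    )
    final.fit(X_fit, y_fit)

    test_scores = final.predict_proba(X[idx_test])[:, 1]
    auc = roc_auc(test_scores, y[idx_test])

    if importance == "permutation":
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(
            final, X[idx_test], y[idx_test], n_repeats=10,
            random_state=int(rng.integers(2**31)),
        ).importances_mean
        imp = np.clip(imp, 0, None)
    else:
        imp = final.feature_importances_
    imp_pct = pd.Series(100 * imp / imp.sum(), index=list(FEATURE_COLUMNS))

    return ClassifierReport(
        auc=float(auc),
        importances=imp_pct,
        test_scores=pd.Series(test_scores, index=features.index[idx_test]),
        test_labels=y_all.iloc[idx_test],
        positive_class=positive,
        best_max_features=best_mf,
        cv_results=cv_results,
        n_train=len(idx_train),
        n_test=len(idx_test),
        n_trees=n_trees,
        seed=seed,
    )


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (ties counted half) = Mann-Whitney U / (n1 * n0)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def feature_ecdf(values_by_group: dict[str, np.ndarray]):
    """Right-continuous empirical CDF per group, evaluable at any point."""
    from statsmodels.distributions.empirical_distribution import ECDF

    out = {}
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {group!r} is empty")
        out[group] = ECDF(vals)
    return out
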