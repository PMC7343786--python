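"""Phenotype association: PCA, ADASYN, Random-Forest LOOCV, Wilcoxon tests.

The 24 synchronisation features of a cohort are associated with binary
phenotypes (echogenicity, symptomaticity, stenosis class, risk class) in two
complementary ways:

* a classification benchmark — standardised features are projected on the
  fewest principal components covering 95% of the variance, the training
  minority class is rebalanced with ADASYN, and a Random Forest (tuning
  grid: 100–900 trees in steps of 200, 2..p candidate features per split,
  inner 10-fold CV) is evaluated by leave-one-out cross-validation, pooling
  the held-out class scores into ACC/SENS/SPEC/PREC/NPV/F1/AUC;
* univariate statistics — a two-sided Wilcoxon rank-sum test per feature,
  significant at p <= 0.05.

PCA, ADASYN and tuning are all refitted inside each leave-one-out training
fold so the held-out plaque never influences the model that scores it.

ADASYN (adaptive synthetic minority oversampling) is implemented here on top
of scikit-learn's nearest-neighbour machinery: each minority sample receives
a share of the deficit ``G = n_maj - n_min`` proportional to the fraction of
majority points among its k nearest neighbours, and synthetic points are
drawn by uniform interpolation toward random minority neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .sync import CC_TYPES

__all__ = [
    "EvaluationReport",
    "pca_select",
    "balance_training",
    "evaluate_loocv",
    "wilcoxon_compare",
    "wilcoxon_table",
    "classification_metrics",
    "variability_experiment",
]

SIGNIFICANCE_LEVEL = 0.05
TREES_GRID = (100, 300, 500, 700, 900)


def _split_features(table: pd.DataFrame, label_col: str):
    X = table.drop(columns=[label_col])
    y = table[label_col]
    return X, y


def pca_select(
    table: pd.DataFrame,
    variance: float = 0.95,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project standardised features on the fewest components covering
    ``variance`` of the total variance.

    Returns the reduced table (PC columns plus the label) and the component
    loadings.  Zero-variance features are dropped with a warning.
    """
    X, y = _split_features(table, label_col)
    keep = X.std(ddof=0) > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        X = X.loc[:, keep]
    Z = StandardScaler().fit_transform(X.to_numpy())
    pca = PCA(svd_solver="full").fit(Z)
    n = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), variance) + 1)
    n = min(n, pca.n_components_)
    if len(table) <= n:
        raise ValueError("fewer samples than retained components")
    scores = pca.transform(Z)[:, :n]
    reduced = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(n)], index=table.index
    )
    reduced[label_col] = y
    loadings = pd.DataFrame(
        pca.components_[:n], columns=X.columns,
        index=[f"PC{i + 1}" for i in range(n)],
    )
    return reduced, loadings


def balance_training(
    train: pd.DataFrame,
    seed: int,
    k: int = 5,
    label_col: str = "label",
) -> pd.DataFrame:
    """ADASYN oversampling of the minority class to near balance (beta = 1).

    Synthetic rows are appended to the training table only; call inside each
    cross-validation training fold.  If the minority class is too small for
    k-nearest-neighbour density estimation, it is duplicated instead (with a
    warning).
    """
    rng = np.random.default_rng(seed)
    X, y = _split_features(train, label_col)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present in the training data")
    minority = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    G = int(n_maj - n_min)
    if G == 0:
        return train.copy()

    Xm = X[y == minority].to_numpy(dtype=float)
    if n_min <= k:
        warnings.warn(
            f"minority class ({n_min}) too small for {k}-NN ADASYN; "
            "duplicating minority samples instead",
            stacklevel=2,
        )
        idx = rng.integers(0, n_min, size=G)
        synth = Xm[idx]
    else:
        Xall = X.to_numpy(dtype=float)
        is_maj = (y != minority).to_numpy()
        nn_all = NearestNeighbors(n_neighbors=k + 1).fit(Xall)
        _, neigh = nn_all.kneighbors(Xm)
        r = is_maj[neigh[:, 1:]].mean(axis=1)  # majority share around each
        if r.sum() == 0:
            r = np.ones_like(r)
        g = np.floor(r / r.sum() * G).astype(int)
        # distribute the rounding remainder to the densest-majority samples
        for i in np.argsort(-r)[: G - g.sum()]:
            g[i] += 1
        k_min = min(k, n_min - 1)
        nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Xm)
        _, neigh_min = nn_min.kneighbors(Xm)
        synth_rows = []
        for i, gi in enumerate(g):
            for _ in range(gi):
                j = neigh_min[i, rng.integers(1, k_min + 1)]
                lam = rng.uniform()
                synth_rows.append(Xm[i] + lam * (Xm[j] - Xm[i]))
        synth = np.array(synth_rows) if synth_rows else np.empty((0, Xm.shape[1]))

    add = pd.DataFrame(synth, columns=X.columns)
    add[label_col] = minority
    return pd.concat([train, add], ignore_index=True)


def classification_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """ACC/SENS/SPEC/PREC/NPV/F1/AUC from pooled class-probability scores."""
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))

    def ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    return {
        "ACC": ratio(tp + tn, len(y_true)),
        "SENS": sens,
        "SPEC": ratio(tn, tn + fp),
        "PREC": prec,
        "NPV": ratio(tn, tn + fn),
        "F1SC": f1,
        "AUC": float(roc_auc_score(y_true, scores)),
    }


@dataclass
class EvaluationReport:
    """Pooled leave-one-out evaluation of one phenotype association."""

    metrics: dict[str, float]
    y_true: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    tuned_params: list[dict] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def _tune_rf(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    trees_grid,
    max_features_grid,
    inner_cv: int,
) -> dict:
    """Grid search over tree count and per-split feature count by inner CV."""
    p = X.shape[1]
    if max_features_grid is None:
        max_features_grid = range(2, p + 1) if p >= 2 else [1]
    best = None
    n_splits = min(inner_cv, int(np.bincount(y).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for n_trees in trees_grid:
        for mf in max_features_grid:
            accs = []
            for tr, te in skf.split(X, y):
                clf = RandomForestClassifier(
                    n_estimators=n_trees,
                    max_features=min(mf, p),
                    random_state=seed,
                )
                clf.fit(X[tr], y[tr])
                accs.append(clf.score(X[te], y[te]))
            score = float(np.mean(accs))
            if best is None or score > best[0]:
                best = (score, {"n_estimators": n_trees, "max_features": min(mf, p)})
    return best[1]


def evaluate_loocv(
    table: pd.DataFrame,
    seed: int,
    label_col: str = "label",
    pos_label=None,
    pca_variance: float = 0.95,
    balance: bool = True,
    tune: bool = False,
    trees_grid=TREES_GRID,
    max_features_grid=None,
    inner_cv: int = 10,
    n_estimators: int = 100,
) -> EvaluationReport:
    """Leave-one-out evaluation of the feature/phenotype association.

    For every held-out plaque the full training recipe is refitted on the
    remaining rows: standardisation + PCA (95% variance), ADASYN rebalancing
    of the minority class, and a Random Forest — either with the tuning grid
    (``tune=True``: 100–900 trees step 200, 2..p split features, inner
    10-fold CV) or with a fixed ``n_estimators``-tree forest.  Held-out class
    probabilities are pooled into the evaluation metrics.  ``pos_label``
    names the clinically positive class; it defaults to the
    lexicographically last label.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 samples")
    y_raw = table[label_col]
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if pos_label is None:
        pos_label = classes[-1]
    y_all = (y_raw == pos_label).astype(int).to_numpy()
    X_all = table.drop(columns=[label_col])

    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=len(table))

    scores = np.empty(len(table))
    tuned: list[dict] = []
    for i in range(len(table)):
        fs = int(fold_seeds[i])
        mask = np.ones(len(table), dtype=bool)
        mask[i] = False
        X_tr = X_all.iloc[mask]
        y_tr = y_all[mask]

        scaler = StandardScaler().fit(X_tr.to_numpy())
        Z_tr = scaler.transform(X_tr.to_numpy())
        pca = PCA(svd_solver="full").fit(Z_tr)
        n = int(
            np.searchsorted(np.cumsum(pca.explained_variance_ratio_), pca_variance)
            + 1
        )
        n = min(n, pca.n_components_)
        P_tr = pca.transform(Z_tr)[:, :n]
        P_te = pca.transform(scaler.transform(X_all.iloc[[i]].to_numpy()))[:, :n]

        train_df = pd.DataFrame(P_tr)
        train_df[label_col] = y_tr
        if balance:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_df = balance_training(train_df, seed=fs, label_col=label_col)
        Xb = train_df.drop(columns=[label_col]).to_numpy()
        yb = train_df[label_col].to_numpy().astype(int)

        if tune:
            params = _tune_rf(Xb, yb, fs, trees_grid, max_features_grid, inner_cv)
        else:
            params = {"n_estimators": n_estimators}
        tuned.append(params)
        clf = RandomForestClassifier(random_state=fs, **params)
        clf.fit(Xb, yb)
        proba = clf.predict_proba(P_te)[0]
        scores[i] = proba[list(clf.classes_).index(1)] if 1 in clf.classes_ else 0.0

    metrics = classification_metrics(y_all, scores)
    return EvaluationReport(
        metrics=metrics,
        y_true=y_all,
        scores=scores,
        predictions=(scores >= 0.5).astype(int),
        tuned_params=tuned,
    )


def wilcoxon_compare(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one feature.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).  Fully tied data
    carry no rank information: p = 1 with a warning.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def wilcoxon_table(
    group_a: pd.DataFrame, group_b: pd.DataFrame, alpha: float = SIGNIFICANCE_LEVEL
) -> pd.DataFrame:
    """Per-feature rank-sum p-values and significance flags (p <= alpha)."""
    rows = []
    for col in group_a.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_compare(group_a[col], group_b[col])
        rows.append({"feature": col, "p_value": p, "significant": p <= alpha})
    return pd.DataFrame(rows).set_index("feature")


def variability_experiment(
    seq,
    contours: dict,
    offsets=(0.0, 0.5, 1.0, 1.5, 2.0),
    cfg=None,
    n_trim: int = 25,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Sensitivity of the phase shifts to contour placement.

    Emulates inter-/intra-observer annotation variability: all four contours
    are displaced radially by each offset (0–2 px, sub-pixel included), the
    full pipeline is re-run, and the per-pair d_max distributions of each
    cross-correlation type are compared with the original annotation by
    rank-sum test.  Returns a table indexed by offset with a p-value column
    per type.
    """
    from .pipeline import extract_plaque_features
    from .tracking import displace_contour

    original = extract_plaque_features(seq, contours, cfg=cfg, n_trim=n_trim)
    rows = []
    for off in offsets:
        if off == 0.0:
            fv = original
        else:
            moved = {k: displace_contour(c, off) for k, c in contours.items()}
            fv = extract_plaque_features(seq, moved, cfg=cfg, n_trim=n_trim)
        row: dict = {"offset": off}
        for cc in CC_TYPES:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"p_{cc}"] = wilcoxon_compare(
                    original.pair_lags[cc], fv.pair_lags[cc]
                )
        row["any_significant"] = any(row[f"p_{cc}"] <= alpha for cc in CC_TYPES)
        rows.append(row)
    return pd.DataFrame(rows).set_index("offset")
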