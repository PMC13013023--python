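"""Seven-classifier comparison on junction feature tables.

Two labeled cohorts of per-junction features are balanced by cell count,
split into train/test *by cell* (all of a cell's junctions follow its
assignment, so no junction of a test cell ever leaks into training),
and classified with seven standard methods — logistic regression (LR),
radial-kernel support vector machine (SVM), k-nearest neighbors (KNN),
random forest (RF), decision tree (DT), Gaussian naive Bayes (Bayes) and
a small multilayer perceptron (NN) — in the 2-feature space
(beta_mean, beta_diff) and the 3-feature space adding rel_leaf_number.

Performance is the ROC AUC over per-junction scores with a 95% DeLong
confidence interval, plus a per-cell ("image") accuracy where each test
cell is assigned the majority hard label of its junctions.

The model fits stand on scikit-learn; the AUC and its DeLong variance are
computed here (and cross-checked in the test suite against exhaustive
pair counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from scipy.spatial.distance import pdist

from .scale_features import FEATURES_2D, FEATURES_3D

METHODS = ("LR", "SVM", "KNN", "RF", "DT", "Bayes", "NN")
MODES = ("2d", "3d")

__all__ = [
    "METHODS",
    "MODES",
    "SplitPlan",
    "ClassifierResult",
    "balance_cohort",
    "split_by_image",
    "fit_predict",
    "roc_auc_ci",
    "image_accuracy",
    "run_comparison",
    "report_table",
]


@dataclass(frozen=True)
class SplitPlan:
    """Cell-wise train/test assignment, stratified by class."""

    train_cells: frozenset[str]
    test_cells: frozenset[str]
    train_fraction: float
    seed: int


@dataclass
class ClassifierResult:
    method: str
    feature_mode: str
    scores: np.ndarray          # per-test-row P(class 1)
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    image_accuracy: tuple[int, int]
    roc_points: np.ndarray      # (fpr, tpr) rows
    knn_k: int | None
    seed: int
    settings: dict = field(default_factory=dict)


def balance_cohort(
    tables: dict[str, pd.DataFrame], seed: int
) -> dict[str, pd.DataFrame]:
    """Subsample the larger class's *cells* to match the smaller one.

    Per-junction counts stay unequal (cells contribute variable numbers of
    junctions); only the cell counts are equalized. Deterministic given
    the seed.
    """
    if len(tables) != 2:
        raise ValueError(f"expected exactly two classes, got {list(tables)}")
    counts = {}
    for label, tab in tables.items():
        cells = sorted(tab["cell_id"].unique())
        if not cells:
            raise ValueError(f"class {label!r} has no cells")
        counts[label] = cells
    n_min = min(len(c) for c in counts.values())
    rng = np.random.default_rng(seed)
    out = {}
    for label, cells in counts.items():
        if len(cells) > n_min:
            keep = set(rng.choice(cells, size=n_min, replace=False))
            out[label] = tables[label][tables[label]["cell_id"].isin(keep)].reset_index(drop=True)
        else:
            out[label] = tables[label]
    return out


def split_by_image(
    tables: dict[str, pd.DataFrame], train_fraction: float = 0.75, seed: int = 0
) -> SplitPlan:
    """Assign whole cells to train/test, stratified by class.

    round(train_fraction * n) cells per class go to training, clamped so
    at least one cell of each class lands on each side.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    for label in sorted(tables):
        cells = sorted(tables[label]["cell_id"].unique())
        if len(cells) < 2:
            raise ValueError(f"class {label!r} needs >= 2 cells to split")
        perm = rng.permutation(len(cells))
        n_train = int(round(train_fraction * len(cells)))
        n_train = min(max(n_train, 1), len(cells) - 1)
        train.update(cells[i] for i in perm[:n_train])
        test.update(cells[i] for i in perm[n_train:])
    return SplitPlan(frozenset(train), frozenset(test), train_fraction, seed)


def _feature_columns(mode: str) -> list[str]:
    if mode == "2d":
        return list(FEATURES_2D)
    if mode == "3d":
        return list(FEATURES_3D)
    raise ValueError(f"feature_mode must be '2d' or '3d', got {mode!r}")


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF width 1/(2 * median pairwise distance^2) on (a subsample of) X."""
    if len(X) > 400:
        X = X[rng.choice(len(X), size=400, replace=False)]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


def _make_estimator(method: str, X_train: np.ndarray, seed: int) -> tuple[object, dict]:
    settings: dict = {}
    if method == "LR":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", LogisticRegression(max_iter=1000))])
    elif method == "SVM":
        rng = np.random.default_rng(seed)
        Xs = StandardScaler().fit_transform(X_train)
        gamma = _median_heuristic_gamma(Xs, rng)
        settings["svm_gamma"] = gamma
        settings["svm_C"] = 1.0
        # sigmoid-calibrated SVC: radial kernel with probability-style scores
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", CalibratedClassifierCV(
                            SVC(kernel="rbf", C=1.0, gamma=gamma,
                                random_state=seed),
                            ensemble=False))])
    elif method == "RF":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif method == "DT":
        est = DecisionTreeClassifier(random_state=seed)
    elif method == "Bayes":
        est = GaussianNB()
    elif method == "NN":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", MLPClassifier(hidden_layer_sizes=(8,),
                                              activation="logistic",
                                              max_iter=10_000,
                                              random_state=seed))])
        settings["nn_hidden"] = (8,)
    elif method == "KNN":
        est = None  # built in fit_predict after k selection
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return est, settings


def _knn_pipeline(k: int) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("clf", KNeighborsClassifier(n_neighbors=k))])


def _select_knn_k(train: pd.DataFrame, cols: list[str], y: np.ndarray, seed: int) -> int:
    """Scan odd k in 1..51 maximizing AUC on a seeded 25% cell-wise validation split."""
    rng = np.random.default_rng(seed)
    cells = sorted(train["cell_id"].unique())
    perm = rng.permutation(len(cells))
    n_val = max(1, int(round(0.25 * len(cells))))
    val_cells = {cells[i] for i in perm[:n_val]}
    val_mask = train["cell_id"].isin(val_cells).to_numpy()
    y_fit, y_val = y[~val_mask], y[val_mask]
    if len(set(y_fit)) < 2 or len(set(y_val)) < 2:
        return 5  # degenerate split; small default
    X_fit = train.loc[~val_mask, cols].to_numpy()
    X_val = train.loc[val_mask, cols].to_numpy()
    best_k, best_auc = 1, -np.inf
    for k in range(1, 52, 2):
        if k > len(X_fit):
            break
        pipe = _knn_pipeline(k)
        pipe.fit(X_fit, y_fit)
        s = pipe.predict_proba(X_val)[:, 1]
        auc, *_ = roc_auc_ci(s, y_val)
        if auc > best_auc:
            best_k, best_auc = k, auc
    return best_k


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    method: str,
    feature_mode: str = "3d",
    seed: int = 0,
    positive_label: str | None = None,
) -> ClassifierResult:
    """Train one classifier and score the test junctions.

    Returns per-test-row P(class 1) plus AUC with DeLong 95% CI and
    per-cell image accuracy. Class 1 is ``positive_label`` (default: the
    lexicographically larger of the two labels).
    """
    cols = _feature_columns(feature_mode)
    for df, name in ((train, "train"), (test, "test")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks feature columns {missing}")
        if df[cols].isna().any().any():
            raise ValueError(f"{name} table contains NaN features")
    labels = sorted(set(train["label"]))
    if len(labels) != 2:
        raise ValueError(f"training set must contain exactly 2 classes, got {labels}")
    if positive_label is None:
        positive_label = labels[1]
    y_train = (train["label"] == positive_label).to_numpy().astype(int)
    y_test = (test["label"] == positive_label).to_numpy().astype(int)
    X_train = train[cols].to_numpy()
    X_test = test[cols].to_numpy()

    knn_k = None
    est, settings = _make_estimator(method, X_train, seed)
    if method == "KNN":
        knn_k = _select_knn_k(train, cols, y_train, seed)
        est = _knn_pipeline(knn_k)
        settings["knn_k"] = knn_k
    est.fit(X_train, y_train)
    scores = est.predict_proba(X_test)[:, 1]

    auc, lo, hi, roc = roc_auc_ci(scores, y_test)
    acc = image_accuracy(scores, test, positive_label)
    return ClassifierResult(
        method=method,
        feature_mode=feature_mode,
        scores=scores,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        image_accuracy=acc,
        roc_points=roc,
        knn_k=knn_k,
        seed=seed,
        settings=settings,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def roc_auc_ci(scores, labels) -> tuple[float, float, float, np.ndarray]:
    """AUC with DeLong 95% confidence interval and ROC curve points.

    The AUC is the normalized Mann-Whitney U statistic (ties count 1/2);
    the variance is DeLong's structural-components estimate, giving
    ``auc ± 1.96 * sqrt(var)`` clipped to [0, 1]. Degenerate variance
    (e.g. perfect separation) collapses the interval onto the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(scores) < 2 or len(set(labels.tolist())) < 2:
        raise ValueError("need >= 2 rows with both classes present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n            # structural components of the positives
    v10 = 1.0 - (tz[m:] - ty) / m      # and of the negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    lo = float(max(0.0, auc - half))
    hi = float(min(1.0, auc + half))

    # ROC points at every distinct threshold
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    s_sorted = scores[order]
    keep = np.r_[np.where(np.diff(s_sorted))[0], len(y) - 1]
    tpr = np.r_[0.0, tps[keep] / m]
    fpr = np.r_[0.0, fps[keep] / n]
    roc = np.column_stack([fpr, tpr])
    return float(auc), lo, hi, roc


def image_accuracy(
    scores: np.ndarray, test: pd.DataFrame, positive_label: str
) -> tuple[int, int]:
    """Per-cell majority-vote accuracy over hard junction labels.

    Each junction is hard-labeled by score > 0.5; a cell is called class 1
    when the mean of its junction labels exceeds 0.5 (an exact 0.5 tie is
    called class 0). Returns (n_correct, n_cells), the "k/n images" form.
    """
    hard = (np.asarray(scores) > 0.5).astype(float)
    df = pd.DataFrame({
        "cell_id": test["cell_id"].to_numpy(),
        "hard": hard,
        "true": (test["label"] == positive_label).to_numpy().astype(int),
    })
    per_cell = df.groupby("cell_id").agg(mean_pred=("hard", "mean"), true=("true", "first"))
    pred = (per_cell["mean_pred"] > 0.5).astype(int)
    n_correct = int((pred == per_cell["true"]).sum())
    return n_correct, len(per_cell)


def run_comparison(
    tables: dict[str, pd.DataFrame],
    train_fraction: float = 0.75,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    modes: tuple[str, ...] = MODES,
) -> dict:
    """Full benchmark: balance, split by cell, fit every method x mode.

    Returns a report dict with the split plan, all settings and one
    :class:`ClassifierResult` per (method, mode). Deterministic given the
    seed; rerunning with the same inputs reproduces the AUC table.
    """
    balanced = balance_cohort(tables, seed=seed)
    plan = split_by_image(balanced, train_fraction=train_fraction, seed=seed)
    all_rows = pd.concat(balanced.values(), ignore_index=True)
    train = all_rows[all_rows["cell_id"].isin(plan.train_cells)].reset_index(drop=True)
    test = all_rows[all_rows["cell_id"].isin(plan.test_cells)].reset_index(drop=True)
    labels = sorted(balanced)
    results: list[ClassifierResult] = []
    for mode in modes:
        for method in methods:
            results.append(
                fit_predict(train, test, method, feature_mode=mode, seed=seed,
                            positive_label=labels[1])
            )
    return {
        "split": plan,
        "positive_label": labels[1],
        "labels": labels,
        "train_fraction": train_fraction,
        "seed": seed,
        "n_train_rows": len(train),
        "n_test_rows": len(test),
        "results": results,
    }


def report_table(report: dict) -> pd.DataFrame:
    """AUC table (one row per method x mode) from a run_comparison report."""
    rows = []
    for r in report["results"]:
        n_correct, n_images = r.image_accuracy
        rows.append({
            "method": r.method,
            "feature_mode": r.feature_mode,
            "auc": r.auc,
            "auc_ci_low": r.auc_ci_low,
            "auc_ci_high": r.auc_ci_high,
            "image_accuracy": f"{n_correct}/{n_images}",
            "knn_k": r.knn_k,
        })
    return pd.DataFrame(rows)
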