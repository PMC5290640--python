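"""Feature-rank aggregation, classifier training and evaluation.

Feature selection follows the rank-aggregation recipe: four single-attribute
evaluators — OneR, chi-squared, ReliefF and gain ratio — score every retained
feature on the training part of each of 10 cross-validation folds; scores
become ranks (1 = best) and the ranks are averaged over evaluators × folds.
Correlation-based feature selection (CFS) returns a subset rather than a
ranking and is reported separately. The evaluators are implemented natively:
angles are first *untangled* — expressed as the circular difference from the
feature's circular mean — so that equal-width discretization does not split
a rotamer population across the ±180° seam.

Classifiers (random forest, naive Bayes, neural network, SVM) are sklearn
estimators fit on the unit-circle (sin, cos) encoding with per-feature
circular-mean imputation learned from the training data. Imputation is what
lets the ML path classify 100% of chains while the geometric baselines must
abstain on disordered structures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, encode_circular

__all__ = [
    "RankedFeatures",
    "TrainedModel",
    "EvaluationReport",
    "SplitSpec",
    "SINGLE_ATTRIBUTE_EVALUATORS",
    "rank_features",
    "cfs_subset",
    "train",
    "predict",
    "evaluate",
    "grid_search",
    "incremental_feature_accuracy",
    "learning_curve",
    "DEFAULT_RF_GRID",
]

POSITIVE = "active"
N_BINS = 10  # equal-width discretization of untangled angles

SINGLE_ATTRIBUTE_EVALUATORS = ("oner", "chi_squared", "relieff", "gain_ratio")

DEFAULT_RF_GRID = {
    "n_estimators": [50, 100, 250, 500],
    "max_features": ["sqrt", "log2", 0.1],
}


# ---------------------------------------------------------------------------
# data preparation


def _check_labels(labels: pd.Series) -> np.ndarray:
    y = (labels == POSITIVE).to_numpy()
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    return y.astype(int)


def _untangle(values: np.ndarray) -> np.ndarray:
    """Angles re-expressed as signed circular deviation from the circular mean.

    Input (n, d) degrees with NaN for missing; output same shape, observed
    cells in (-180, 180] centered so that the dominant population sits near 0
    and no contiguous population straddles the seam.
    """
    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        rad = np.radians(col[obs])
        mean = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))
        d = col[obs] - mean
        d = np.mod(d + 180.0, 360.0) - 180.0
        d[d == -180.0] = 180.0
        out[obs, j] = d
    return out


def _discretize(col: np.ndarray) -> np.ndarray:
    """10 equal-width bins over (-180, 180]; NaN-safe (missing -> -1)."""
    bins = np.full(col.shape, -1, dtype=int)
    obs = ~np.isnan(col)
    idx = np.floor((col[obs] + 180.0) / (360.0 / N_BINS)).astype(int)
    bins[obs] = np.clip(idx, 0, N_BINS - 1)
    return bins


# ---------------------------------------------------------------------------
# single-attribute evaluators (higher score = more informative)


def _score_oner(x: np.ndarray, y: np.ndarray) -> float:
    """Accuracy of the best one-feature rule (majority class per bin)."""
    bins = _discretize(x)
    obs = bins >= 0
    if not obs.any():
        return 0.0
    correct = 0
    for b in np.unique(bins[obs]):
        yb = y[bins == b]
        correct += max((yb == 1).sum(), (yb == 0).sum())
    return correct / obs.sum()


def _score_chi_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-squared statistic of the binned feature vs the class."""
    bins = _discretize(x)
    obs = bins >= 0
    if not obs.any():
        return 0.0
    b, yy = bins[obs], y[obs]
    stat = 0.0
    n = len(yy)
    n1 = yy.sum()
    for val in np.unique(b):
        m = b == val
        nb = m.sum()
        for cls, ncls in ((1, n1), (0, n - n1)):
            expected = nb * ncls / n
            if expected > 0:
                observed = ((yy[m] == cls)).sum()
                stat += (observed - expected) ** 2 / expected
    return stat


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _score_gain_ratio(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    obs = bins >= 0
    if not obs.any():
        return 0.0
    b, yy = bins[obs], y[obs]
    n = len(yy)
    h_class = _entropy(np.bincount(yy, minlength=2).astype(float))
    cond = 0.0
    split_counts = []
    for val in np.unique(b):
        m = b == val
        split_counts.append(m.sum())
        cond += m.sum() / n * _entropy(np.bincount(yy[m], minlength=2).astype(float))
    split_info = _entropy(np.asarray(split_counts, dtype=float))
    if split_info <= 0:
        return 0.0
    return (h_class - cond) / split_info


def _circular_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise circular distance in [0, 1] between untangled angles."""
    d = np.abs(a - b)
    return np.minimum(d, 360.0 - d) / 180.0


def _score_relieff_all(x: np.ndarray, y: np.ndarray, k: int = 10,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """ReliefF weights for all features at once (k neighbors, all instances).

    Distances use the circular metric on untangled angles; missing values
    are imputed at 0 (the circular-mean direction) for neighbor search and
    weight updates alike.
    """
    xi = np.where(np.isnan(x), 0.0, x)
    n, d = xi.shape
    k = min(k, n - 1)
    # pairwise distance accumulated feature-by-feature to bound memory
    dist = np.zeros((n, n))
    for j in range(d):
        col = xi[:, j]
        dist += _circular_diff(col[:, None], col[None, :])
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(d)
    p1 = y.mean()
    priors = {1: p1, 0: 1 - p1}
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        same = y[order[i]] == y[i]
        hits = order[i][same][:k]
        misses = order[i][~same][:k]
        if len(hits) == 0 or len(misses) == 0:
            continue
        diff_hits = _circular_diff(xi[i][None, :], xi[hits]).mean(axis=0)
        diff_miss = _circular_diff(xi[i][None, :], xi[misses]).mean(axis=0)
        other = 1 - y[i]
        w += -diff_hits / n + (priors[other] / (1 - priors[y[i]])) * diff_miss / n
    return w


# ---------------------------------------------------------------------------
# rank aggregation


@dataclass
class RankedFeatures:
    """Features ordered by average rank over evaluators x folds."""

    table: pd.DataFrame  # index: feature name; columns: average_rank + per-run ranks

    @property
    def names(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = best score; ties broken by feature position (canonical order)."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=float)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


_EVALUATORS = {
    "oner": _score_oner,
    "chi_squared": _score_chi_squared,
    "gain_ratio": _score_gain_ratio,
}


def rank_features(matrix: FeatureMatrix, labels: pd.Series | None = None,
                  evaluators: Sequence[str] = SINGLE_ATTRIBUTE_EVALUATORS,
                  folds: int = 10, seed: int = 0) -> RankedFeatures:
    """Average feature ranks over single-attribute evaluators and CV folds."""
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels are required for feature ranking")
    labels = labels.loc[matrix.values.index]
    y_all = _check_labels(labels)
    unknown = set(evaluators) - set(SINGLE_ATTRIBUTE_EVALUATORS)
    if unknown:
        raise ValueError(f"unknown evaluators: {sorted(unknown)}")

    names = [f.name for f in matrix.features]
    raw = matrix.values.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    rank_cols = {}
    for fold_i, (tr_idx, _) in enumerate(skf.split(raw, y_all)):
        x = _untangle(raw[tr_idx])
        y = y_all[tr_idx]
        for ev in evaluators:
            if ev == "relieff":
                scores = _score_relieff_all(x, y)
            else:
                fn = _EVALUATORS[ev]
                scores = np.array([fn(x[:, j], y) for j in range(x.shape[1])])
            rank_cols[f"{ev}_fold{fold_i}"] = _scores_to_ranks(scores)

    table = pd.DataFrame(rank_cols, index=names)
    table.insert(0, "average_rank", table.mean(axis=1))
    # ascending average rank; ties resolved by canonical feature order
    table["_pos"] = np.arange(len(names))
    table = table.sort_values(["average_rank", "_pos"]).drop(columns="_pos")
    return RankedFeatures(table=table)


def cfs_subset(matrix: FeatureMatrix, labels: pd.Series | None = None,
               seed: int = 0) -> list[str]:
    """Correlation-based feature selection: greedy forward search on the
    CFS merit k·r_cf / sqrt(k + k(k-1)·r_ff), with absolute Pearson
    correlations on imputed untangled angles. Stops when no addition strictly
    improves the merit."""
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels are required for CFS")
    labels = labels.loc[matrix.values.index]
    y = _check_labels(labels).astype(float)
    names = [f.name for f in matrix.features]
    x = _untangle(matrix.values.to_numpy(dtype=float))
    x = np.where(np.isnan(x), 0.0, x)

    def safe_corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))

    r_cf = np.array([safe_corr(x[:, j], y) for j in range(x.shape[1])])
    # correlations below the ~2-sigma sampling noise floor are treated as zero,
    # so chance correlations in uninformative features cannot grow the subset
    r_cf[r_cf < 2.0 / math.sqrt(len(y))] = 0.0
    d = x.shape[1]
    r_ff = np.eye(d)

    def feat_corr(i, j):
        if r_ff[i, j] == 0 and i != j:
            r_ff[i, j] = r_ff[j, i] = safe_corr(x[:, i], x[:, j])
        return r_ff[i, j]

    selected: list[int] = []
    merit = 0.0
    while True:
        best_j, best_merit = None, merit
        for j in range(d):
            if j in selected:
                continue
            cand = selected + [j]
            k = len(cand)
            mean_cf = r_cf[cand].mean()
            if k == 1:
                mean_ff = 0.0
            else:
                pair_sum = sum(feat_corr(i1, i2) for a, i1 in enumerate(cand)
                               for i2 in cand[a + 1:])
                mean_ff = pair_sum / (k * (k - 1) / 2)
            m = k * mean_cf / math.sqrt(k + k * (k - 1) * mean_ff)
            if m > best_merit + 1e-12:
                best_merit, best_j = m, j
        if best_j is None:
            break
        selected.append(best_j)
        merit = best_merit
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# classifier training / prediction


@dataclass
class TrainedModel:
    algorithm: str
    hyperparameters: dict
    feature_names: list[str]
    imputation_stats: dict[str, tuple[float, float]]
    estimator: object
    seed: int
    format_version: int = 1

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError("archive does not contain a TrainedModel")
        return model


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    roc: tuple[np.ndarray, np.ndarray]
    auc: float
    confusion: dict[str, int]  # tp, fp, tn, fn (positive = active)
    coverage: float = 1.0


def _make_estimator(algorithm: str, hyperparameters: dict, seed: int):
    hp = dict(hyperparameters)
    if algorithm == "random_forest":
        hp.setdefault("n_estimators", 250)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "naive_bayes":
        return GaussianNB(**hp)
    if algorithm == "neural_network":
        hp.setdefault("hidden_layer_sizes", (50,))
        hp.setdefault("max_iter", 2000)
        return MLPClassifier(random_state=seed, **hp)
    if algorithm == "svm":
        # scores come from the decision function via a logistic map
        return SVC(random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _encode_for_model(matrix: FeatureMatrix, feature_names: Sequence[str],
                      imputation_stats=None):
    missing = [n for n in feature_names if n not in matrix.values.columns]
    if missing:
        raise KeyError(f"matrix lacks model features: {missing[:5]}")
    feats = [matrix.feature_by_name(n) for n in feature_names]
    return encode_circular(matrix, feats, imputation_stats=imputation_stats)


def train(matrix: FeatureMatrix, labels: pd.Series | None = None,
          algorithm: str = "random_forest", hyperparameters: dict | None = None,
          selected_features: Sequence[str] | None = None, seed: int = 0) -> TrainedModel:
    """Fit a classifier on the circular encoding of the selected features."""
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels are required for training")
    labels = labels.loc[matrix.values.index]
    y = _check_labels(labels)
    names = list(selected_features) if selected_features is not None else [
        f.name for f in matrix.features
    ]
    enc = _encode_for_model(matrix, names)
    est = _make_estimator(algorithm, hyperparameters or {}, seed)
    est.fit(enc.data.to_numpy(), y)
    return TrainedModel(
        algorithm=algorithm,
        hyperparameters=hyperparameters or {},
        feature_names=names,
        imputation_stats=enc.imputation_stats,
        estimator=est,
        seed=seed,
    )


def predict(model: TrainedModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-row predicted state and active-class score; never abstains.

    Rows whose model features are all imputed still get a prediction (that is
    the point of imputation) but are flagged ``low_information``.
    """
    enc = _encode_for_model(matrix, model.feature_names, model.imputation_stats)
    x = enc.data.to_numpy()
    est = model.estimator
    if hasattr(est, "predict_proba"):
        score = est.predict_proba(x)[:, list(est.classes_).index(1)]
    else:
        raw = est.decision_function(x)
        score = 1.0 / (1.0 + np.exp(-raw))
    label = np.where(score >= 0.5, POSITIVE, "inactive")
    low_info = enc.imputed.all(axis=1).to_numpy()
    return pd.DataFrame(
        {"predicted_state": label, "score": score, "low_information": low_info},
        index=matrix.values.index,
    )


def evaluate(model: TrainedModel, matrix: FeatureMatrix,
             labels: pd.Series) -> EvaluationReport:
    labels = labels.loc[matrix.values.index]
    y = (labels == POSITIVE).to_numpy().astype(int)
    pred = predict(model, matrix)
    yhat = (pred["predicted_state"] == POSITIVE).to_numpy().astype(int)
    tp = int(((y == 1) & (yhat == 1)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = roc_curve(y, pred["score"])
        roc_auc = float(sk_auc(fpr, tpr))
    else:
        fpr = tpr = np.array([])
        roc_auc = float("nan")
    return EvaluationReport(
        accuracy=(tp + tn) / len(y),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
        roc=(fpr, tpr),
        auc=roc_auc,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


# ---------------------------------------------------------------------------
# splits, grid search, curves


@dataclass
class SplitSpec:
    """Balanced training split: n per class, remainder is the validation set."""

    n_train_per_class: int = 500
    seed: int = 0
    stratified: bool = True

    def split(self, labels: pd.Series) -> tuple[pd.Index, pd.Index]:
        rng = np.random.default_rng(self.seed)
        train_keys = []
        for cls in (POSITIVE, "inactive"):
            keys = labels.index[labels == cls]
            if len(keys) < self.n_train_per_class:
                raise ValueError(
                    f"class {cls!r} has {len(keys)} rows < {self.n_train_per_class}"
                )
            chosen = rng.choice(len(keys), size=self.n_train_per_class, replace=False)
            train_keys.extend(keys[sorted(chosen)])
        train_idx = pd.Index(train_keys)
        test_idx = labels.index.difference(train_idx, sort=False)
        return train_idx, test_idx


def grid_search(matrix: FeatureMatrix, labels: pd.Series | None,
                algorithm: str = "random_forest", grid: dict | None = None,
                folds: int = 10, seed: int = 0,
                selected_features: Sequence[str] | None = None):
    """Exhaustive CV over a hyperparameter grid; best by mean accuracy.

    Ties prefer fewer trees (when the grid has ``n_estimators``), then the
    lexicographically smallest parameter setting.
    """
    if labels is None:
        labels = matrix.labels
    labels = labels.loc[matrix.values.index]
    y = _check_labels(labels)
    if grid is None:
        grid = DEFAULT_RF_GRID if algorithm == "random_forest" else {}
    if not grid:
        raise ValueError("empty hyperparameter grid")
    names = list(selected_features) if selected_features is not None else [
        f.name for f in matrix.features
    ]
    enc = _encode_for_model(matrix, names)
    x = enc.data.to_numpy()

    keys = sorted(grid)
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))

    rows = []
    results = []
    for hp in points:
        accs = []
        for fold_i, (tr, te) in enumerate(splits):
            est = _make_estimator(algorithm, hp, seed)
            est.fit(x[tr], y[tr])
            acc = float((est.predict(x[te]) == y[te]).mean())
            accs.append(acc)
            rows.append({**hp, "fold": fold_i, "accuracy": acc})
        results.append((hp, float(np.mean(accs))))

    def tie_key(item):
        hp, acc = item
        trees = hp.get("n_estimators", 0)
        return (-acc, trees, sorted((k, str(v)) for k, v in hp.items()))

    best_hp, best_acc = min(results, key=tie_key)
    return best_hp, pd.DataFrame(rows)


def incremental_feature_accuracy(ranked: RankedFeatures, matrix: FeatureMatrix,
                                 labels: pd.Series | None = None, k_max: int = 20,
                                 algorithm: str = "random_forest", seed: int = 0,
                                 train_fraction: float = 0.5) -> pd.DataFrame:
    """Accuracy/precision/recall as the top-k ranked features are added.

    One stratified train/hold-out split (fixed by ``seed``) is reused across
    k so the curve reflects feature content, not split variance.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > len(ranked.names):
        raise ValueError("k_max exceeds the number of ranked features")
    if labels is None:
        labels = matrix.labels
    labels = labels.loc[matrix.values.index]
    y = _check_labels(labels)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_fraction, stratify=y,
                              random_state=seed)
    m_tr = FeatureMatrix(matrix.features, matrix.values.iloc[tr])
    m_te = FeatureMatrix(matrix.features, matrix.values.iloc[te])
    lab_tr, lab_te = labels.iloc[tr], labels.iloc[te]

    rows = []
    for k in range(1, k_max + 1):
        names = ranked.top(k)
        model = train(m_tr, lab_tr, algorithm, selected_features=names, seed=seed)
        rep_tr = evaluate(model, m_tr, lab_tr)
        rep_te = evaluate(model, m_te, lab_te)
        rows.append({
            "k": k,
            "feature_added": names[-1],
            "train_accuracy": rep_tr.accuracy,
            "test_accuracy": rep_te.accuracy,
            "test_precision": rep_te.precision,
            "test_recall": rep_te.recall,
        })
    return pd.DataFrame(rows).set_index("k")


def learning_curve(matrix: FeatureMatrix, labels: pd.Series | None = None,
                   train_sizes: Sequence[int] = (10, 25, 50, 100, 200),
                   algorithm: str = "random_forest", repeats: int = 3,
                   seed: int = 0,
                   selected_features: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean +/- sd hold-out accuracy at increasing training-set sizes."""
    if labels is None:
        labels = matrix.labels
    labels = labels.loc[matrix.values.index]
    y = _check_labels(labels)
    n = len(y)
    if max(train_sizes) >= n:
        raise ValueError("largest training size leaves nothing to evaluate")
    feats = matrix.features if selected_features is None else [
        matrix.feature_by_name(nm) for nm in selected_features
    ]
    values = matrix.values[[f.name for f in feats]]
    rows = []
    for size in train_sizes:
        accs = []
        for rep in range(repeats):
            rs = seed * 1000 + rep
            tr, te = train_test_split(np.arange(n), train_size=size, stratify=y,
                                      random_state=rs)
            m_tr = FeatureMatrix(feats, values.iloc[tr])
            m_te = FeatureMatrix(feats, values.iloc[te])
            model = train(m_tr, labels.iloc[tr], algorithm, seed=seed)
            accs.append(evaluate(model, m_te, labels.iloc[te]).accuracy)
        rows.append({"train_size": size, "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0})
    return pd.DataFrame(rows).set_index("train_size")
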