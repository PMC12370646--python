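"""Ordinal item-score modeling: balanced splitting, level merging,
Gain-ranked feature selection, SMOTE-in-LOOCV model search and the LASSO
subscale regression.

The pipeline per clinical item is:

1. split the cohort 80/20 with demographic balance (age, sex, disease
   duration) and every observed score level present in training;
2. merge sparse score levels (training count <= 5) into the adjacent
   lower level, applying the same map to the test set;
3. rank all constructed features by total Gain of a reference
   gradient-boosted fit on the full training set;
4. for every (top-K, hyperparameter, algorithm) configuration run
   leave-one-out cross-validation with minority-class oversampling (SMOTE)
   applied only inside each fold's training subset — the left-out
   participant never contributes to oversampling;
5. select the configuration with the highest LOOCV weighted F1 (ties:
   higher exact accuracy, then smaller K, then gradient boosting before
   the RBF max-margin classifier) and refit it on the whole training set
   with the same oversampling.

The subscale (sum of the five item scores) is predicted by L1-penalised
linear regression with the penalty chosen at minimum mean 10-fold
cross-validated error; only non-zero-coefficient features are reported.

SMOTE is implemented here directly (interpolation between within-class
nearest neighbours, k = 5) with the standard small-class fallbacks: k is
reduced to m - 1 for a class of m < k + 1 members and a singleton class
is duplicated.
"""

from __future__ import annotations

import dataclasses
import itertools

import joblib
import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import metrics as _metrics
from .features import sensors_of_constructed
from .synth import ITEMS

#: hyperparameter grids of the two candidate algorithms
GBT_GRID = {
    "learning_rate": (0.05, 0.1),
    "max_depth": (3, 4),
    "gamma": (0.1, 0.2),
    "reg_lambda": (3, 4, 5),
}
SVM_GRID = {"gamma": (0.001, 0.01, 0.1, 1), "C": (0.1, 1, 10, 100)}

#: selected-feature counts searched: top 5, 10, ..., 50 by Gain
K_GRID = tuple(range(5, 55, 5))

#: reference hyperparameters of the ranking fit (lowest grid corner)
RANKING_PARAMS = {"learning_rate": 0.1, "max_depth": 3, "gamma": 0.1, "reg_lambda": 3}

N_ESTIMATORS = 100

GBT = "gradient_boosted_trees"
RBF = "rbf_max_margin"


def expand_grid(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------


class SplitError(RuntimeError):
    pass


def split_cohort(
    labels: pd.DataFrame,
    train_frac: float = 0.8,
    max_tries: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    items: tuple[str, ...] = ITEMS,
) -> tuple[list[str], list[str]]:
    """Repeated random 80/20 split until balance constraints hold.

    Constraints: (a) every score level observed in the cohort appears in
    the training set for every item; (b) no demographic imbalance —
    Mann-Whitney p > alpha for age and disease duration, chi-square
    p > alpha for sex.  Deterministic given ``seed``; raises
    :class:`SplitError` with the failing constraint when ``max_tries`` is
    exhausted.
    """
    n = len(labels)
    if n < 10:
        raise ValueError("need at least 10 participants to split")
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    ids = labels["participant"].to_numpy()
    last_failure = "no attempt made"
    for _ in range(max_tries):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        ok = True
        for item in items:
            scores = labels[item].to_numpy()
            if set(scores) - set(scores[tr]):
                last_failure = f"{item}: score level missing from training"
                ok = False
                break
        if not ok:
            continue
        for col in ("age", "pd_duration"):
            p = _stats.mannwhitneyu(
                labels[col].to_numpy()[tr], labels[col].to_numpy()[te]
            ).pvalue
            if p <= alpha:
                last_failure = f"{col}: Mann-Whitney p = {p:.3f} <= {alpha}"
                ok = False
                break
        if not ok:
            continue
        sex = labels["sex"].to_numpy()
        if len(set(sex)) > 1:
            table = pd.crosstab(
                np.isin(np.arange(n), tr), sex
            ).to_numpy()
            p = _stats.chi2_contingency(table).pvalue
            if p <= alpha:
                last_failure = f"sex: chi-square p = {p:.3f} <= {alpha}"
                continue
        return list(ids[np.sort(tr)]), list(ids[np.sort(te)])
    raise SplitError(f"no balanced split in {max_tries} tries; last failure: {last_failure}")


# ---------------------------------------------------------------------------
# score-level merging
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MergeMap:
    """Monotone mapping of original scores 0-4 onto merged levels 0..M-1."""

    item: str
    mapping: tuple[int, ...]  # length 5, score -> merged level

    def __post_init__(self) -> None:
        if len(self.mapping) != 5:
            raise ValueError("mapping must cover scores 0..4")
        if any(b < a for a, b in zip(self.mapping, self.mapping[1:])):
            raise ValueError("mapping must be monotone non-decreasing")
        if sorted(set(self.mapping)) != list(range(self.m)):
            raise ValueError("mapping must be surjective onto 0..M-1")

    @property
    def m(self) -> int:
        return max(self.mapping) + 1

    def apply(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=int)
        return np.asarray(self.mapping, dtype=int)[scores]

    def level_labels(self) -> list[str]:
        groups: dict[int, list[str]] = {}
        for score, level in enumerate(self.mapping):
            groups.setdefault(level, []).append(str(score))
        return ["/".join(groups[level]) for level in range(self.m)]


def merge_levels(train_scores, item: str = "item", min_n: int = 5) -> MergeMap:
    """Merge sparse score levels into the adjacent lower level.

    A level whose training sample size is <= ``min_n`` (counted on the
    original training histogram) joins the next lower level; a sparse
    lowest level joins upward instead.  The same map must be applied
    verbatim to test data.  Raises when everything collapses into a single
    level (item not modelable).
    """
    scores = np.asarray(train_scores, dtype=int)
    if scores.min() < 0 or scores.max() > 4:
        raise ValueError("scores must lie in 0..4")
    counts = np.bincount(scores, minlength=5)
    mapping = [0] * 5
    level = 0
    for s in range(1, 5):
        if counts[s] <= min_n:
            mapping[s] = mapping[s - 1]
        else:
            level += 1
            mapping[s] = level
    if counts[0] <= min_n and max(mapping) > 0:
        # sparse lowest level: fold upward into the next group
        first_other = next(m for m in mapping if m > 0)
        mapping = [max(m - first_other, 0) for m in mapping]
    if max(mapping) == 0:
        raise ValueError(f"{item}: all scores merge into one level; not modelable")
    return MergeMap(item, tuple(mapping))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_balance(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes to the majority count.

    Synthetic samples interpolate between a class member and one of its k
    within-class nearest neighbours; a class with m < k + 1 members uses
    k = m - 1, and a singleton class is duplicated verbatim.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    xs, ys = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = int(target - cnt)
        if need <= 0:
            continue
        Xc = X[y == cls]
        m = len(Xc)
        if m == 1:
            new = np.repeat(Xc, need, axis=0)
        else:
            k_eff = min(k, m - 1)
            nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
            neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
            base = rng.integers(0, m, size=need)
            pick = neigh[base, rng.integers(0, k_eff, size=need)]
            gap = rng.random((need, 1))
            new = Xc[base] + gap * (Xc[pick] - Xc[base])
        xs.append(new)
        ys.append(np.full(need, cls, dtype=int))
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Gain ranking and classifiers
# ---------------------------------------------------------------------------


def _make_classifier(algorithm: str, params: dict, seed: int):
    if algorithm == GBT:
        return XGBClassifier(
            n_estimators=N_ESTIMATORS,
            learning_rate=params["learning_rate"],
            max_depth=params["max_depth"],
            gamma=params["gamma"],
            reg_lambda=params["reg_lambda"],
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    if algorithm == RBF:
        return SVC(kernel="rbf", gamma=params["gamma"], C=params["C"], random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def rank_features_by_gain(
    X: pd.DataFrame, y, seed: int = 0, params: dict | None = None
) -> list[tuple[str, float]]:
    """All features ordered by total Gain of a reference boosted fit.

    Constant or unused columns receive Gain 0; ties break
    lexicographically by feature name.  Missing values are median-imputed
    before fitting.
    """
    params = params or RANKING_PARAMS
    Xf = X.fillna(X.median())
    clf = _make_classifier(GBT, params, seed)
    clf.fit(Xf.to_numpy(), np.asarray(y, dtype=int))
    booster = clf.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    # booster names are f0, f1, ... in column order
    gains = {col: raw.get(f"f{i}", 0.0) for i, col in enumerate(Xf.columns)}
    return sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# LOOCV model search
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CVResult:
    algorithm: str
    params: dict
    k: int
    report: _metrics.ItemReport
    flagged_folds: int  # folds whose training subset missed a class

    @property
    def key(self):
        return (
            -self.report.weighted_f1,
            -self.report.acc_exact,
            self.k,
            0 if self.algorithm == GBT else 1,
        )


def loocv_evaluate(
    X: pd.DataFrame,
    y_merged: np.ndarray,
    ranked_features: list[str],
    algorithm: str,
    param_grid: list[dict],
    k_grid: tuple[int, ...],
    seed: int = 0,
    smote_k: int = 5,
    audit: list | None = None,
) -> list[CVResult]:
    """Leave-one-out evaluation of every (K, hyperparameter) configuration.

    For each left-out participant the fold's training subset is
    median-imputed, oversampled with SMOTE and fitted; the left-out row
    never enters imputation or oversampling.  Predictions are aggregated
    into one confusion matrix per configuration.  When ``audit`` is a
    list, (left_out_index, fold_training_indices) pairs are appended for
    leakage inspection.
    """
    y = np.asarray(y_merged, dtype=int)
    n = len(X)
    m = int(y.max()) + 1
    results = []
    for k in k_grid:
        feats = ranked_features[:k]
        Xk = X[feats].to_numpy(dtype=float)
        folds = []
        for i in range(n):
            tr = np.r_[0:i, i + 1 : n]
            Xtr = Xk[tr]
            med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            Xtr = np.where(np.isnan(Xtr), med, Xtr)
            xte = np.where(np.isnan(Xk[i]), med, Xk[i])
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, i]))
            Xa, ya = smote_balance(Xtr, y[tr], rng, k=smote_k)
            flagged = len(set(y[tr])) < m
            folds.append((Xa, ya, xte, flagged))
            if audit is not None:
                audit.append((i, tuple(tr)))
        for params in param_grid:
            preds = np.empty(n, dtype=int)
            flagged_folds = 0
            for i, (Xa, ya, xte, flagged) in enumerate(folds):
                flagged_folds += int(flagged)
                clf = _make_classifier(algorithm, params, seed)
                clf.fit(Xa, ya)
                preds[i] = int(clf.predict(xte[None, :])[0])
            cm = _metrics.confusion_matrix(y, preds, m)
            results.append(
                CVResult(algorithm, dict(params), k, _metrics.item_report(cm), flagged_folds)
            )
    return results


def select_best(results: list[CVResult]) -> CVResult:
    """Highest LOOCV weighted F1; ties by exact accuracy, then smaller K,
    then gradient boosting before the RBF classifier."""
    if not results:
        raise ValueError("no CV results to select from")
    return min(results, key=lambda r: r.key)


# ---------------------------------------------------------------------------
# final per-item model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TrainedItemModel:
    """Refit configuration of one item, ready for held-out evaluation."""

    item: str
    algorithm: str
    params: dict
    k: int
    features: list[str]
    gain_scores: list[float]
    merge_map: MergeMap
    medians: np.ndarray
    estimator: object
    cv_report: _metrics.ItemReport | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xk = X[self.features].to_numpy(dtype=float)
        Xk = np.where(np.isnan(Xk), self.medians, Xk)
        return np.asarray(self.estimator.predict(Xk), dtype=int)

    def evaluate(self, X: pd.DataFrame, scores) -> _metrics.ItemReport:
        y = self.merge_map.apply(scores)
        cm = _metrics.confusion_matrix(y, self.predict(X), self.merge_map.m)
        return _metrics.item_report(cm, self.merge_map.level_labels())

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedItemModel":
        return joblib.load(path)


def fit_final(
    X: pd.DataFrame,
    y_merged: np.ndarray,
    item: str,
    best: CVResult,
    ranked: list[tuple[str, float]],
    merge_map: MergeMap,
    seed: int = 0,
    smote_k: int = 5,
) -> TrainedItemModel:
    """Refit the selected configuration on the full training set with the
    same SMOTE procedure."""
    feats = [name for name, _ in ranked[: best.k]]
    gains = [g for _, g in ranked[: best.k]]
    Xk = X[feats].to_numpy(dtype=float)
    med = np.nanmedian(Xk, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xk = np.where(np.isnan(Xk), med, Xk)
    rng = np.random.default_rng(np.random.SeedSequence([seed, best.k]))
    Xa, ya = smote_balance(Xk, np.asarray(y_merged, dtype=int), rng, k=smote_k)
    clf = _make_classifier(best.algorithm, best.params, seed)
    clf.fit(Xa, ya)
    return TrainedItemModel(
        item=item,
        algorithm=best.algorithm,
        params=dict(best.params),
        k=best.k,
        features=feats,
        gain_scores=gains,
        merge_map=merge_map,
        medians=med,
        estimator=clf,
        cv_report=best.report,
    )


def sensor_contribution(model: TrainedItemModel) -> dict[str, float]:
    """Per-sensor-group share of the model's selected features.

    A feature derived from several sensors counts once for each group, so
    contributions can exceed 100 % in total.
    """
    counts = {g: 0 for g in ("waist", "chest", "hand", "thigh", "shank", "foot")}
    for name in model.features:
        for group in sensors_of_constructed(name):
            counts[group] += 1
    k = len(model.features)
    return {g: c / k for g, c in counts.items()}


# ---------------------------------------------------------------------------
# subscale regression
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubscaleModel:
    """L1-penalised linear model of the five-item subscale sum."""

    lambda_: float
    coefficients: dict[str, float]  # non-zero betas by feature name
    intercept: float
    feature_names: list[str]
    medians: np.ndarray
    scaler: StandardScaler
    estimator: object

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.feature_names].to_numpy(dtype=float)
        Xv = np.where(np.isnan(Xv), self.medians, Xv)
        return self.estimator.predict(self.scaler.transform(Xv))

    def evaluate(self, X: pd.DataFrame, y) -> _metrics.RegressionReport:
        return _metrics.regression_metrics(np.asarray(y, dtype=float), self.predict(X))


def fit_subscale(
    X: pd.DataFrame,
    y_subscale,
    seed: int = 0,
    cv: int = 10,
    alpha: float | None = None,
) -> SubscaleModel:
    """LASSO with the penalty at minimum mean ``cv``-fold CV error.

    Features are standardized (so one penalty acts comparably across
    units) and median-imputed on training data.  ``alpha`` overrides the
    cross-validated penalty when given.  Only non-zero-coefficient
    features are reported.
    """
    y = np.asarray(y_subscale, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("subscale target is constant; nothing to fit")
    Xv = X.to_numpy(dtype=float)
    med = np.nanmedian(Xv, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xv = np.where(np.isnan(Xv), med, Xv)
    scaler = StandardScaler().fit(Xv)
    Xs = scaler.transform(Xv)
    if alpha is None:
        est = LassoCV(cv=cv, random_state=seed, alphas=60, max_iter=20000).fit(Xs, y)
        lam = float(est.alpha_)
    else:
        est = Lasso(alpha=alpha, max_iter=20000).fit(Xs, y)
        lam = float(alpha)
    coefs = {
        name: float(c)
        for name, c in zip(X.columns, est.coef_)
        if c != 0.0
    }
    return SubscaleModel(
        lambda_=lam,
        coefficients=coefs,
        intercept=float(est.intercept_),
        feature_names=list(X.columns),
        medians=med,
        scaler=scaler,
        estimator=est,
    )
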