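"""Skill models: elastic-net feature selection, regression trees, LOSO CV.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``) so it composes with pipelines and model selection:

* features are standardised with training-set mean and standard
  deviation (zero-variance columns dropped and recorded);
* an elastic net fitted to the **summed** OSATS score (penalty strength
  and l1 mixing chosen by inner 5-fold CV on mean squared error) keeps
  the features with nonzero coefficients;
* one pruned regression tree per OSATS domain is fitted on the selected
  features (cost-complexity pruning chosen by inner CV, minimum leaf
  size 3); the summed prediction is the sum of the five domain trees,
  rounded and clipped to [5, 25].

Evaluation is leave-one-subject-out: every fold holds out all trials of
one subject and re-runs standardisation, selection, and fitting on the
remaining subjects, so no statistic of a held-out subject ever touches
training.  Accuracy is reported with the six-metric set: summed-score
accuracy within +/-2 and +/-4 points and Pearson r, and rounded-average
accuracy exact and within +/-1 plus Pearson r, alongside a 5x5 confusion
matrix of rounded averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .features import CATEGORIES, SUBSETS, maf_manifest, subset_names
from .trial_io import OSATS_DOMAINS, OSATSRating

__all__ = [
    "rounded_average",
    "OSATSRegressor",
    "BaselineRegressor",
    "select_features",
    "fit_model",
    "predict",
    "loso_evaluate",
    "baseline_predict",
    "compute_metrics",
    "EvalReport",
]

SUMMED_MIN, SUMMED_MAX = 5, 25


def rounded_average(summed: int) -> int:
    """Rounded-average OSATS score: round(summed / 5), half away from zero."""
    if not (SUMMED_MIN <= summed <= SUMMED_MAX):
        raise ValueError(f"summed score {summed} outside [{SUMMED_MIN}, {SUMMED_MAX}]")
    return int(math.floor(summed / 5 + 0.5))


def _ratings_to_domains(ratings) -> np.ndarray:
    """Coerce ratings to an (n, 5) integer domain matrix."""
    if isinstance(ratings, pd.DataFrame):
        return ratings[list(OSATS_DOMAINS)].to_numpy(dtype=int)
    ratings = list(ratings) if not isinstance(ratings, np.ndarray) else ratings
    if len(ratings) and isinstance(ratings[0], OSATSRating):
        return np.array([r.domains for r in ratings], dtype=int)
    arr = np.asarray(ratings)
    if arr.ndim == 2 and arr.shape[1] == 5:
        return arr.astype(int)
    raise ValueError("ratings must be OSATSRating objects, an (n,5) array, "
                     "or a DataFrame with the five domain columns")


class OSATSRegressor(BaseEstimator, RegressorMixin):
    """Elastic-net-selected regression trees predicting summed OSATS score.

    Parameters
    ----------
    subset : str or None
        Sensor subset (``T``, ``TG``, ``TM``, ``TMV``, ``TMG``, ``TMVG``)
        restricting which manifest features the model may use; ``None``
        uses every column of ``X``.
    mode : {'per_domain', 'summed'}
        ``per_domain`` fits one tree per OSATS domain and sums the five
        outputs (default); ``summed`` fits a single tree on the summed
        score.
    l1_ratios : sequence of float
        Elastic-net mixing grid searched by inner CV.
    cv : int
        Inner cross-validation folds for the penalty and tree pruning.
    min_samples_leaf : int
        Minimum leaf size of each regression tree.
    random_state : int or None
        Seed for inner-CV fold shuffling.
    """

    def __init__(self, subset: str | None = "TMVG", mode: str = "per_domain",
                 l1_ratios: tuple = (0.5, 0.7, 0.9, 0.95, 1.0), cv: int = 5,
                 n_alphas: int = 20, min_samples_leaf: int = 3,
                 random_state: int | None = None):
        self.subset = subset
        self.mode = mode
        self.l1_ratios = l1_ratios
        self.cv = cv
        self.n_alphas = n_alphas
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        """Fit on feature matrix ``X`` and ratings ``y``.

        ``y`` may be OSATSRating objects, an (n, 5) domain matrix, or a
        DataFrame with the five domain columns.  A 1-D vector of summed
        scores is accepted in ``summed`` mode only.
        """
        X = self._as_frame(X)
        y_arr = np.asarray(y) if not isinstance(y, (pd.DataFrame, list)) else y
        if isinstance(y_arr, np.ndarray) and y_arr.ndim == 1:
            if self.mode != "summed":
                raise ValueError("1-D summed labels require mode='summed'")
            domains = None
            summed = y_arr.astype(float)
        else:
            domains = _ratings_to_domains(y)
            summed = domains.sum(axis=1).astype(float)
        if len(np.unique(summed)) < 2:
            raise ValueError("degenerate labels: fewer than 2 distinct summed scores")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 training trials")

        cols = self._subset_columns(X)
        Xs = X[cols].to_numpy(dtype=float)

        mean = Xs.mean(axis=0)
        std = Xs.std(axis=0, ddof=0)
        keep = std > 0
        self.dropped_zero_variance_ = [c for c, k in zip(cols, keep) if not k]
        cols = [c for c, k in zip(cols, keep) if k]
        mean, std = mean[keep], std[keep]
        Z = (Xs[:, keep] - mean) / std

        self.feature_names_in_ = list(X.columns)
        self.standardizer_ = {"columns": cols, "mean": mean, "std": std}
        self.train_median_summed_ = float(np.median(summed))

        self.selected_features_ = self._select(Z, cols, summed)
        if not self.selected_features_:
            # all-zero elastic net: fall back to a constant median model
            self.trees_ = None
            return self

        idx = [cols.index(c) for c in self.selected_features_]
        Zsel = Z[:, idx]
        rng = np.random.default_rng(self.random_state)
        if self.mode == "per_domain":
            if domains is None:
                raise ValueError("per-domain trees require domain-level labels")
            self.trees_ = [self._fit_tree(Zsel, domains[:, d].astype(float), rng)
                           for d in range(5)]
        elif self.mode == "summed":
            self.trees_ = [self._fit_tree(Zsel, summed, rng)]
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        names = getattr(self, "feature_names_in_", None)
        if names is not None and len(names) == X.shape[1]:
            return pd.DataFrame(X, columns=names)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def _subset_columns(self, X: pd.DataFrame) -> list[str]:
        if self.subset is None:
            return list(X.columns)
        allowed = subset_names(self.subset)
        missing = [c for c in allowed if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing[:5]}")
        return allowed

    def _select(self, Z: np.ndarray, cols: list[str], summed: np.ndarray) -> list[str]:
        folds = KFold(n_splits=min(self.cv, Z.shape[0]), shuffle=True,
                      random_state=self.random_state)
        enet = ElasticNetCV(l1_ratio=list(self.l1_ratios), alphas=self.n_alphas,
                            cv=folds, max_iter=2000, tol=1e-3)
        # features are already standardised; ElasticNetCV centers internally.
        # Path points far from the CV optimum may stop on max_iter; that is
        # expected at this tolerance and does not affect the selected set.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            enet.fit(Z, summed)
        self.enet_ = enet
        return [c for c, w in zip(cols, enet.coef_) if abs(w) > 1e-10]

    def _fit_tree(self, Z: np.ndarray, y: np.ndarray, rng) -> DecisionTreeRegressor:
        """Regression tree with cost-complexity pruning chosen by inner CV."""
        seed = int(rng.integers(2 ** 31 - 1))
        base = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                     random_state=seed)
        path = base.cost_complexity_pruning_path(Z, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
        if alphas.size > 8:  # coarsen the path to keep the CV cheap
            alphas = np.quantile(alphas, np.linspace(0, 1, 8))
        best_alpha, best_mse = 0.0, np.inf
        folds = KFold(n_splits=min(self.cv, len(y)), shuffle=True, random_state=seed)
        for a in alphas:
            mse = 0.0
            for tr, te in folds.split(Z):
                t = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                          ccp_alpha=float(a), random_state=seed)
                t.fit(Z[tr], y[tr])
                mse += float(np.mean((t.predict(Z[te]) - y[te]) ** 2))
            if mse < best_mse - 1e-12:
                best_mse, best_alpha = mse, float(a)
        tree = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                     ccp_alpha=best_alpha, random_state=seed)
        tree.fit(Z, y)
        return tree

    # -- prediction -------------------------------------------------------

    def _transform(self, X) -> np.ndarray:
        X = self._as_frame(X)
        std = self.standardizer_
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing[:5]}")
        cols, mean, scale = std["columns"], std["mean"], std["std"]
        Z = (X[cols].to_numpy(dtype=float) - mean) / scale
        idx = [cols.index(c) for c in self.selected_features_]
        return Z[:, idx]

    def predict(self, X) -> np.ndarray:
        """Integer summed-score predictions, clipped to [5, 25]."""
        if self.trees_ is None:  # median fallback
            n = self._as_frame(X).shape[0]
            raw = np.full(n, self.train_median_summed_)
        else:
            Z = self._transform(X)
            raw = np.sum([t.predict(Z) for t in self.trees_], axis=0)
        return np.clip(np.floor(raw + 0.5), SUMMED_MIN, SUMMED_MAX).astype(int)

    def predict_rounded(self, X) -> np.ndarray:
        return np.array([rounded_average(s) for s in self.predict(X)])

    def selected_counts_by_category(self) -> dict[str, int]:
        """How many selected features fall in each sensor category."""
        cat = {d.name: d.category for d in maf_manifest()}
        counts = {c: 0 for c in CATEGORIES}
        for name in self.selected_features_:
            if name in cat:
                counts[cat[name]] += 1
        return counts


class BaselineRegressor(BaseEstimator, RegressorMixin):
    """Control models: uniform random guessing or the training median.

    ``random`` draws summed scores uniformly from the observed 5-20
    range; ``median`` predicts the training median summed score on every
    trial (its correlation with anything is undefined, reported as NaN).
    """

    def __init__(self, kind: str = "median", random_state: int | None = None):
        self.kind = kind
        self.random_state = random_state

    def fit(self, X, y):
        if self.kind not in ("random", "median"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "median":
            y = np.asarray(y, dtype=float)
            if y.ndim == 2:
                y = y.sum(axis=1)
            if y.size == 0:
                raise ValueError("median baseline requires training labels")
            self.median_summed_ = int(np.floor(np.median(y) + 0.5))
        self.rng_ = np.random.default_rng(self.random_state)
        return self

    def predict(self, X) -> np.ndarray:
        n = X if isinstance(X, int) else np.asarray(X).shape[0]
        if self.kind == "random":
            return self.rng_.integers(5, 21, size=n)  # uniform on [5, 20]
        return np.full(n, self.median_summed_, dtype=int)

    def predict_rounded(self, X) -> np.ndarray:
        return np.array([rounded_average(int(s)) for s in self.predict(X)])


# ---------------------------------------------------------------------------
# Metrics

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with a NaN sentinel when either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_metrics(pred_summed, true_summed) -> dict:
    """The six-metric set plus the 5x5 rounded-average confusion matrix."""
    p = np.asarray(pred_summed, dtype=int)
    t = np.asarray(true_summed, dtype=int)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("prediction/truth length mismatch or empty")
    pr = np.array([rounded_average(int(s)) for s in p])
    tr = np.array([rounded_average(int(s)) for s in t])
    conf = np.zeros((5, 5), dtype=int)
    for a, b in zip(tr, pr):
        conf[a - 1, b - 1] += 1
    with np.errstate(invalid="ignore"):
        row = conf.sum(axis=1, keepdims=True)
        conf_norm = np.where(row > 0, conf / np.maximum(row, 1), 0.0)
    return {
        "summed_within2": float(np.mean(np.abs(p - t) <= 2)),
        "summed_within4": float(np.mean(np.abs(p - t) <= 4)),
        "summed_r": _pearson(p, t),
        "rounded_exact": float(np.mean(pr == tr)),
        "rounded_within1": float(np.mean(np.abs(pr - tr) <= 1)),
        "rounded_r": _pearson(pr, tr),
        "confusion": conf,
        "confusion_row_normalized": conf_norm,
    }


@dataclass
class EvalReport:
    """Pooled LOSO predictions, metrics, and selection bookkeeping."""

    subset: str
    trial_ids: list
    subject_ids: list
    true_summed: np.ndarray
    pred_summed: np.ndarray
    metrics: dict
    selected_counts: dict[str, float] = field(default_factory=dict)
    n_folds: int = 0

    def to_dict(self) -> dict:
        m = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.metrics.items()}
        return {
            "subset": self.subset,
            "n_folds": self.n_folds,
            "trial_ids": list(self.trial_ids),
            "subject_ids": list(self.subject_ids),
            "true_summed": self.true_summed.tolist(),
            "pred_summed": self.pred_summed.tolist(),
            "metrics": m,
            "selected_counts_by_category": self.selected_counts,
        }


# ---------------------------------------------------------------------------
# Functional wrappers

def select_features(X, y, subset: str | None = None,
                    l1_ratios=(0.5, 0.7, 0.9, 0.95, 1.0), cv: int = 5,
                    random_state: int | None = None) -> list[str]:
    """Elastic-net feature selection against the summed score (wrapper)."""
    model = OSATSRegressor(subset=subset, mode="summed", l1_ratios=l1_ratios,
                           cv=cv, random_state=random_state)
    X = model._as_frame(X)
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y.sum(axis=1)
    if len(np.unique(y)) < 2:
        return []
    cols = model._subset_columns(X)
    Xs = X[cols].to_numpy(dtype=float)
    std = Xs.std(axis=0)
    keep = std > 0
    cols = [c for c, k in zip(cols, keep) if k]
    Z = (Xs[:, keep] - Xs[:, keep].mean(axis=0)) / Xs[:, keep].std(axis=0)
    return model._select(Z, cols, y)


def fit_model(X, ratings, subset: str = "TMVG", mode: str = "per_domain",
              random_state: int | None = None, **kw) -> OSATSRegressor:
    return OSATSRegressor(subset=subset, mode=mode,
                          random_state=random_state, **kw).fit(X, ratings)


def predict(model: OSATSRegressor, X) -> tuple[np.ndarray, np.ndarray]:
    """(summed, rounded-average) predictions from a fitted model."""
    s = model.predict(X)
    return s, np.array([rounded_average(int(v)) for v in s])


def baseline_predict(kind: str, train_summed, n_trials: int,
                     seed: int | None = None) -> np.ndarray:
    b = BaselineRegressor(kind=kind, random_state=seed)
    b.fit(None, np.asarray(train_summed, dtype=float))
    return b.predict(n_trials)


def loso_evaluate(X: pd.DataFrame, ratings, subject_ids, subset: str = "TMVG",
                  mode: str = "per_domain", seed: int | None = None,
                  trial_ids=None, **kw) -> EvalReport:
    """Leave-one-subject-out evaluation of the skill model.

    One fold per distinct subject (processed in sorted order); each
    fold's standardisation, selection, and tree fitting see only the
    training subjects.  Predictions are pooled over all trials before
    computing metrics.
    """
    domains = _ratings_to_domains(ratings)
    summed = domains.sum(axis=1)
    subject_ids = np.asarray(subject_ids)
    if trial_ids is None:
        trial_ids = list(range(len(subject_ids)))
    subjects = sorted(set(subject_ids.tolist()))
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")

    pred = np.zeros(len(subject_ids), dtype=int)
    counts_acc = {c: 0.0 for c in CATEGORIES}
    n_folds = 0
    for subj in subjects:
        test = subject_ids == subj
        if not np.any(test):
            continue
        train = ~test
        model = OSATSRegressor(subset=subset, mode=mode, random_state=seed, **kw)
        model.fit(X.loc[train], domains[train])
        pred[test] = model.predict(X.loc[test])
        for c, v in model.selected_counts_by_category().items():
            counts_acc[c] += v
        n_folds += 1

    metrics = compute_metrics(pred, summed)
    selected = {c: counts_acc[c] / n_folds for c in CATEGORIES}
    return EvalReport(subset=subset, trial_ids=list(trial_ids),
                      subject_ids=subject_ids.tolist(), true_summed=summed,
                      pred_summed=pred, metrics=metrics,
                      selected_counts=selected, n_folds=n_folds)
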