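"""Cohort-level redundancy reduction and the ordered fold-internal
preprocessing chain: outlier removal, borderline-sample (Tomek link)
removal, univariate R² feature selection and SMOTE minority oversampling.

All steps are sklearn-style estimators. Selectors implement
``fit``/``transform``/``get_support``; steps that change the *row* set
(outlier, borderline, balance) follow the imbalanced-learn
``fit_resample(X, y)`` convention, since sklearn transformers cannot alter
``y``. Every statistic (medians, MADs, correlations, rankings, neighbor
graphs) is computed from the rows passed to ``fit``/``fit_resample`` —
validation rows never influence them, which is what makes the chain safe to
run inside each Monte Carlo fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

CANONICAL_ORDER = ("outlier", "borderline", "select", "balance")


# --------------------------------------------------------------------------
# cohort-level redundancy reduction (label-free, applied once before CV)

class CorrelationRedundancyFilter(TransformerMixin, BaseEstimator):
    """Greedy removal of features nearly collinear with an earlier one.

    Scanning columns in order, a feature is dropped when its absolute
    Pearson correlation with any earlier *retained* feature exceeds
    ``threshold`` (default 0.95). Zero-variance features correlate with
    nothing and are retained with a warning.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate correlations")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("zero-variance feature(s) retained by redundancy filter")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        keep: list[int] = []
        for j in range(X.shape[1]):
            if all(abs(corr[j, k]) <= self.threshold for k in keep):
                keep.append(j)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[keep] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def redundancy_reduce(table, corr_threshold: float = 0.95):
    """Apply the redundancy filter to a FeatureTable, returning a reduced copy."""
    from .extract import FeatureTable

    filt = CorrelationRedundancyFilter(corr_threshold).fit(table.features.values)
    feats = table.features.loc[:, filt.get_support()]
    return FeatureTable(feats, table.labels, table.patient_ids, table.groups)


# --------------------------------------------------------------------------
# fold-internal steps

class RobustZOutlierDetector(BaseEstimator):
    """Row-wise outlier vote on robust z-scores.

    Per feature, z = (x - median) / (1.4826 MAD); a row is an outlier when
    |z| > ``z_thresh`` for at least ``min_frac`` of the usable features.
    Features with MAD = 0 cast no votes.
    """

    def __init__(self, z_thresh: float = 4.0, min_frac: float = 0.10):
        self.z_thresh = z_thresh
        self.min_frac = min_frac

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 5:
            raise ValueError("need at least 5 rows for outlier detection")
        self.median_ = np.median(X, axis=0)
        self.mad_ = np.median(np.abs(X - self.median_), axis=0)
        self.usable_ = self.mad_ > 0
        return self

    def flags(self, X) -> np.ndarray:
        check_is_fitted(self, "median_")
        X = np.asarray(X, dtype=np.float64)
        usable = self.usable_
        if not usable.any():
            return np.zeros(X.shape[0], dtype=bool)
        z = (X[:, usable] - self.median_[usable]) / (1.4826 * self.mad_[usable])
        votes = (np.abs(z) > self.z_thresh).mean(axis=1)
        return votes >= self.min_frac

    def fit_resample(self, X, y):
        self.fit(X)
        keep = ~self.flags(X)
        return _take(X, keep), np.asarray(y)[keep]


class TomekLinkCleaner(BaseEstimator):
    """Remove the majority-class member of every Tomek link.

    A Tomek link is a pair of opposite-class samples that are each other's
    nearest neighbor in Euclidean distance over standardized features —
    borderline or noisy points sitting on the class boundary. Minority-class
    rows are never removed.
    """

    def fit_resample(self, X, y):
        Xa = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("both classes must be present for Tomek-link cleaning")
        minority = classes[np.argmin(counts)]

        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xa - mu) / sd
        d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = d2.argmin(axis=1)

        remove = np.zeros(len(y), dtype=bool)
        for i in range(len(y)):
            j = nn[i]
            if nn[j] == i and y[i] != y[j]:
                for k in (i, j):
                    if y[k] != minority:
                        remove[k] = True
        self.removed_ = remove
        keep = ~remove
        return _take(X, keep), y[keep]


class RSquaredSelector(TransformerMixin, BaseEstimator):
    """Top-n univariate R² feature selection against a binary label.

    R² of a feature is its squared Pearson correlation with the 0/1 label
    (the R² of the univariate regression). Constant features score 0; ties
    break by column order.
    """

    def __init__(self, n_features: int = 15):
        self.n_features = n_features

    def fit(self, X, y):
        Xa = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if Xa.shape[0] < 3:
            raise ValueError("need at least 3 rows for R2 ranking")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for R2 ranking")
        xc = Xa - Xa.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
        self.scores_ = np.where(sx > 0, r**2, 0.0)
        n = min(self.n_features, Xa.shape[1])
        # stable sort on -score keeps column order as the tie-break
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        sel = np.sort(self.ranking_[:n])
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        self.support_[sel] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class SmoteOversampler(BaseEstimator):
    """Synthetic minority oversampling to exact class balance.

    New minority rows are x_i + lambda (x_nn - x_i) with lambda ~ U(0, 1)
    and x_nn one of the ``k_neighbors`` nearest minority neighbors of x_i
    (k is capped at minority count - 1). ``fit_resample`` also returns a
    boolean marker identifying synthetic rows so they can be audited out of
    any validation set.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        Xa = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min < 2:
            raise ValueError("minority class has a single sample; SMOTE needs a neighbor")
        n_new = int(n_maj - n_min)
        if n_new == 0:
            synth = np.zeros(len(y), dtype=bool)
            return _take(X, np.ones(len(y), bool)), y.copy(), synth

        rng = np.random.default_rng(self.random_state)
        Xmin = Xa[y == minority]
        k = min(self.k_neighbors, n_min - 1)
        d2 = ((Xmin[:, None, :] - Xmin[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1)[:, :k]

        base = rng.integers(0, n_min, size=n_new)
        pick = nn_idx[base, rng.integers(0, k, size=n_new)]
        lam = rng.uniform(0.0, 1.0, size=n_new)
        X_new = Xmin[base] + lam[:, None] * (Xmin[pick] - Xmin[base])

        X_out = np.vstack([Xa, X_new])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        synthetic = np.concatenate([np.zeros(len(y), bool), np.ones(n_new, bool)])
        if isinstance(X, pd.DataFrame):
            X_out = pd.DataFrame(X_out, columns=X.columns)
        return X_out, y_out, synthetic


# --------------------------------------------------------------------------
# the ordered plan

@dataclass
class PreprocessPlan:
    """Ordered fold-internal preprocessing recipe.

    ``steps`` is a subset of {outlier, borderline, select, balance} and is
    always executed in that canonical order; selection precedes balancing so
    synthetic samples are generated in the selected subspace.
    """

    steps: tuple[str, ...] = CANONICAL_ORDER
    outlier_k: float = 4.0
    outlier_min_frac: float = 0.10
    rank_top_n: int = 15
    corr_threshold: float = 0.95
    smote_k: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.steps) - set(CANONICAL_ORDER)
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")
        order = [s for s in CANONICAL_ORDER if s in self.steps]
        if list(self.steps) != order:
            raise ValueError(
                f"steps must respect the canonical order {CANONICAL_ORDER}, got {self.steps}"
            )
        if self.rank_top_n < 1:
            raise ValueError("rank_top_n must be >= 1")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")

    @classmethod
    def none(cls) -> "PreprocessPlan":
        return cls(steps=())

    @classmethod
    def from_yaml(cls, path: str) -> "PreprocessPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = {"steps": list(self.steps), "outlier_k": self.outlier_k,
                "outlier_min_frac": self.outlier_min_frac, "rank_top_n": self.rank_top_n,
                "corr_threshold": self.corr_threshold, "smote_k": self.smote_k,
                "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def preprocess_fold(
    train: pd.DataFrame,
    labels: np.ndarray,
    plan: PreprocessPlan,
    seed: int | None = None,
):
    """Run the plan on one fold's training data.

    Returns ``(X, y, synthetic_marker, selected_feature_names, audit_log)``.
    The audit log records row/column counts after each step. Raises if a
    step empties one of the classes.
    """
    X = train.copy()
    y = np.asarray(labels, dtype=float)
    synthetic = np.zeros(len(y), dtype=bool)
    audit = [{"step": "input", "rows": len(y), "cols": X.shape[1]}]
    rng_seed = seed if seed is not None else plan.seed

    for step in plan.steps:
        if step == "outlier":
            det = RobustZOutlierDetector(plan.outlier_k, plan.outlier_min_frac)
            X, y = det.fit_resample(X, y)
        elif step == "borderline":
            X, y = TomekLinkCleaner().fit_resample(X, y)
        elif step == "select":
            sel = RSquaredSelector(plan.rank_top_n).fit(X, y)
            X = sel.transform(X)
        elif step == "balance":
            X, y, synthetic = SmoteOversampler(plan.smote_k, rng_seed).fit_resample(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError(f"preprocessing step {step!r} emptied a class")
        audit.append({"step": step, "rows": len(y), "cols": X.shape[1]})
        if step != "balance":
            synthetic = np.zeros(len(y), dtype=bool)

    selected = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return X, y, synthetic, selected, audit


def _take(X, keep: np.ndarray):
    if isinstance(X, pd.DataFrame):
        return X.loc[keep]
    return np.asarray(X)[keep]
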