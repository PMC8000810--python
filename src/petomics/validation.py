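"""Monte Carlo cross-validation with fold-internal preprocessing, confusion
matrix analytics, Mann-Whitney AUC, sham (label permutation) analysis, and
occurrence-based feature importance.

Every fold draws a fresh stratified 90/10 split at the *patient* level (both
lesions of a patient land on the same side), fits the preprocessing chain on
the training rows only, trains the five-forest majority-vote ensemble, and
scores the untouched validation rows. Splits depend only on (seed, fold),
never on the preprocessing plan, so with/without-preprocessing comparisons
at the same seed reuse identical fold sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ensemble import DEFAULT_MEMBER_CONFIGS, MajorityVoteForest
from .extract import FeatureTable
from .preprocessing import PreprocessPlan, preprocess_fold

METRIC_NAMES = ("SENS", "SPEC", "PPV", "NPV", "ACC")


@dataclass
class FoldResult:
    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    scores: np.ndarray
    y_true: np.ndarray
    selected_features: list[str]
    seed: int
    val_patients: tuple[str, ...] = ()
    n_synthetic_train: int = 0

    @property
    def auc(self) -> float:
        return mann_whitney_auc(self.scores, self.y_true)


@dataclass
class ModelReport:
    label_name: str
    folds: list[FoldResult]
    plan: PreprocessPlan
    sham: bool = False
    fingerprint: str = ""

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def aggregate(self) -> dict[str, float]:
        """Cross-fold mean metrics on the % scale, plus mean AUC in [0, 1].

        Per-fold metrics with a zero denominator are undefined and excluded
        from the mean (never imputed as 0 or 100).
        """
        out: dict[str, float] = {}
        for name in METRIC_NAMES:
            vals = [m[name] for f in self.folds
                    if (m := confusion_metrics(f))[name] is not None]
            out[name] = float(np.mean(vals)) if vals else float("nan")
        out["AUC"] = float(np.mean([f.auc for f in self.folds]))
        return out

    def occurrences(self) -> dict[str, int]:
        return feature_occurrence(self)

    def to_json(self, path: str) -> None:
        payload = {
            "label": self.label_name,
            "sham": self.sham,
            "n_folds": self.n_folds,
            "plan_steps": list(self.plan.steps),
            "aggregate": self.aggregate(),
            "occurrences": self.occurrences(),
            "folds": [
                {"fold": f.fold, "tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn,
                 "auc": f.auc, "selected": f.selected_features}
                for f in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion_metrics(fold: FoldResult) -> dict[str, float | None]:
    """SENS/SPEC/PPV/NPV/ACC in percent; None where the denominator is 0."""
    tp, fp, tn, fn = fold.tp, fold.fp, fold.tn, fold.fn
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "SENS": ratio(tp, tp + fn),
        "SPEC": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "ACC": 100.0 * (tp + tn) / total,
    }


def mann_whitney_auc(scores, y_true) -> float:
    """AUC as P(score+ > score-) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_true, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in the validation set")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# fold construction

def _patient_frame(table: FeatureTable, y: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"patient": table.patient_ids.values, "y": y})
    pat = df.groupby("patient")["y"].first()
    return pat


def _stratified_patient_split(patient_labels: pd.Series, train_ratio: float,
                              rng: np.random.Generator) -> tuple[set, set]:
    """Random stratified split of patients; every class keeps at least one
    patient on each side."""
    val: list = []
    train: list = []
    for cls in np.unique(patient_labels.values):
        ids = patient_labels.index[patient_labels.values == cls].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_val = max(1, int(round((1.0 - train_ratio) * len(ids))))
        if n_val >= len(ids):
            raise ValueError(f"class {cls}: too few patients ({len(ids)}) to stratify")
        val.extend(ids[:n_val])
        train.extend(ids[n_val:])
    return set(train), set(val)


def _run_fold(
    fold: int,
    features: pd.DataFrame,
    y: np.ndarray,
    patients: np.ndarray,
    plan: PreprocessPlan,
    member_configs,
    train_ratio: float,
    seed: int,
    score: str,
) -> FoldResult:
    split_rng = np.random.default_rng(np.random.SeedSequence((seed, fold, 0)))
    prep_seed = int(np.random.SeedSequence((seed, fold, 1)).generate_state(1)[0] % (2**31))
    model_seed = int(np.random.SeedSequence((seed, fold, 2)).generate_state(1)[0] % (2**31))

    pat_labels = pd.Series(y, index=patients).groupby(level=0).first()
    train_p, val_p = _stratified_patient_split(pat_labels, train_ratio, split_rng)
    in_train = np.isin(patients, list(train_p))
    in_val = np.isin(patients, list(val_p))

    X_tr, y_tr, synthetic, selected, _audit = preprocess_fold(
        features.loc[in_train], y[in_train], plan, seed=prep_seed
    )
    selected = selected if selected is not None else list(features.columns)
    X_val = features.loc[in_val, selected]
    y_val = y[in_val]

    model = MajorityVoteForest(member_configs, random_state=model_seed).fit(X_tr, y_tr)
    y_hat = model.predict(X_val)
    scores = (model.mean_member_proba(X_val) if score == "mean_proba"
              else model.vote_fraction(X_val))

    tp = int(((y_hat == 1) & (y_val == 1)).sum())
    fp = int(((y_hat == 1) & (y_val == 0)).sum())
    tn = int(((y_hat == 0) & (y_val == 0)).sum())
    fn = int(((y_hat == 0) & (y_val == 1)).sum())
    return FoldResult(fold, tp, fp, tn, fn, scores, y_val, selected, seed,
                      val_patients=tuple(sorted(val_p)),
                      n_synthetic_train=int(synthetic.sum()))


def monte_carlo_cv(
    table: FeatureTable,
    label_name: str,
    plan: PreprocessPlan | None = None,
    member_configs=DEFAULT_MEMBER_CONFIGS,
    n_folds: int = 100,
    train_ratio: float = 0.9,
    seed: int = 0,
    score: str = "vote_fraction",
    _permute_labels: bool = False,
) -> ModelReport:
    """Monte Carlo cross-validation of one predictive model.

    Rows whose label is NA are dropped first. Each of the ``n_folds`` folds
    re-splits patients 90/10 (stratified by class), preprocesses the
    training rows with ``plan``, trains the ensemble and scores validation.
    """
    plan = plan if plan is not None else PreprocessPlan.none()
    sub = table.rows_with_label(label_name)
    y_all = sub.labels[label_name].to_numpy(dtype=float)
    counts = pd.Series(y_all).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(f"label {label_name!r}: need >= 2 lesions per class")

    patients = sub.patient_ids.to_numpy()
    folds = []
    for f in range(n_folds):
        y = y_all
        if _permute_labels:
            # fold-specific permutation of the patient-level labels, so twin
            # lesions stay consistent under the sham
            perm_rng = np.random.default_rng(np.random.SeedSequence((seed, f, 3)))
            uniq = pd.unique(patients)
            pat_y = pd.Series(y_all, index=patients).groupby(level=0).first()
            permuted = pd.Series(
                pat_y.loc[uniq].to_numpy()[perm_rng.permutation(len(uniq))], index=uniq
            )
            y = permuted.loc[patients].to_numpy()
        folds.append(
            _run_fold(f, sub.features, y, patients, plan, member_configs,
                      train_ratio, seed, score)
        )
    return ModelReport(label_name, folds, plan, sham=_permute_labels)


def sham_analysis(table, label_name, plan=None, member_configs=DEFAULT_MEMBER_CONFIGS,
                  n_folds: int = 100, train_ratio: float = 0.9, seed: int = 0,
                  score: str = "vote_fraction") -> ModelReport:
    """Chance-level control: the full pipeline on randomly permuted labels.

    Labels are re-permuted once per fold before splitting; everything else is
    identical to ``monte_carlo_cv``. On any cohort the mean fold AUC should
    land near 0.5.
    """
    return monte_carlo_cv(table, label_name, plan, member_configs, n_folds,
                          train_ratio, seed, score, _permute_labels=True)


def feature_occurrence(report: ModelReport) -> dict[str, int]:
    """Folds (0..n_folds) in which each feature entered the selected top-n,
    sorted by decreasing occurrence."""
    counts: dict[str, int] = {}
    for f in report.folds:
        for name in f.selected_features:
            counts[name] = counts.get(name, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
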