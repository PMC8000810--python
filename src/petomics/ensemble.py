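"""Majority-vote ensemble of five differently configured random forests.

Mixing several forest configurations and deciding by majority vote damps
the sensitivity of the result to any single hyperparameter choice — useful
on small clinical cohorts where one configuration can win or lose a fold by
chance. The ensemble is a full sklearn classifier: ``fit`` / ``predict`` /
``predict_proba`` / ``get_params``, so it composes with pipelines and model
selection.
"""

from __future__ import annotations

import hashlib

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

#: five forest configurations varying tree count, depth and split width
DEFAULT_MEMBER_CONFIGS = (
    {"n_estimators": 100, "max_depth": None, "max_features": "sqrt", "min_samples_leaf": 1},
    {"n_estimators": 200, "max_depth": None, "max_features": "sqrt", "min_samples_leaf": 1},
    {"n_estimators": 100, "max_depth": 8, "max_features": "sqrt", "min_samples_leaf": 1},
    {"n_estimators": 200, "max_depth": None, "max_features": 0.3, "min_samples_leaf": 1},
    {"n_estimators": 100, "max_depth": 8, "max_features": 0.3, "min_samples_leaf": 2},
)


class MajorityVoteForest(ClassifierMixin, BaseEstimator):
    """Five independently seeded random forests deciding by majority vote.

    The decision label is the majority of the five hard votes (five voters,
    so no ties on binary problems); the continuous score used for ROC
    analysis is the fraction of positive votes — five discrete levels,
    faithful to a hard-voting ensemble.

    Parameters
    ----------
    member_configs : sequence of 5 dicts
        Keyword arguments for each ``RandomForestClassifier`` member.
    random_state : int or None
        Seeds the five members with distinct derived streams.
    """

    def __init__(self, member_configs=DEFAULT_MEMBER_CONFIGS, random_state=None):
        self.member_configs = member_configs
        self.random_state = random_state

    def fit(self, X, y):
        if len(self.member_configs) != 5:
            raise ValueError("the ensemble takes exactly 5 member configurations")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        seeds = np.random.SeedSequence(self.random_state).generate_state(5) % (2**31)
        self.members_ = [
            RandomForestClassifier(random_state=int(seeds[k]), **cfg).fit(X, y)
            for k, cfg in enumerate(self.member_configs)
        ]
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = self._fingerprint(X, y)
        return self

    def _fingerprint(self, X, y) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(X).tobytes())
        h.update(np.ascontiguousarray(y).tobytes())
        h.update(repr(self.member_configs).encode())
        h.update(repr(self.random_state).encode())
        return h.hexdigest()[:16]

    def _votes(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: trained on {self.n_features_in_}, got {X.shape[1]}"
            )
        return np.stack([m.predict(X) for m in self.members_])

    def predict(self, X) -> np.ndarray:
        votes = self._votes(X)
        positive = self.classes_[-1]
        frac = (votes == positive).mean(axis=0)
        return np.where(frac > 0.5, self.classes_[-1], self.classes_[0])

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of the five members voting for the positive class."""
        votes = self._votes(X)
        return (votes == self.classes_[-1]).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        frac = self.vote_fraction(X)
        return np.column_stack([1.0 - frac, frac])

    def mean_member_proba(self, X) -> np.ndarray:
        """Average of the members' own class-1 probabilities (config
        alternative to the hard-vote fraction for ROC scoring)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=np.float64)
        return np.mean([m.predict_proba(X)[:, -1] for m in self.members_], axis=0)


def train_ensemble(X, y, member_configs=DEFAULT_MEMBER_CONFIGS, random_state=None) -> MajorityVoteForest:
    return MajorityVoteForest(member_configs, random_state).fit(X, y)


def predict_vote(ensemble: MajorityVoteForest, X) -> tuple[np.ndarray, np.ndarray]:
    """(majority labels, positive-vote fractions) for a fitted ensemble."""
    return ensemble.predict(X), ensemble.vote_fraction(X)
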