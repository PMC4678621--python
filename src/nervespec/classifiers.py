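"""Binary tissue classifiers: RBF-kernel SVM, PLS-DA, and a Gini-grown
classification tree. The positive class is always fascicular nerve.

SVM uses conventional default hyperparameters (C = 1, gamma =
1/n_features) and expects standardised features. PLS-DA regresses a
0/1-coded class response on the spectra directly (no prior feature
extraction), keeps 10 latent variables by default, and thresholds the
predicted score with a two-Gaussian discriminant: class-conditional
normal densities are estimated from the training scores and the
decision boundary is the prior-weighted equal-posterior point between
the class score means, falling back to the midpoint of the means when a
variance is degenerate. CART grows a Gini-impurity tree with a minimum
leaf size of 5 and cost-complexity pruning chosen by 5-fold
cross-validation inside the training partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_METHODS = ("svm_rbf", "plsda", "cart")


@dataclass
class TrainedClassifier:
    """Fitted classifier plus the feature contract it was trained under."""

    method: str
    estimator: Any
    feature_names: list[str]
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def _check(self, X: np.ndarray, feature_names: list[str] | None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if feature_names is not None:
            names = list(feature_names)
            if names != self.feature_names:
                if sorted(names) != sorted(self.feature_names):
                    raise ValueError("feature names do not match training contract")
                # permuted columns: reorder to the training layout
                order = [names.index(n) for n in self.feature_names]
                X = X[:, order]
        return X


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2 or not set(classes) <= {0, 1}:
        raise ValueError("labels must contain both classes coded 0/1")
    return y


def train_svm_rbf(X_train, y_train, feature_names: list[str],
                  C: float = 1.0, gamma: float | str = "auto",
                  ) -> TrainedClassifier:
    """Soft-margin RBF SVM; gamma='auto' is 1/n_features."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = _check_binary(y_train)
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(X, y)
    return TrainedClassifier("svm_rbf", clf, list(feature_names),
                             {"C": C, "gamma": gamma})


class _PLSDA:
    """PLS regression of the 0/1 response + Gaussian discriminant threshold."""

    def __init__(self, n_latent: int):
        self.n_latent = n_latent

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PLSDA":
        rank = min(X.shape[0] - 1, X.shape[1])
        if self.n_latent > rank:
            raise ValueError(
                f"n_latent={self.n_latent} exceeds the training-data rank {rank}")
        self.pls = PLSRegression(n_components=self.n_latent, scale=False)
        self.pls.fit(X, y.astype(float))
        scores = self.pls.predict(X).ravel()
        self.threshold = self._bayes_threshold(scores, y)
        return self

    @staticmethod
    def _bayes_threshold(scores: np.ndarray, y: np.ndarray) -> float:
        """Equal-posterior point of two Gaussians fitted to the
        class-conditional training scores (prior-weighted); midpoint of
        the class means when a variance is degenerate."""
        s0, s1 = scores[y == 0], scores[y == 1]
        m0, m1 = s0.mean(), s1.mean()
        v0, v1 = s0.var(ddof=1) if s0.size > 1 else 0.0, \
            s1.var(ddof=1) if s1.size > 1 else 0.0
        if v0 <= 0 or v1 <= 0:
            return 0.5 * (m0 + m1)
        p1 = y.mean()
        p0 = 1.0 - p1
        # solve log N(t; m0, v0) + log p0 == log N(t; m1, v1) + log p1
        a = 0.5 * (1.0 / v0 - 1.0 / v1)
        b = m1 / v1 - m0 / v0
        c = (0.5 * (m0 ** 2 / v0 - m1 ** 2 / v1)
             + 0.5 * np.log(v1 / v0) + np.log(p0 / p1))
        if abs(a) < 1e-300:
            return -c / b if b != 0 else 0.5 * (m0 + m1)
        disc = b ** 2 - 4 * a * c
        if disc < 0:
            return 0.5 * (m0 + m1)
        roots = np.array([(-b + np.sqrt(disc)) / (2 * a),
                          (-b - np.sqrt(disc)) / (2 * a)])
        # keep the root between (or nearest to) the class means
        lo, hi = sorted((m0, m1))
        inside = roots[(roots >= lo) & (roots <= hi)]
        if inside.size:
            return float(inside[0])
        return float(roots[np.argmin(np.abs(roots - 0.5 * (m0 + m1)))])

    def predict(self, X: np.ndarray) -> np.ndarray:
        # y is regressed as 0/1, so the positive class always has the
        # higher mean training score and the threshold sits between.
        scores = self.pls.predict(X).ravel()
        return (scores > self.threshold).astype(int)


def train_plsda(X_train, y_train, feature_names: list[str],
                n_latent: int = 10) -> TrainedClassifier:
    """PLS-DA on spectra (or any matrix); see module docstring."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = _check_binary(y_train)
    est = _PLSDA(n_latent).fit(X, y)
    return TrainedClassifier("plsda", est, list(feature_names),
                             {"n_latent": n_latent})


def gini_impurity(proportions) -> float:
    """Unity minus the sum of squared class proportions at a node."""
    p = np.asarray(proportions, dtype=float)
    if p.sum() <= 0:
        raise ValueError("empty node")
    p = p / p.sum()
    return float(1.0 - np.sum(p ** 2))


def train_cart(X_train, y_train, feature_names: list[str],
               min_samples_leaf: int = 5, prune_cv_folds: int = 5,
               random_state: int = 0) -> TrainedClassifier:
    """Gini classification tree with CV-selected cost-complexity pruning."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = _check_binary(y_train)

    base = DecisionTreeClassifier(criterion="gini",
                                  min_samples_leaf=min_samples_leaf,
                                  random_state=random_state)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
    best_alpha = 0.0
    if alphas.size > 1 and np.bincount(y).min() >= prune_cv_folds:
        cv = StratifiedKFold(prune_cv_folds, shuffle=True,
                             random_state=random_state)
        best_score = -np.inf
        for alpha in alphas[:-1]:  # last alpha collapses to the root
            tree = DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=min_samples_leaf,
                ccp_alpha=alpha, random_state=random_state)
            score = cross_val_score(tree, X, y, cv=cv).mean()
            if score > best_score + 1e-12:
                best_score = score
                best_alpha = alpha
    clf = DecisionTreeClassifier(criterion="gini",
                                 min_samples_leaf=min_samples_leaf,
                                 ccp_alpha=best_alpha,
                                 random_state=random_state)
    clf.fit(X, y)
    return TrainedClassifier("cart", clf, list(feature_names),
                             {"min_samples_leaf": min_samples_leaf,
                              "ccp_alpha": float(best_alpha)})


def predict(clf: TrainedClassifier, X, feature_names: list[str] | None = None,
            ) -> np.ndarray:
    """Predict 0/1 labels; enforces the feature-name/width contract."""
    X = clf._check(X, feature_names)
    if X.size == 0:
        return np.zeros(0, dtype=int)
    return np.asarray(clf.estimator.predict(X)).astype(int)
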