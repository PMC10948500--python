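"""Classifier family/variant registry.

Eight classifier families are benchmarked, each through named variants
(27 in total): decision trees (fine/medium/coarse), discriminant analysis
(linear/quadratic), naive Bayes (Gaussian/kernel), SVM (linear, quadratic,
cubic, fine/medium/coarse Gaussian), k-NN (cubic/cosine), ensembles
(boosted, bagged, subspace discriminant, subspace k-NN, RUS-boosted
trees), neural networks (narrow/medium/wide/bi-layered/tri-layered) and
kernel approximation (SVM / logistic regression on random Fourier
features).

The variant names follow common GUI-toolbox presets whose exact
hyperparameters are not standardised; the registry pins each variant to an
explicit, reproducible configuration (documented per entry below) and every
setting can be overridden through ``ClassifierSpec.params``. Families whose
presets standardise their inputs (SVM, k-NN, neural nets, kernel
approximation) get a StandardScaler stage. Inherently binary learners use
one-vs-one multi-class handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "FAMILIES", "all_specs", "make_estimator"]


@dataclass(frozen=True)
class ClassifierSpec:
    """One (family, variant) cell of the registry, with optional
    hyperparameter overrides applied on top of the preset."""

    family: str
    variant: str
    params: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.family}/{self.variant}"


class RandomUndersampleAdaBoost(BaseEstimator, ClassifierMixin):
    """AdaBoost on trees after fit-time random undersampling.

    Stand-in for RUS-boosted trees: every class is randomly undersampled to
    the minority-class count before boosting. On a balanced design the
    resampling is a near no-op, matching the variant's intent.
    """

    def __init__(self, n_estimators=30, max_leaf_nodes=20, random_state=None):
        self.n_estimators = n_estimators
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            keep.append(rng.choice(idx, size=n_min, replace=False))
        keep = np.sort(np.concatenate(keep))
        self.booster_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes, random_state=self.random_state
            ),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )
        self.booster_.fit(X[keep], y[keep])
        self.classes_ = self.booster_.classes_
        return self

    def predict(self, X):
        return self.booster_.predict(X)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature 1-D Gaussian kernel densities.

    Class-conditional densities are products of univariate KDEs with
    Silverman's bandwidth per (class, feature). Vectorised log-likelihood
    evaluation; priors from training frequencies.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.train_ = []
        self.bandwidth_ = []
        self.log_prior_ = []
        for c in self.classes_:
            xc = X[y == c]
            n = xc.shape[0]
            sd = xc.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1e-9
            h = 1.06 * sd * n ** (-1 / 5)  # Silverman
            self.train_.append(xc)
            self.bandwidth_.append(h)
            self.log_prior_.append(np.log(n / X.shape[0]))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], len(self.classes_)))
        for ci, (xc, h, lp) in enumerate(
            zip(self.train_, self.bandwidth_, self.log_prior_)
        ):
            # (test, train, features) differences, feature-wise KDE
            z = (X[:, None, :] - xc[None, :, :]) / h
            dens = np.exp(-0.5 * z**2).mean(axis=1) / (h * np.sqrt(2 * np.pi))
            out[:, ci] = lp + np.log(np.maximum(dens, 1e-300)).sum(axis=1)
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", estimator)])


def _tree(max_leaf_nodes):
    def build(n_features, seed, **kw):
        return DecisionTreeClassifier(
            max_leaf_nodes=kw.pop("max_leaf_nodes", max_leaf_nodes),
            random_state=seed,
            **kw,
        )

    return build


def _svm(kernel, degree=3, scale_factor=None):
    def build(n_features, seed, **kw):
        if scale_factor is None:
            gamma = kw.pop("gamma", "scale")
        else:
            ks = scale_factor * np.sqrt(n_features)  # toolbox kernel scale
            gamma = kw.pop("gamma", 1.0 / ks**2)
        return _scaled(
            SVC(
                kernel=kernel,
                degree=degree,
                gamma=gamma,
                C=kw.pop("C", 1.0),
                decision_function_shape="ovo",
                random_state=seed,
                **kw,
            )
        )

    return build


def _mlp(hidden):
    def build(n_features, seed, **kw):
        return _scaled(
            MLPClassifier(
                hidden_layer_sizes=kw.pop("hidden_layer_sizes", hidden),
                max_iter=kw.pop("max_iter", 400),
                random_state=seed,
                **kw,
            )
        )

    return build


def _kernel_approx(linear_model):
    def build(n_features, seed, **kw):
        expansion = kw.pop("n_components", 2 * n_features)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "rff",
                    RBFSampler(
                        gamma=1.0 / n_features,
                        n_components=expansion,
                        random_state=seed,
                    ),
                ),
                ("clf", linear_model(seed, **kw)),
            ]
        )

    return build


_REGISTRY: dict[tuple[str, str], object] = {
    # decision trees: preset max number of leaves 100 / 20 / 4
    ("decision_tree", "fine"): _tree(100),
    ("decision_tree", "medium"): _tree(20),
    ("decision_tree", "coarse"): _tree(4),
    ("discriminant", "linear"): lambda F, seed, **kw: LinearDiscriminantAnalysis(**kw),
    ("discriminant", "quadratic"): lambda F, seed, **kw: QuadraticDiscriminantAnalysis(
        **kw
    ),
    ("naive_bayes", "gaussian"): lambda F, seed, **kw: GaussianNB(**kw),
    ("naive_bayes", "kernel"): lambda F, seed, **kw: KernelNaiveBayes(**kw),
    ("svm", "linear"): _svm("linear"),
    ("svm", "quadratic"): _svm("poly", degree=2),
    ("svm", "cubic"): _svm("poly", degree=3),
    # Gaussian SVM kernel scales sqrt(F)/4, sqrt(F), 4*sqrt(F)
    ("svm", "fine_gaussian"): _svm("rbf", scale_factor=0.25),
    ("svm", "medium_gaussian"): _svm("rbf", scale_factor=1.0),
    ("svm", "coarse_gaussian"): _svm("rbf", scale_factor=4.0),
    ("knn", "cubic"): lambda F, seed, **kw: _scaled(
        KNeighborsClassifier(
            n_neighbors=kw.pop("n_neighbors", 10), metric="minkowski", p=3, **kw
        )
    ),
    ("knn", "cosine"): lambda F, seed, **kw: _scaled(
        KNeighborsClassifier(
            n_neighbors=kw.pop("n_neighbors", 10), metric="cosine", **kw
        )
    ),
    # ensembles: 30 learners throughout
    ("ensemble", "boosted"): lambda F, seed, **kw: AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
        n_estimators=kw.pop("n_estimators", 30),
        random_state=seed,
        **kw,
    ),
    ("ensemble", "bagged"): lambda F, seed, **kw: RandomForestClassifier(
        n_estimators=kw.pop("n_estimators", 30), random_state=seed, **kw
    ),
    ("ensemble", "subspace_discriminant"): lambda F, seed, **kw: BaggingClassifier(
        estimator=LinearDiscriminantAnalysis(),
        n_estimators=kw.pop("n_estimators", 30),
        bootstrap=False,
        max_features=kw.pop("max_features", 0.5),
        random_state=seed,
        **kw,
    ),
    ("ensemble", "subspace_knn"): lambda F, seed, **kw: BaggingClassifier(
        estimator=KNeighborsClassifier(n_neighbors=1),
        n_estimators=kw.pop("n_estimators", 30),
        bootstrap=False,
        max_features=kw.pop("max_features", 0.5),
        random_state=seed,
        **kw,
    ),
    ("ensemble", "rusboosted_trees"): lambda F, seed, **kw: RandomUndersampleAdaBoost(
        random_state=seed, **kw
    ),
    ("neural_net", "narrow"): _mlp((10,)),
    ("neural_net", "medium"): _mlp((25,)),
    ("neural_net", "wide"): _mlp((100,)),
    ("neural_net", "bilayered"): _mlp((10, 10)),
    ("neural_net", "trilayered"): _mlp((10, 10, 10)),
    ("kernel_approx", "svm"): _kernel_approx(
        lambda seed, **kw: LinearSVC(C=kw.pop("C", 1.0), random_state=seed, **kw)
    ),
    ("kernel_approx", "logistic"): _kernel_approx(
        lambda seed, **kw: LogisticRegression(
            max_iter=kw.pop("max_iter", 1000), random_state=seed, **kw
        )
    ),
}

FAMILIES: tuple[str, ...] = tuple(
    dict.fromkeys(family for family, _ in _REGISTRY)
)


def all_specs(families=None) -> list[ClassifierSpec]:
    """Every registered (family, variant) pair, optionally filtered."""
    return [
        ClassifierSpec(family=f, variant=v)
        for (f, v) in _REGISTRY
        if families is None or f in families
    ]


def make_estimator(spec: ClassifierSpec, n_features: int, random_state: int = 0):
    """Instantiate the scikit-learn estimator for a registry cell."""
    key = (spec.family, spec.variant)
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown classifier spec {spec.family}/{spec.variant}; "
            f"known: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[key](n_features, random_state, **dict(spec.params))
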