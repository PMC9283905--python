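"""nu-SVM classification with nested cross-validated model selection.

The classifier is the nu-parametrized soft-margin SVM (linear or Gaussian
kernel), where ``nu`` upper-bounds the fraction of margin errors and
lower-bounds the fraction of support vectors. Features are conditioned by
total-variance PCA and optionally projected by a metric learner before the
SVM sees them; both transforms are fit strictly on the training side of
every split.

Model selection follows a nested stratified 10-fold scheme: for each outer
training partition, every candidate configuration (d_pc, p, nu and, for the
Gaussian kernel, sigma_SVM) is scored by inner 10-fold cross-validation with
all stages refit per inner fold; the best mean inner accuracy wins (ties
prefer the simpler model: smaller d_pc, then p, then nu, then larger
sigma_SVM), is refit on the full outer-train partition, and is scored once
on the held-out outer fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import NuSVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import TotalVariancePCA
from .learners import CEML, EGML, NCA, EuclideanBaseline

logger = logging.getLogger(__name__)

__all__ = [
    "NuSVM",
    "HyperGrid",
    "CVResult",
    "nested_cv",
    "paired_fold_test",
    "make_learner",
]


class NuSVM(ClassifierMixin, BaseEstimator):
    """nu-SVM with class labels {1, 2} and an explicit sign convention.

    The decision value ``z`` treats class 1 as the positive class:
    ``z > 0`` predicts 1, ``z <= 0`` predicts 2 (ties go to class 2).
    ``kernel='gaussian'`` uses ``exp(-||x - x'||^2 / (2 sigma^2))``.
    """

    def __init__(self, nu=0.5, kernel="linear", sigma=1.0):
        self.nu = nu
        self.kernel = kernel
        self.sigma = sigma

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"kernel must be 'linear' or 'gaussian', got {self.kernel!r}")
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must lie in (0, 1], got {self.nu}")
        classes = np.unique(y)
        if not np.array_equal(classes, [1, 2]):
            raise ValueError(f"labels must be exactly {{1, 2}}, got {classes}")
        if self.kernel == "gaussian":
            if self.sigma <= 0:
                raise ValueError(f"sigma must be positive, got {self.sigma}")
            svc = NuSVC(nu=self.nu, kernel="rbf", gamma=1.0 / (2.0 * self.sigma**2))
        else:
            svc = NuSVC(nu=self.nu, kernel="linear")
        t = np.where(y == 1, 1, -1)
        try:
            svc.fit(X, t)
        except ValueError as exc:
            if "nu" in str(exc).lower():
                raise ValueError(
                    f"nu={self.nu} is infeasible for this class balance: {exc}"
                ) from exc
            raise
        self.svc_ = svc
        self.classes_ = np.array([1, 2])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X)
        # sklearn orders classes [-1, +1] and signs the decision toward +1,
        # which is our class 1
        return self.svc_.decision_function(X)

    def predict(self, X):
        z = self.decision_function(X)
        return np.where(z > 0, 1, 2)


@dataclass(frozen=True)
class HyperGrid:
    """Search grids for the nested selection.

    ``sigma_svm_scales`` are multipliers ``c`` giving Gaussian SVM
    bandwidths ``sigma = sqrt(c * p)`` (with ``p = d_pc`` for the Euclidean
    baseline, whose SVM sees the conditioned PCs directly).
    """

    d_pc: tuple = (30, "rank")
    p: tuple[int, ...] = (3, 10, 100)
    nu: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.8)
    sigma_svm_scales: tuple[float, ...] = (5.0, 1.0, 0.5, 0.25, 0.05)

    def __post_init__(self):
        if not (self.d_pc and self.p and self.nu and self.sigma_svm_scales):
            raise ValueError("every grid must be non-empty")

    @classmethod
    def for_feature(cls, feature_kind: str) -> "HyperGrid":
        """Default d_pc options by feature kind: the low-band Fourier
        features (d = 189) search {30, 189}; the high-dimensional kinds
        search {300, rank}."""
        if feature_kind == "F1B":
            return cls(d_pc=(30, 189))
        if feature_kind in ("F1A", "F2"):
            return cls(d_pc=(300, "rank"))
        raise ValueError(f"unknown feature kind {feature_kind!r}")


@dataclass
class CVResult:
    """Outer-fold accuracies and the per-fold selected configuration."""

    fold_accuracies: np.ndarray
    chosen_params: list[dict]
    learner: str
    svm_kind: str
    seed: int
    n_folds: int = 10
    extras: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def make_learner(name: str, p: int, seed: int, **kwargs):
    """Instantiate a metric learner by name ('euclidean' returns identity)."""
    name = name.lower()
    if name == "euclidean":
        return EuclideanBaseline()
    cls = {"ceml": CEML, "egml": EGML, "nca": NCA}.get(name)
    if cls is None:
        raise ValueError(
            f"unknown learner {name!r}; choose euclidean, ceml, egml or nca"
        )
    return cls(n_components=p, random_state=seed, **kwargs)


def _candidates(grid: HyperGrid, learner: str, svm_kind: str):
    p_values = (None,) if learner == "euclidean" else grid.p
    sig_values = grid.sigma_svm_scales if svm_kind == "gaussian" else (None,)
    for d_pc, p, nu, sc in itertools.product(grid.d_pc, p_values, grid.nu, sig_values):
        yield {"d_pc": d_pc, "p": p, "nu": nu, "sigma_scale": sc}


def _fit_score(cfg, learner_name, svm_kind, seed, X_tr, y_tr, X_te, y_te, learner_kwargs):
    """Fit PCA -> learner -> SVM on the train side, return test accuracy."""
    d_pc = cfg["d_pc"]
    if d_pc != "rank":
        d_pc = min(int(d_pc), min(X_tr.shape[0] - 1, X_tr.shape[1]))
    pca = TotalVariancePCA(n_components=d_pc).fit(X_tr)
    Z_tr, Z_te = pca.transform(X_tr), pca.transform(X_te)

    if learner_name == "euclidean":
        learner = EuclideanBaseline().fit(Z_tr, y_tr)
        p_eff = Z_tr.shape[1]
    else:
        p_eff = min(int(cfg["p"]), Z_tr.shape[1])
        learner = make_learner(learner_name, p_eff, seed, **learner_kwargs)
        learner.fit(Z_tr, y_tr)
    P_tr, P_te = learner.transform(Z_tr), learner.transform(Z_te)

    if svm_kind == "gaussian":
        sigma = float(np.sqrt(cfg["sigma_scale"] * p_eff))
        svm = NuSVM(nu=cfg["nu"], kernel="gaussian", sigma=sigma)
    else:
        svm = NuSVM(nu=cfg["nu"], kernel="linear")
    svm.fit(P_tr, y_tr)
    return float(np.mean(svm.predict(P_te) == y_te))


def _tie_break_key(cfg):
    d_pc = np.inf if cfg["d_pc"] == "rank" else cfg["d_pc"]
    p = 0 if cfg["p"] is None else cfg["p"]
    sc = 0.0 if cfg["sigma_scale"] is None else -cfg["sigma_scale"]
    return (d_pc, p, cfg["nu"], sc)


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    learner: str = "euclidean",
    grid: HyperGrid | None = None,
    svm_kind: str = "linear",
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
    learner_kwargs: dict | None = None,
) -> CVResult:
    """Nested stratified k-fold evaluation of one learner/SVM combination.

    Every transform is refit inside each split; no information crosses from
    a test partition into any fitted stage. A single-candidate grid skips
    the inner loop (nothing to select). Inner folds where the nu value is
    infeasible for the class balance are skipped and logged; a candidate
    infeasible on every inner fold is discarded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 20:
        raise ValueError(f"need at least 20 samples for nested CV, got {len(y)}")
    grid = grid or HyperGrid()
    learner_kwargs = learner_kwargs or {}
    candidates = list(_candidates(grid, learner, svm_kind))

    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    fold_acc, chosen = [], []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if len(candidates) == 1:
            best = candidates[0]
        else:
            inner = StratifiedKFold(
                n_splits=n_inner, shuffle=True, random_state=seed + 1000 + k
            )
            splits = list(inner.split(X_tr, y_tr))
            scored = []
            for cfg in candidates:
                accs = []
                for itr, ite in splits:
                    try:
                        accs.append(
                            _fit_score(
                                cfg, learner, svm_kind, seed,
                                X_tr[itr], y_tr[itr], X_tr[ite], y_tr[ite],
                                learner_kwargs,
                            )
                        )
                    except ValueError as exc:
                        logger.info(
                            "inner fold skipped for %s: %s", cfg, exc
                        )
                if accs:
                    scored.append((np.mean(accs), cfg))
            if not scored:
                raise ValueError(
                    "no grid candidate is feasible for the inner folds"
                )
            best_acc = max(s for s, _ in scored)
            tied = [c for s, c in scored if s >= best_acc - 1e-12]
            best = min(tied, key=_tie_break_key)
        acc = _fit_score(
            best, learner, svm_kind, seed, X_tr, y_tr, X[te], y[te], learner_kwargs
        )
        fold_acc.append(acc)
        chosen.append(dict(best))
    return CVResult(
        fold_accuracies=np.asarray(fold_acc),
        chosen_params=chosen,
        learner=learner,
        svm_kind=svm_kind,
        seed=seed,
        n_folds=n_outer,
    )


def paired_fold_test(res_a: CVResult, res_b: CVResult) -> tuple[float, float]:
    """Two-sided paired t-test across matched outer-fold accuracies.

    Both results must come from the same fold assignment (same seed and
    fold count). A zero-variance nonzero difference drives ``p`` to the
    degenerate 0 limit, which scipy reports as 0.0; identical vectors give
    ``t = 0, p = 1``.
    """
    if res_a.seed != res_b.seed or res_a.n_folds != res_b.n_folds:
        raise ValueError(
            "paired comparison requires matching folds (same seed and fold count)"
        )
    a, b = res_a.fold_accuracies, res_b.fold_accuracies
    if np.allclose(a, b):
        return 0.0, 1.0
    d = a - b
    if np.std(d, ddof=1) == 0:
        logger.warning("paired_fold_test: zero-variance nonzero difference")
        return float(np.inf) * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
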