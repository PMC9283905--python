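"""Supervised linear metric learners: CEML, EGML, NCA, and an identity baseline.

All learners fit a linear map ``A`` (d_in x p) so that Euclidean distance in
the projected space ``Y = X A`` reflects class membership:

* **CEML** (conditional-entropy metric learning) minimizes the matrix-based
  conditional entropy ``S_alpha(L | Y)`` of the labels given the projection,
  subject to ``tr(A^T A) = p`` (the trace constraint prevents the kernel from
  trivially saturating by blowing up the scale of ``Y``).
* **EGML** (entropy-gap metric learning) maximizes the entropy gap
  ``E_pi[S_alpha(L, Y_pi)] - S_alpha(L, Y)`` — the joint entropy surplus of
  randomly re-paired data over the observed pairing. The gap vanishes when
  the projected scale is far from the kernel bandwidth in either direction,
  so no trace constraint is needed: the objective self-selects the scale.
* **NCA** (neighborhood component analysis) maximizes the expected
  leave-one-out accuracy of a soft (softmax-weighted) nearest-neighbor
  classifier in the projected space.

Each is a scikit-learn transformer (``fit``/``transform``); the learned map
is exposed as ``A_`` and the fit is deterministic given ``random_state``.
Optimization is full-batch gradient descent with Armijo backtracking; CEML
uses the tangent-projected gradient and retracts onto the trace sphere after
every step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .entropy import (
    DEFAULT_ALPHA,
    DEFAULT_EIG_CLIP,
    gaussian_gram,
    label_gram,
)

__all__ = [
    "CEML",
    "EGML",
    "NCA",
    "EuclideanBaseline",
    "project",
    "ceml_objective_grad",
    "egml_objective_grad",
    "nca_objective_grad",
    "save_projection",
    "load_projection",
]


# ---------------------------------------------------------------------------
# objective values and analytic gradients
# ---------------------------------------------------------------------------


def _entropy_and_gram_grad(
    G: np.ndarray,
    mask: np.ndarray | None,
    alpha: float,
    eig_clip: float,
    need_grad: bool,
) -> tuple[float, np.ndarray | None]:
    """S_alpha of (mask o G)/tr(mask o G) and, optionally, dS/dG.

    ``mask`` is an optional symmetric Hadamard factor (e.g. a label Gram
    matrix); ``None`` means the marginal entropy of ``G`` itself. The
    gradient of the unit-trace normalization and matrix power is

        dS/dM = alpha / ((1 - alpha) t tr(N^alpha)) (N^(alpha-1) - tr(N^alpha) I)

    with ``M = mask o G``, ``t = tr(M)`` and ``N = M / t``; the Hadamard
    factor then passes through element-wise.
    """
    M = G if mask is None else mask * G
    t = float(np.trace(M))
    if t <= 0:
        raise ValueError("Gram matrix trace must be positive")
    N = M / t
    if need_grad:
        w, V = np.linalg.eigh(N)
    else:
        w = np.linalg.eigvalsh(N)
        V = None
    keep = w > eig_clip
    lam = w[keep]
    tr_a = float(np.sum(lam**alpha))
    S = float(np.log(tr_a) / (1.0 - alpha))
    if not need_grad:
        return S, None
    Vk = V[:, keep]
    Npow = (Vk * lam ** (alpha - 1.0)) @ Vk.T
    dS_dM = (alpha / ((1.0 - alpha) * t * tr_a)) * (
        Npow - tr_a * np.eye(N.shape[0])
    )
    dS_dG = dS_dM if mask is None else dS_dM * mask
    return S, dS_dG


def _gram_grad_to_A(
    X: np.ndarray, Y: np.ndarray, G: np.ndarray, W: np.ndarray, sigma: float
) -> np.ndarray:
    """Chain dObj/dG through the Gaussian kernel and ``Y = X A`` to dObj/dA."""
    M = (W + W.T) * G
    grad_Y = -(1.0 / (sigma * sigma)) * (M.sum(axis=1)[:, None] * Y - M @ Y)
    return X.T @ grad_Y


def ceml_objective_grad(
    A: np.ndarray,
    X: np.ndarray,
    labels: np.ndarray,
    sigma: float,
    alpha: float = DEFAULT_ALPHA,
    eig_clip: float = DEFAULT_EIG_CLIP,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Conditional entropy S_alpha(L | X A) and its gradient w.r.t. ``A``."""
    K_L = label_gram(labels)
    Y = X @ A
    G = gaussian_gram(Y, sigma)
    Sj, Wj = _entropy_and_gram_grad(G, K_L, alpha, eig_clip, need_grad)
    Sm, Wm = _entropy_and_gram_grad(G, None, alpha, eig_clip, need_grad)
    val = Sj - Sm
    if not need_grad:
        return val, None
    return val, _gram_grad_to_A(X, Y, G, Wj - Wm, sigma)


def egml_objective_grad(
    A: np.ndarray,
    X: np.ndarray,
    labels: np.ndarray,
    sigma: float,
    perms: list[np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    eig_clip: float = DEFAULT_EIG_CLIP,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Entropy gap EG_alpha(L; X A) for fixed permutations, and its gradient.

    A permutation of the samples inside the joint is equivalent to the
    inverse permutation applied to the label Gram matrix (a conjugation that
    leaves the spectrum alone), which keeps the kernel chain rule identical
    for every term.
    """
    K_L = label_gram(labels)
    Y = X @ A
    G = gaussian_gram(Y, sigma)
    Sb, Wb = _entropy_and_gram_grad(G, K_L, alpha, eig_clip, need_grad)
    val = 0.0
    Wsum = np.zeros_like(G) if need_grad else None
    for p in perms:
        q = np.argsort(p)
        K_Lq = K_L[np.ix_(q, q)]
        Sp, Wp = _entropy_and_gram_grad(G, K_Lq, alpha, eig_clip, need_grad)
        val += Sp
        if need_grad:
            Wsum += Wp
    val = val / len(perms) - Sb
    if not need_grad:
        return val, None
    W = Wsum / len(perms) - Wb
    return val, _gram_grad_to_A(X, Y, G, W, sigma)


def nca_objective_grad(
    A: np.ndarray,
    X: np.ndarray,
    labels: np.ndarray,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """NCA objective sum_i P_i (expected soft LOO accuracy) and gradient.

    ``P_ij = softmax_j(-||A^T x_i - A^T x_j||^2)`` with ``P_ii = 0``; the
    value returned is the sum over samples of the probability mass assigned
    to same-class neighbors.
    """
    labels = np.asarray(labels)
    Y = X @ A
    sq = np.sum(Y * Y, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    logits = -d2
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    p_i = np.sum(P * same, axis=1)
    val = float(p_i.sum())
    if not need_grad:
        return val, None
    W = P * (p_i[:, None] - same)
    S = W + W.T
    grad_Y = 2.0 * (S.sum(axis=1)[:, None] * Y - S @ Y)
    return val, X.T @ grad_Y


# ---------------------------------------------------------------------------
# shared optimizer
# ---------------------------------------------------------------------------

_ARMIJO_C = 1e-4
_BACKTRACK = 0.5
_MAX_BACKTRACKS = 60


def _descend(fun, A, retract, tangent, max_iter, tol):
    """Backtracking gradient descent; ``fun(A, need_grad)`` is minimized.

    ``retract`` maps an arbitrary matrix back onto the feasible set (identity
    for unconstrained learners); ``tangent`` projects the Euclidean gradient
    onto the feasible directions at ``A``.
    """
    obj, grad = fun(A, True)
    trace = [(0, obj)]
    step = 1.0
    converged = False
    for it in range(1, max_iter + 1):
        d = tangent(A, grad)
        gn2 = float(np.vdot(d, d))
        if gn2 <= 0.0 or not np.isfinite(gn2):
            converged = True
            break
        s = step
        accepted = False
        for _ in range(_MAX_BACKTRACKS):
            A_try = retract(A - s * d)
            obj_try, _ = fun(A_try, False)
            if obj_try <= obj - _ARMIJO_C * s * gn2:
                accepted = True
                break
            s *= _BACKTRACK
        if not accepted:
            converged = True
            break
        rel = abs(obj - obj_try) / max(1.0, abs(obj))
        A = A_try
        obj, grad = fun(A, True)
        trace.append((it, obj))
        step = min(s / _BACKTRACK, 1e6)
        if rel < tol:
            converged = True
            break
    return A, trace, converged


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _BaseMetricLearner(TransformerMixin, BaseEstimator):
    """Shared fitting machinery; subclasses define the objective."""

    _maximize = False

    def __init__(
        self,
        n_components=2,
        max_iter=500,
        tol=1e-6,
        init="pca_directions",
        random_state=0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    # subclass hooks -------------------------------------------------------
    def _make_objective(self, X, y, rng):
        raise NotImplementedError

    def _retract(self, A):
        return A

    def _tangent(self, A, grad):
        return grad

    def _scale_init(self, A, X):
        return A

    # ---------------------------------------------------------------------
    def _init_A(self, X, rng):
        d = X.shape[1]
        p = self.n_components
        if self.init == "pca_directions":
            Xc = X - X.mean(axis=0)
            _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
            if Vt.shape[0] < p:
                raise ValueError(
                    f"rank of X ({Vt.shape[0]}) is below n_components={p}"
                )
            A = Vt[:p].T.copy()
        elif self.init == "random_orthonormal":
            Q, _ = np.linalg.qr(rng.standard_normal((d, p)))
            A = Q[:, :p]
        else:
            raise ValueError(f"unknown init {self.init!r}")
        return self._scale_init(A, X)

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y), dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "metric learning needs at least 2 classes; the objective is "
                "degenerate for single-class data"
            )
        p = self.n_components
        if not 1 <= p <= X.shape[1]:
            raise ValueError(
                f"n_components={p} must be in [1, n_features={X.shape[1]}]"
            )
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")
        rng = np.random.default_rng(self.random_state)
        fun = self._make_objective(X, y, rng)
        if self._maximize:
            inner = fun

            def fun(A, need_grad):  # noqa: F811 - sense flip
                v, g = inner(A, need_grad)
                return -v, None if g is None else -g

        A0 = self._init_A(X, rng)
        A, trace, converged = _descend(
            fun, A0, self._retract, self._tangent, self.max_iter, self.tol
        )
        sense = -1.0 if self._maximize else 1.0
        self.A_ = A
        self.n_features_in_ = X.shape[1]
        self.classes_ = classes
        self.converged_ = converged
        self.n_iter_ = trace[-1][0]
        self.objective_trace_ = [(it, sense * v) for it, v in trace]
        self.objective_ = self.objective_trace_[-1][1]
        return self

    def transform(self, X):
        check_is_fitted(self, "A_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.A_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, the learned map expects "
                f"{self.A_.shape[0]}"
            )
        return X @ self.A_

    def _resolved_sigma(self):
        sigma = getattr(self, "sigma", None)
        return float(np.sqrt(self.n_components / 2.0)) if sigma is None else sigma


class CEML(_BaseMetricLearner):
    """Conditional-entropy metric learning with the trace constraint.

    Parameters
    ----------
    n_components : int
        Output dimension ``p``.
    sigma : float or None
        Gaussian kernel bandwidth on the projected space; ``None`` selects
        ``sqrt(p / 2)``, matched to inputs whose total variance has been
        normalized to the dimension count.
    alpha : float
        Entropy order, must exceed 1; 1.01 approximates Shannon behavior.
    """

    def __init__(
        self,
        n_components=2,
        sigma=None,
        alpha=DEFAULT_ALPHA,
        eig_clip=DEFAULT_EIG_CLIP,
        max_iter=500,
        tol=1e-6,
        init="pca_directions",
        random_state=0,
    ):
        super().__init__(n_components, max_iter, tol, init, random_state)
        self.sigma = sigma
        self.alpha = alpha
        self.eig_clip = eig_clip

    def _make_objective(self, X, y, rng):
        sigma = self._resolved_sigma()
        self.sigma_ = sigma

        def fun(A, need_grad):
            return ceml_objective_grad(
                A, X, y, sigma, self.alpha, self.eig_clip, need_grad
            )

        return fun

    def _retract(self, A):
        # rescale onto the sphere tr(A^T A) = p
        t = float(np.sum(A * A))
        if t <= 0:
            raise ValueError("projection collapsed to zero during optimization")
        return A * np.sqrt(self.n_components / t)

    def _tangent(self, A, grad):
        # remove the radial component; pure rescaling cannot change the
        # constrained objective
        return grad - (np.vdot(grad, A) / self.n_components) * A


class EGML(_BaseMetricLearner):
    """Entropy-gap metric learning (unconstrained, scale-self-tuning).

    The expectation over sample-label re-pairings is approximated with
    ``n_perm`` permutations drawn once per fit from ``random_state``, so the
    objective is deterministic within a fit and across reruns.
    """

    _maximize = True

    def __init__(
        self,
        n_components=2,
        sigma=None,
        alpha=DEFAULT_ALPHA,
        eig_clip=DEFAULT_EIG_CLIP,
        n_perm=10,
        max_iter=500,
        tol=1e-6,
        init="pca_directions",
        random_state=0,
    ):
        super().__init__(n_components, max_iter, tol, init, random_state)
        self.sigma = sigma
        self.alpha = alpha
        self.eig_clip = eig_clip
        self.n_perm = n_perm

    def _make_objective(self, X, y, rng):
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be at least 1, got {self.n_perm}")
        sigma = self._resolved_sigma()
        self.sigma_ = sigma
        n = X.shape[0]
        perms = [rng.permutation(n) for _ in range(self.n_perm)]

        def fun(A, need_grad):
            return egml_objective_grad(
                A, X, y, sigma, perms, self.alpha, self.eig_clip, need_grad
            )

        return fun

    def _scale_init(self, A, X):
        # start where the gap is alive: mean projected pairwise squared
        # distance matched to 2 sigma^2 (the gap closes at both scale
        # extremes, where gradients vanish)
        sigma = self._resolved_sigma()
        Y = X @ A
        sq = np.sum(Y * Y, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
        m = float(np.sum(np.triu(d2, 1))) / (len(Y) * (len(Y) - 1) / 2)
        if m <= 0:
            return A
        return A * np.sqrt(2.0 * sigma * sigma / m)


class NCA(_BaseMetricLearner):
    """Neighborhood component analysis: soft leave-one-out k-nn accuracy."""

    _maximize = True

    def __init__(
        self,
        n_components=2,
        max_iter=500,
        tol=1e-6,
        init="pca_directions",
        random_state=0,
    ):
        super().__init__(n_components, max_iter, tol, init, random_state)

    def _make_objective(self, X, y, rng):
        def fun(A, need_grad):
            return nca_objective_grad(A, X, y, need_grad)

        return fun


class EuclideanBaseline(TransformerMixin, BaseEstimator):
    """Identity map: no metric is learned, distances stay Euclidean."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        d = X.shape[1]
        self.A_ = np.eye(d)
        self.n_features_in_ = d
        self.converged_ = True
        self.objective_trace_ = []
        return self

    def transform(self, X):
        check_is_fitted(self, "A_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.A_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.A_.shape[0]}"
            )
        return X @ self.A_


def project(X: np.ndarray, learner) -> np.ndarray:
    """Apply a fitted learner's linear map: ``Y = X A``."""
    return learner.transform(X)


# ---------------------------------------------------------------------------
# serialization: JSON metadata + whitespace-delimited matrix sidecar
# ---------------------------------------------------------------------------

_LEARNER_NAMES = {
    "CEML": CEML,
    "EGML": EGML,
    "NCA": NCA,
    "EuclideanBaseline": EuclideanBaseline,
}


def save_projection(learner, path) -> None:
    """Write a fitted learner's map and provenance to ``path`` (+ ``.mat.txt``)."""
    check_is_fitted(learner, "A_")
    path = Path(path)
    meta = {
        "learner": type(learner).__name__,
        "params": {
            k: v for k, v in learner.get_params().items() if np.isscalar(v) or v is None
        },
        "shape": list(learner.A_.shape),
        "converged": bool(learner.converged_),
        "matrix_file": path.name + ".mat.txt",
    }
    path.write_text(json.dumps(meta, indent=2))
    np.savetxt(path.with_name(meta["matrix_file"]), learner.A_)


def load_projection(path):
    """Load a projection saved by :func:`save_projection` (unfitted state is
    reconstructed; only ``A_`` and provenance are restored)."""
    path = Path(path)
    meta = json.loads(path.read_text())
    cls = _LEARNER_NAMES[meta["learner"]]
    learner = cls(**{k: v for k, v in meta["params"].items() if k in cls().get_params()})
    A = np.loadtxt(path.with_name(meta["matrix_file"]))
    learner.A_ = A.reshape(meta["shape"])
    learner.n_features_in_ = meta["shape"][0]
    learner.converged_ = meta["converged"]
    return learner
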