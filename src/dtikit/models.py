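"""Per-protein (or per-drug) classifiers.

KL1LR — kernel L1-regularized logistic regression.  For each example i and
each kernel k two features are built: x+ (mean similarity to positive-labelled
training co-examples, excluding i itself) and x- (mean similarity to
negative-labelled ones).  A logistic model on the interleaved features
(x+_1, x-_1, ..., x+_m, x-_m) with an L1 penalty on the coefficients (not the
intercept) yields interaction probabilities; the lasso drives the features of
uninformative kernels to exactly zero, making the fitted model directly
interpretable as "which similarity source carries the signal".

The SVM route scores held-out examples with a precomputed-kernel support
vector classifier; its decision values are mapped to probabilities by a
Platt sigmoid fitted on the training decision values (with Platt's smoothed
targets), which keeps the whole route deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.svm import SVC

from .core_io import SimilarityMatrix, aligned

__all__ = [
    "KL1LRFeatures",
    "KL1LRModel",
    "SVMSpec",
    "build_features",
    "fit_kl1lr",
    "predict_kl1lr",
    "fit_svm",
]


@dataclass
class KL1LRFeatures:
    """Interleaved (x+, x-) kernel-mean features for a set of evaluated examples."""

    xplus: np.ndarray  # n_eval x m
    xminus: np.ndarray  # n_eval x m
    labels: np.ndarray | None = None  # labels of the evaluated examples, if known

    def __post_init__(self):
        self.xplus = np.atleast_2d(np.asarray(self.xplus, dtype=float))
        self.xminus = np.atleast_2d(np.asarray(self.xminus, dtype=float))
        if self.xplus.shape != self.xminus.shape:
            raise ValueError("xplus and xminus must have matching shapes")
        if not (np.all(np.isfinite(self.xplus)) and np.all(np.isfinite(self.xminus))):
            raise ValueError("non-finite feature values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n(self) -> int:
        return self.xplus.shape[0]

    @property
    def m(self) -> int:
        return self.xplus.shape[1]

    @property
    def design(self) -> np.ndarray:
        """n x 2m design matrix with columns (x+_1, x-_1, ..., x+_m, x-_m)."""
        x = np.empty((self.n, 2 * self.m))
        x[:, 0::2] = self.xplus
        x[:, 1::2] = self.xminus
        return x


@dataclass
class KL1LRModel:
    """Fitted KL1LR coefficients: intercept + (b+_k, b-_k) per kernel."""

    intercept: float
    coefficients: np.ndarray  # length 2m, interleaved (b+_1, b-_1, ...)
    lam: float
    kkt_residual: float = field(default=np.nan)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not (np.isfinite(self.intercept) and np.all(np.isfinite(self.coefficients))):
            raise ValueError("non-finite model parameters")

    @property
    def n_kernels(self) -> int:
        return self.coefficients.size // 2


def build_features(
    kernels: Sequence[SimilarityMatrix] | Sequence[np.ndarray],
    labels: np.ndarray,
    train_indices: np.ndarray,
    eval_indices: np.ndarray | None = None,
) -> KL1LRFeatures:
    """Kernel-mean features of ``eval_indices`` relative to the training set.

    For evaluated example i and kernel K: x+ is the mean of K(i, j) over
    training j with y_j = 1 and j != i, x- the mean over training j with
    y_j = 0 and j != i.  Self-exclusion stops the unit diagonal from leaking
    an example's own label into its features.  ``eval_indices`` defaults to
    the training set itself (in-sample features for fitting).
    """
    mats = [k.values if isinstance(k, SimilarityMatrix) else np.asarray(k, float) for k in kernels]
    if isinstance(kernels[0], SimilarityMatrix):
        aligned([k for k in kernels if isinstance(k, SimilarityMatrix)])
    y = np.asarray(labels).astype(np.int8)
    train = np.asarray(train_indices, dtype=np.intp)
    ev = train if eval_indices is None else np.asarray(eval_indices, dtype=np.intp)
    pos = train[y[train] == 1]
    neg = train[y[train] == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training set needs at least one positive and one negative example")

    m = len(mats)
    xplus = np.empty((ev.size, m))
    xminus = np.empty((ev.size, m))
    in_pos = np.isin(ev, pos)
    in_neg = np.isin(ev, neg)
    for k, mat in enumerate(mats):
        rows = mat[np.ix_(ev, pos)]
        sums = rows.sum(axis=1)
        counts = np.full(ev.size, float(pos.size))
        self_diag = mat[ev, ev]
        sums = np.where(in_pos, sums - self_diag, sums)
        counts = np.where(in_pos, counts - 1, counts)
        if np.any(counts == 0):
            raise ValueError("an evaluated positive has no positive co-examples")
        xplus[:, k] = sums / counts

        rows = mat[np.ix_(ev, neg)]
        sums = rows.sum(axis=1)
        counts = np.full(ev.size, float(neg.size))
        sums = np.where(in_neg, sums - self_diag, sums)
        counts = np.where(in_neg, counts - 1, counts)
        if np.any(counts == 0):
            raise ValueError("an evaluated negative has no negative co-examples")
        xminus[:, k] = sums / counts
    return KL1LRFeatures(xplus, xminus, labels=y[ev])


def _penalized_objective(x: np.ndarray, y01: np.ndarray, b0: float, beta: np.ndarray, lam: float):
    """Objective -loglik + lam * ||beta||_1 and its smooth-part gradient."""
    z = b0 + x @ beta
    # -loglik = sum log(1 + exp(z)) - y*z, computed stably
    nll = float(np.sum(np.logaddexp(0.0, z) - y01 * z))
    p = expit(z)
    g0 = float(np.sum(p - y01))
    g = x.T @ (p - y01)
    return nll + lam * np.abs(beta).sum(), g0, g


def kkt_residual(x: np.ndarray, y01: np.ndarray, b0: float, beta: np.ndarray, lam: float) -> float:
    """Max violation of the first-order conditions of the L1 logistic problem."""
    _, g0, g = _penalized_objective(x, y01, b0, beta, lam)
    r = np.where(
        beta != 0,
        np.abs(g + lam * np.sign(beta)),
        np.maximum(np.abs(g) - lam, 0.0),
    )
    return float(max(abs(g0), r.max(initial=0.0)))


def fit_kl1lr(f: KL1LRFeatures, lam: float, tol: float = 1e-8, max_iter: int = 20000) -> KL1LRModel:
    """Fit KL1LR: minimize -loglik(b0, beta) + lam * ||beta||_1, intercept free.

    Solved via the smooth split beta = b+ - b- with b+/- >= 0 (box-constrained
    L-BFGS-B), then polished by proximal-gradient steps until the KKT residual
    of the original nonsmooth convex problem is below ``tol`` (default far
    tighter than the 1e-6 contract).  Deterministic.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x = f.design
    if f.labels is None:
        raise ValueError("features carry no labels to fit against")
    y01 = (f.labels == 1).astype(float)
    n, d = x.shape

    def split_obj(theta):
        b0 = theta[0]
        bp = theta[1 : 1 + d]
        bm = theta[1 + d :]
        beta = bp - bm
        z = b0 + x @ beta
        nll = np.sum(np.logaddexp(0.0, z) - y01 * z)
        p = expit(z)
        resid = p - y01
        g = x.T @ resid
        grad = np.concatenate(([resid.sum()], g + lam, -g + lam))
        return nll + lam * (bp.sum() + bm.sum()), grad

    theta0 = np.zeros(1 + 2 * d)
    theta0[0] = _safe_logit(y01.mean())
    bounds = [(None, None)] + [(0.0, None)] * (2 * d)
    res = minimize(
        split_obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-12},
    )
    b0 = float(res.x[0])
    beta = res.x[1 : 1 + d] - res.x[1 + d :]
    beta[np.abs(beta) < 1e-12] = 0.0

    # proximal-gradient polish: guarantees the KKT contract independent of
    # the quasi-Newton stopping state
    lip = 0.25 * (np.linalg.norm(x, 2) ** 2 + x.shape[0]) + 1e-12
    step = 1.0 / lip
    for _ in range(max_iter):
        if kkt_residual(x, y01, b0, beta, lam) <= tol:
            break
        _, g0, g = _penalized_objective(x, y01, b0, beta, lam)
        b0 -= step * g0
        beta = _soft_threshold(beta - step * g, step * lam)
    return KL1LRModel(b0, beta, lam, kkt_residual=kkt_residual(x, y01, b0, beta, lam))


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def penalized_objective_value(model: KL1LRModel, f: KL1LRFeatures) -> float:
    """Independent evaluation of -loglik + lam*||beta||_1 at the fitted model."""
    y01 = (f.labels == 1).astype(float)
    val, _, _ = _penalized_objective(f.design, y01, model.intercept, model.coefficients, model.lam)
    return val


def predict_kl1lr(model: KL1LRModel, f: KL1LRFeatures) -> np.ndarray:
    """Interaction probabilities 1/(1 + exp(-(b0 + x.beta))) for each example."""
    x = f.design
    if x.shape[1] != model.coefficients.size:
        raise ValueError(
            f"feature width {x.shape[1]} != model coefficient count {model.coefficients.size}"
        )
    return expit(model.intercept + x @ model.coefficients)


@dataclass
class SVMSpec:
    """Precomputed-kernel SVM: cost parameter C and a PSD-corrected kernel."""

    cost: float
    kernel: SimilarityMatrix
    probability_calibration: str = "platt"

    def __post_init__(self):
        if not self.cost > 0:
            raise ValueError("SVM cost C must be > 0")
        if self.probability_calibration not in ("platt", "sigmoid-on-decision"):
            raise ValueError(f"unknown calibration {self.probability_calibration!r}")


def _platt_sigmoid(decision: np.ndarray, y01: np.ndarray) -> tuple[float, float]:
    """Fit P(y=1|f) = sigmoid(a*f + b) on training decision values.

    Uses Platt's smoothed targets so separable decision values still give a
    finite, deterministic fit.
    """
    n_pos = float(y01.sum())
    n_neg = float(len(y01) - n_pos)
    t = np.where(y01 == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def obj(ab):
        a, b = ab
        z = a * decision + b
        val = np.sum(np.logaddexp(0.0, z) - t * z)
        p = expit(z)
        grad = np.array([np.sum((p - t) * decision), np.sum(p - t)])
        return val, grad

    res = minimize(obj, np.array([1.0, 0.0]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14})
    return float(res.x[0]), float(res.x[1])


def fit_svm(
    spec: SVMSpec,
    labels: np.ndarray,
    train_indices: np.ndarray,
    heldout_indices: np.ndarray,
) -> np.ndarray:
    """Train a precomputed-kernel SVC and return calibrated held-out probabilities.

    The classifier sees only the train x train kernel block; held-out examples
    are scored through their kernel rows against the training set and mapped
    to (0, 1) by a Platt sigmoid fitted on training decision values.
    """
    y = np.asarray(labels).astype(int)
    train = np.asarray(train_indices, dtype=np.intp)
    held = np.asarray(heldout_indices, dtype=np.intp)
    y_train = y[train]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    k = spec.kernel.values
    clf = SVC(C=spec.cost, kernel="precomputed")
    clf.fit(k[np.ix_(train, train)], y_train)
    dec_train = clf.decision_function(k[np.ix_(train, train)])
    a, b = _platt_sigmoid(dec_train, (y_train == 1).astype(float))
    dec_held = clf.decision_function(k[np.ix_(held, train)])
    return expit(a * dec_held + b)
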