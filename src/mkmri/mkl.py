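"""Multi-kernel linear SVM with simplex-constrained kernel weights.

The classifier combines one Gram matrix per feature modality,

    K(x_i, x) = sum_f  beta_f * k_f(x_i^(f), x^(f)),    beta_f >= 0, sum_f beta_f = 1,

and trains a soft-margin SVM on the combined kernel.  Kernel weights and the
SVM are optimized alternately: given the current ``beta`` the classical SVM
dual is solved on the combined kernel; then ``beta`` takes a projected
reduced-gradient step (gradient component per kernel
``-1/2 * sum_ij alpha_i alpha_j y_i y_j k_f,ij``, Danskin's theorem) with a
golden-section line search on the same objective.  The two steps repeat until
neither ``beta`` nor the objective moves more than ``tol``.

The inner dual,

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C,

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection.  The loop is numba-compiled when numba is available
(the identical Python function runs otherwise).

For linear kernels the per-feature primal contribution is recoverable as
``w^(f) = (beta_f / s_f) * sum_i alpha_i y_i x_i^(f)``, where ``s_f`` is the
optional mean-diagonal kernel scale; with that convention the primal identity
``f(x) = sum_f <w^(f), x^(f)> + b`` holds exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class ConvergenceError(RuntimeError):
    """SMO failed to reach the requested KKT tolerance."""


def _smo(Q, y, C, tol, max_iter, alpha):
    """SMO over f(a) = 1/2 a'Qa - sum(a), s.t. y'a = 0, 0 <= a <= C.

    Q = (y y') * K.  ``alpha`` is the (possibly warm) starting point, modified
    in place.  Returns (alpha, G, n_iter, converged) with G the gradient
    Q a - 1.
    """
    n = y.shape[0]
    G = np.dot(Q, alpha) - 1.0
    tau = 1e-12
    it = 0
    while it < max_iter:
        m = -np.inf
        M = np.inf
        i = -1
        j = -1
        for t in range(n):
            yG = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if yG > m:
                    m = yG
                    i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if yG < M:
                    M = yG
                    j = t
        if m - M < tol:
            return alpha, G, it, True
        ai_old = alpha[i]
        aj_old = alpha[j]
        if y[i] != y[j]:
            quad = Q[i, i] + Q[j, j] + 2.0 * Q[i, j]
            if quad <= 0.0:
                quad = tau
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            ai = ai_old + delta
            aj = aj_old + delta
            if diff > 0.0:
                if aj < 0.0:
                    aj = 0.0
                    ai = diff
            else:
                if ai < 0.0:
                    ai = 0.0
                    aj = -diff
            if diff > 0.0:
                if ai > C:
                    ai = C
                    aj = C - diff
            else:
                if aj > C:
                    aj = C
                    ai = C + diff
        else:
            quad = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
            if quad <= 0.0:
                quad = tau
            delta = (G[i] - G[j]) / quad
            ssum = ai_old + aj_old
            ai = ai_old - delta
            aj = aj_old + delta
            if ssum > C:
                if ai > C:
                    ai = C
                    aj = ssum - C
            else:
                if aj < 0.0:
                    aj = 0.0
                    ai = ssum
            if ssum > C:
                if aj > C:
                    aj = C
                    ai = ssum - C
            else:
                if ai < 0.0:
                    ai = 0.0
                    aj = ssum
        alpha[i] = ai
        alpha[j] = aj
        dai = ai - ai_old
        daj = aj - aj_old
        for t in range(n):
            G[t] += Q[t, i] * dai + Q[t, j] * daj
        it += 1
    return alpha, G, it, False


try:  # compiled inner loop; the pure-Python body is the fallback
    from numba import njit

    _smo = njit(cache=True)(_smo)
except Exception:  # pragma: no cover - numba is a declared dependency
    logger.info("numba unavailable; SMO runs in pure Python")


def linear_gram(matrix) -> np.ndarray:
    """Gram matrix of row-wise inner products (linear kernel)."""
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    return X @ X.T


@dataclass
class KernelSet:
    """F per-feature Gram matrices with simplex weights."""

    kernels: list
    beta: np.ndarray

    def validate(self, sym_tol: float = 1e-10, eig_tol: float = 1e-8,
                 simplex_tol: float = 1e-10) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if len(self.kernels) != beta.size:
            raise ValueError("one weight per kernel required")
        if (beta < -simplex_tol).any() or abs(beta.sum() - 1.0) > simplex_tol:
            raise ValueError(f"beta {beta} is off the probability simplex")
        n = None
        for k in self.kernels:
            k = np.asarray(k, dtype=float)
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise ValueError("kernels must be square")
            if n is None:
                n = k.shape[0]
            elif k.shape[0] != n:
                raise ValueError("kernels differ in size")
            scale = max(np.abs(k).max(), 1.0)
            if np.abs(k - k.T).max() > sym_tol * scale:
                raise ValueError("kernel is not symmetric")
            min_eig = np.linalg.eigvalsh(k)[0]
            if min_eig < -eig_tol * max(k.diagonal().max(), 1.0):
                raise ValueError(f"kernel has negative eigenvalue {min_eig:g}")


def combine_kernels(kset: KernelSet) -> np.ndarray:
    """Entrywise simplex-weighted sum of the Gram matrices."""
    kset.validate()
    out = np.zeros_like(np.asarray(kset.kernels[0], dtype=float))
    for b, k in zip(kset.beta, kset.kernels):
        out += b * np.asarray(k, dtype=float)
    return out


def solve_svm_dual(gram, y, C: float, tol: float = 1e-8,
                   max_iter: int = 2_000_000, alpha0=None):
    """Solve the box-constrained SVM dual on one Gram matrix.

    Returns ``(alpha, b, objective)`` where ``objective`` is the maximized
    dual value.  The bias ``b`` is the average KKT estimate over unbounded
    support vectors (``1e-6 < alpha_i < C - 1e-6``); if none exist the
    midpoint of the feasibility interval is used.
    """
    K = np.asarray(gram, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("gram must be n x n matching y")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes (+1/-1) must be present")
    if C <= 0:
        raise ValueError("C must be positive")
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n) if alpha0 is None else np.array(alpha0, dtype=float)
    alpha, G, n_iter, ok = _smo(Q, y, float(C), float(tol), max_iter, alpha)
    if not ok:
        yG = -y * G
        raise ConvergenceError(
            f"SMO did not converge in {n_iter} iterations "
            f"(KKT violation {yG.max() - yG.min():g}, tol {tol:g})")
    # objective:  sum(a) - 1/2 a'Qa  =  1/2 sum(a) - 1/2 a'G
    obj = 0.5 * alpha.sum() - 0.5 * float(alpha @ G)
    yG = -y * G
    free = (alpha > 1e-6) & (alpha < C - 1e-6)
    if free.any():
        b = float(yG[free].mean())
    else:
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        hi = yG[up].max() if up.any() else 0.0
        lo = yG[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b, float(obj)


def project_simplex(v) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class MKLResult:
    """Fit output of the alternating kernel-weight / SVM optimization."""

    alpha: np.ndarray
    b: float
    beta: np.ndarray
    kernel_scales: np.ndarray
    objective_path: list
    dual_objective: float
    duality_gap: float
    n_outer: int
    converged: bool

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 1e-8)


def _duality_gap(K, y, C, alpha, b):
    ay = alpha * y
    w2 = float(ay @ K @ ay)
    f = K @ ay + b
    xi = np.maximum(0.0, 1.0 - y * f)
    primal = 0.5 * w2 + C * xi.sum()
    dual = alpha.sum() - 0.5 * w2
    return (primal - dual) / max(1.0, abs(primal))


def fit_mkl(kernels, y, C: float = 100.0, tol: float = 1e-4,
            max_outer: int = 100, normalize_kernels: bool = True,
            svm_tol: float = 1e-8, n_line_search: int = 16) -> MKLResult:
    """Alternating optimization of simplex kernel weights and the SVM dual.

    ``beta`` starts uniform at 1/F.  Each outer iteration solves the SVM on
    the beta-combined kernel, then line-searches a projected gradient step
    for ``beta``; only non-increasing objective moves are accepted, so the
    recorded objective path is monotone.  Stops when ``max |dbeta| < tol`` or
    the relative objective decrease falls below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    F = len(kernels)
    if F < 1:
        raise ValueError("need at least one kernel")
    Ks = [np.asarray(k, dtype=float) for k in kernels]
    n = y.size
    for k in Ks:
        if k.shape != (n, n):
            raise ValueError("all Grams must be n x n matching y")
    if normalize_kernels:
        scales = np.array([max(k.diagonal().mean(), 1e-300) for k in Ks])
    else:
        scales = np.ones(F)
    Ks = [k / s for k, s in zip(Ks, scales)]

    beta = np.full(F, 1.0 / F)
    alpha, b, obj = solve_svm_dual(_combine(Ks, beta), y, C, tol=svm_tol)
    path = [obj]
    converged = F == 1
    outer = 0
    if F > 1:
        for outer in range(1, max_outer + 1):
            ay = alpha * y
            grad = np.array([-0.5 * float(ay @ k @ ay) for k in Ks])
            gspan = np.abs(grad - grad.mean()).max()
            if gspan < 1e-15:
                converged = True
                break

            cache: dict[float, tuple] = {}

            def evaluate(tstep):
                cand = project_simplex(beta - tstep * grad)
                a, bb, o = solve_svm_dual(_combine(Ks, cand), y, C,
                                          tol=svm_tol, alpha0=alpha)
                cache[tstep] = (o, cand, a, bb)
                return o

            t_hi = 1.0 / gspan  # enough to traverse the simplex
            cache[0.0] = (obj, beta, alpha, b)
            lo, hi = 0.0, t_hi
            c1 = hi - _GOLDEN * (hi - lo)
            c2 = lo + _GOLDEN * (hi - lo)
            f1, f2 = evaluate(c1), evaluate(c2)
            for _ in range(n_line_search):
                if f1 <= f2:
                    hi, c2, f2 = c2, c1, f1
                    c1 = hi - _GOLDEN * (hi - lo)
                    f1 = evaluate(c1)
                else:
                    lo, c1, f1 = c1, c2, f2
                    c2 = lo + _GOLDEN * (hi - lo)
                    f2 = evaluate(c2)
            best = min(cache, key=lambda k_: cache[k_][0])
            if not np.isfinite(cache[best][0]):
                raise ConvergenceError("non-finite MKL objective")
            obj_new, beta_new, alpha, b = cache[best]
            dbeta = np.abs(beta_new - beta).max()
            dobj = path[-1] - obj_new
            beta = beta_new
            path.append(obj_new)
            logger.debug("outer %d: obj=%.10g dbeta=%.3g beta=%s",
                         outer, obj_new, dbeta, np.round(beta, 4))
            if dbeta < tol or dobj < tol * max(1.0, abs(path[-2])):
                converged = True
                break

    K_final = _combine(Ks, beta)
    gap = _duality_gap(K_final, y, C, alpha, b)
    return MKLResult(alpha=alpha, b=b, beta=beta, kernel_scales=scales,
                     objective_path=path, dual_objective=path[-1],
                     duality_gap=gap, n_outer=outer, converged=converged)


def _combine(Ks, beta):
    out = beta[0] * Ks[0]
    for b, k in zip(beta[1:], Ks[1:]):
        out = out + b * k
    return out


class MultiKernelSVC(ClassifierMixin, BaseEstimator):
    """Multi-kernel linear SVM classifier (scikit-learn style).

    Parameters
    ----------
    C : float
        Soft-margin box constraint, shared by all fits.
    kernel : {"linear", "precomputed"}
        With "linear", ``fit`` takes a list of per-feature matrices of shape
        (n_samples, D_f) and Grams are row inner products.  With
        "precomputed", ``fit`` takes the F Gram matrices directly and
        ``decision_function`` takes F cross-kernel matrices of shape
        (n_test, n_train).
    normalize_kernels : bool
        Divide each Gram by its mean diagonal before weighting so kernel
        scales are comparable and ``beta`` is interpretable.
    tol, max_outer : float, int
        Outer-loop convergence controls of the alternating optimization.
    svm_tol : float
        KKT tolerance of the inner SMO solver.

    Attributes
    ----------
    beta_ : (F,) kernel weights on the simplex.
    alpha_ : (n,) dual coefficients, ``0 <= alpha_i <= C``.
    intercept_ : float bias term.
    support_ : indices with non-negligible ``alpha``.
    classes_ : sorted class labels; the larger one plays the +1 role.
    duality_gap_, n_iter_, objective_path_ : fit diagnostics.
    """

    def __init__(self, C: float = 100.0, kernel: str = "linear",
                 normalize_kernels: bool = True, tol: float = 1e-4,
                 max_outer: int = 100, svm_tol: float = 1e-8):
        self.C = C
        self.kernel = kernel
        self.normalize_kernels = normalize_kernels
        self.tol = tol
        self.max_outer = max_outer
        self.svm_tol = svm_tol

    @staticmethod
    def _as_list(X) -> list:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return [np.asarray(X, dtype=float)]
        return [np.asarray(getattr(x, "values", x), dtype=float) for x in X]

    def fit(self, X, y) -> "MultiKernelSVC":
        Xs = self._as_list(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes required")
        y_pm = np.where(y == self.classes_[1], 1.0, -1.0)
        if self.kernel == "linear":
            grams = [linear_gram(Xf) for Xf in Xs]
            self.X_fit_ = Xs
        elif self.kernel == "precomputed":
            grams = Xs
            self.X_fit_ = None
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        res = fit_mkl(grams, y_pm, C=self.C, tol=self.tol,
                      max_outer=self.max_outer,
                      normalize_kernels=self.normalize_kernels,
                      svm_tol=self.svm_tol)
        self.result_ = res
        self.beta_ = res.beta
        self.alpha_ = res.alpha
        self.intercept_ = res.b
        self.support_ = res.support
        self.y_fit_ = y_pm
        self.kernel_scales_ = res.kernel_scales
        self.duality_gap_ = res.duality_gap
        self.n_iter_ = res.n_outer
        self.objective_path_ = res.objective_path
        return self

    def _columns(self, X) -> list:
        """Per-feature raw cross-kernel matrices k_f(x_i, x), shape (m, n)."""
        Xs = self._as_list(X)
        if self.kernel == "linear":
            return [Xt @ Xf.T for Xt, Xf in zip(Xs, self.X_fit_)]
        return Xs

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        cols = self._columns(X)
        n = self.alpha_.size
        for c in cols:
            if c.shape[-1] != n:
                raise ValueError("test kernel columns do not match training size")
        ay = self.alpha_ * self.y_fit_
        f = np.zeros(cols[0].shape[0])
        for beta, s, c in zip(self.beta_, self.kernel_scales_, cols):
            f += (beta / s) * (c @ ay)
        return f + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # sign(0) -> +1 (the patient class by the labeling convention)
        return self.classes_[(d >= 0).astype(int)]


def decision_function(model: MultiKernelSVC, test_kernel_columns) -> np.ndarray:
    """Decision values from raw per-feature kernel columns k_f(x_i, x)."""
    check_is_fitted(model, "beta_")
    cols = [np.asarray(c, dtype=float) for c in test_kernel_columns]
    cols = [c[None, :] if c.ndim == 1 else c for c in cols]
    ay = model.alpha_ * model.y_fit_
    f = np.zeros(cols[0].shape[0])
    for beta, s, c in zip(model.beta_, model.kernel_scales_, cols):
        f += (beta / s) * (c @ ay)
    return f + model.intercept_


def extract_weight_vectors(model: MultiKernelSVC, feature_matrices=None) -> list:
    """Per-feature primal weight vectors ``w^(f)`` of a linear-kernel fit.

    ``w^(f) = (beta_f / s_f) * sum_i alpha_i y_i x_i^(f)`` — the effective
    per-feature primal contribution, including the kernel-scale factor, so
    that ``sum_f <w^(f), x^(f)> + intercept_`` equals the decision function.
    """
    check_is_fitted(model, "beta_")
    if model.kernel != "linear" or model.X_fit_ is None:
        raise ValueError("weight vectors require a linear-kernel fit")
    Xs = model.X_fit_ if feature_matrices is None else model._as_list(feature_matrices)
    ay = model.alpha_ * model.y_fit_
    return [(beta / s) * (Xf.T @ ay)
            for beta, s, Xf in zip(model.beta_, model.kernel_scales_, Xs)]
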