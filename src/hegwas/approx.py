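"""HE-friendly numerical building blocks, in exact (plaintext) arithmetic.

Homomorphic evaluation supports only additions and multiplications, so the
association pipeline replaces every non-polynomial step of semi-parallel
GWAS with a polynomial surrogate:

* the logistic sigmoid is replaced by a degree-7 least-squares polynomial
  on [-8, 8];
* the Fisher-scoring matrix inverse U^-1 = adj(U)/det(U) is replaced by the
  adjugate alone, with the determinant reciprocal absorbed into a fixed
  step constant alpha (``beta += alpha * adj(U) X^T (y - p)``);
* real-number division is replaced by Goldschmidt's multiplicative
  iteration on a publicly bounded operand.

The functions here define those surrogates exactly; the encrypted pipeline
(:mod:`hegwas.pipeline`) must agree with them up to encryption noise, which
is what the end-to-end tests check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import integrate, stats

#: Degree-7 least-squares coefficients of sigma(x) in t = x/8 over [-8, 8]:
#: g(x) = 0.5 + 1.735 t - 4.194 t^3 + 5.434 t^5 - 2.507 t^7.
SIGMOID7_COEFFS = (0.5, 1.735, -4.194, 5.434, -2.507)
SIGMOID7_HALF_WIDTH = 8.0


def sigmoid(x):
    """The exact logistic function sigma(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def sigmoid_poly7(x):
    """Degree-7 polynomial approximation of the sigmoid on [-8, 8].

    Outside the fitting interval the polynomial diverges (it is not
    clamped); callers are responsible for keeping their linear predictors
    inside the domain.  The maximal error on the interval is about 0.032.
    """
    t = np.asarray(x, dtype=float) / SIGMOID7_HALF_WIDTH
    t2 = t * t
    c0, c1, c3, c5, c7 = SIGMOID7_COEFFS
    return c0 + t * (c1 + t2 * (c3 + t2 * (c5 + t2 * c7)))


def fit_sigmoid_lsq(degree: int, half_width: float = SIGMOID7_HALF_WIDTH
                    ) -> np.ndarray:
    """Continuous-L2 polynomial fit of the sigmoid on [-half_width, half_width].

    Projects sigma onto polynomials of the scaled variable t = x/half_width
    using Legendre quadrature, which is the natural orthogonal basis for an
    unweighted L2 fit on an interval.  Returns the monomial coefficients
    (c_0, c_1, ..., c_degree) in t.  By the symmetry sigma(x) - 1/2 odd, all
    even-order coefficients beyond the constant 1/2 vanish (up to quadrature
    error).
    """
    if degree < 1:
        raise ValueError("degree must be at least 1")
    leg_coeffs = []
    for d in range(degree + 1):
        basis = legendre.Legendre.basis(d)
        num, _ = integrate.quad(
            lambda u, b=basis: sigmoid(half_width * u) * b(u), -1, 1,
            limit=200, epsabs=1e-12, epsrel=1e-12)
        leg_coeffs.append(num * (2 * d + 1) / 2.0)
    return legendre.leg2poly(leg_coeffs)


def goldschmidt_inverse(x, iters: int, bound: float):
    """Approximate 1/x by Goldschmidt's division iteration.

    The operand is normalized by the public ``bound`` so that
    n = 2x/bound lies in (0, 2); with e = 1 - n the reciprocal expands as
    1/n = prod_{i>=0} (1 + e^(2^i)), truncated after ``iters`` factors, so
    the relative error is |e|^(2^iters) -- it decays doubly exponentially.

    Parameters
    ----------
    x : scalar or array, with 0 < x <= bound elementwise.
    iters : number of product factors (0 gives the linear estimate 1/n ~ 1).
    bound : public upper bound used for normalization.
    """
    x = np.asarray(x, dtype=float)
    if bound <= 0:
        raise ValueError("bound must be positive")
    if np.any(x <= 0) or np.any(x > bound):
        raise ValueError("goldschmidt_inverse requires 0 < x <= bound")
    if iters < 0:
        raise ValueError("iters must be nonnegative")
    n = 2.0 * x / bound
    e = 1.0 - n
    r = np.ones_like(n)
    for _ in range(iters):
        r = r * (1.0 + e)
        e = e * e
    return r * (2.0 / bound)


def zsq_to_pvalue(zsq):
    """p-value of a squared z-statistic: the chi-square(1 df) upper tail.

    Equivalent to the two-sided normal tail of sqrt(zsq).  NaN inputs
    (flagged SNPs) propagate to NaN p-values.
    """
    zsq = np.asarray(zsq, dtype=float)
    if np.any(zsq[~np.isnan(zsq)] < 0):
        raise ValueError("squared statistics must be nonnegative")
    return stats.chi2.sf(zsq, df=1)


# ---------------------------------------------------------------------------
# design standardization
# ---------------------------------------------------------------------------


def standardize_design(X: np.ndarray, y: np.ndarray | None = None,
                       alpha: float = 8.0) -> np.ndarray:
    """Rescale a design matrix so the adjugate update is well-conditioned.

    The modified update ``beta += alpha * adj(U) X^T (y - p)`` is Newton's
    step multiplied by gamma = alpha * det(U); it converges quadratically
    when gamma is one at the fixed point.  Covariate columns (all but the
    leading intercept column) are z-scored, then the whole matrix --
    intercept included -- is scaled by the constant s solving
    ``alpha * det(s^2 U*) = 1`` where U* = Z^T W Z uses the converged IRLS
    weights when the phenotype is supplied (a cheap plaintext calibration
    the data owner performs before encrypting), or the starting weights
    W = I/4 otherwise.  Uniform rescaling of X is an exact
    reparameterization of the logistic model: fitted probabilities, squared
    statistics and p-values are unchanged.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first design column must be the intercept (all ones)")
    Z = X.copy()
    for j in range(1, k):
        sd = X[:, j].std()
        if sd == 0:
            raise ValueError(f"covariate column {j} is constant")
        Z[:, j] = (X[:, j] - X[:, j].mean()) / sd
    if y is None:
        U = Z.T @ Z / 4.0
    else:
        from .oracles import fisher_scoring_exact
        _, _, w = fisher_scoring_exact(Z, np.asarray(y, dtype=float))
        U = (Z * w[:, None]).T @ Z
    s = (alpha * np.linalg.det(U)) ** (-1.0 / (2.0 * k))
    return Z * s


# ---------------------------------------------------------------------------
# modified Fisher scoring
# ---------------------------------------------------------------------------


def _adjugate(U: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact adjugate and determinant by cofactor minors (small k only)."""
    k = U.shape[0]
    if k == 1:
        return np.ones((1, 1)), float(U[0, 0])
    adj = np.empty_like(U, dtype=float)
    for i in range(k):
        for j in range(k):
            minor = np.delete(np.delete(U, i, axis=0), j, axis=1)
            adj[j, i] = (-1) ** (i + j) * np.linalg.det(minor)
    det = float(U[0, :] @ adj[:, 0])
    return adj, det


@dataclass
class FisherState:
    """Final state of the adjugate-based (inversion-free) Fisher scoring."""

    beta: np.ndarray      # coefficients, length k
    p_vec: np.ndarray     # fitted probabilities, length n
    W_diag: np.ndarray    # working weights p*(1-p)
    adjU: np.ndarray      # adj(X^T W X), k x k
    detU: float
    alpha: float
    iter: int


def modified_fisher_scoring(X: np.ndarray, y: np.ndarray, alpha: float = 8.0,
                            iters: int = 4, sigmoid_fn: str = "poly7",
                            beta_guard: float = 1e6) -> FisherState:
    """Inversion-free logistic fitting: beta += alpha * adj(U) X^T (y - p).

    Runs exactly ``iters`` updates from beta = 0 (each recomputing
    p = g(X beta), W = p(1-p) and U = X^T W X), then evaluates the final
    p, W, U, adj(U) and det(U) at the returned coefficients, which is the
    state the semi-parallel association stage consumes.

    ``sigmoid_fn`` selects the exact sigmoid or its degree-7 polynomial
    surrogate ("exact" | "poly7").  The caller is expected to have
    standardized X (see :func:`standardize_design`) so that
    alpha * det(U) is near one; a coarse divergence guard raises if
    ||beta|| explodes, which is the symptom of a mis-scaled alpha.
    """
    g = {"exact": sigmoid, "poly7": sigmoid_poly7}[sigmoid_fn]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)

    def analysis(beta):
        p = g(X @ beta)
        w = p * (1.0 - p)
        U = (X * w[:, None]).T @ X
        adjU, detU = _adjugate(U)
        return p, w, U, adjU, detU

    for _ in range(iters):
        p, w, U, adjU, detU = analysis(beta)
        beta = beta + alpha * (adjU @ (X.T @ (y - p)))
        if not np.all(np.isfinite(beta)) or np.linalg.norm(beta) > beta_guard:
            raise ArithmeticError(
                "modified Fisher scoring diverged; alpha is too large for "
                "this design scale (standardize X or reduce alpha)")
    p, w, U, adjU, detU = analysis(beta)
    return FisherState(beta=beta, p_vec=p, W_diag=w, adjU=adjU, detU=detU,
                       alpha=alpha, iter=iters)


# ---------------------------------------------------------------------------
# modified semi-parallel association
# ---------------------------------------------------------------------------


@dataclass
class SemiParallelResult:
    """Per-SNP outputs of the modified semi-parallel algorithm.

    ``zsq = detU * c^2 / d`` with c = S^T (y - p) and
    d = det(U) * diag(S^T W S) - diag(V^T adj(U) V); in the streamlined
    mode ("exp1") the division is deferred, so ``numerator`` and
    ``denominator`` carry det(U) * c^2 and d separately.
    """

    c: np.ndarray
    d: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray
    zsq: np.ndarray
    pval: np.ndarray
    flagged: np.ndarray   # boolean; degenerate SNPs (d <= 0)
    fisher: FisherState
    mode: str


def modified_semiparallel(X: np.ndarray, y: np.ndarray, S: np.ndarray,
                          alpha: float = 8.0, iters: int = 4,
                          mode: str = "exp2", gs_iters: int = 8,
                          d_bound: float | None = None,
                          sigmoid_fn: str = "poly7") -> SemiParallelResult:
    """HE-friendly semi-parallel GWAS on a fitted covariate-only model.

    After the modified Fisher scoring converges, each SNP's squared Wald
    statistic is assembled from inversion-free pieces:

        c   = S^T (y - p)                      (score against the residual)
        d_i = det(U) * (S^T W S)_ii - (V^T adj(U) V)_ii,   V = X^T W S
        z_i^2 = det(U) * c_i^2 / d_i

    which equals the statistic of the original algorithm whenever the
    Fisher score X^T (y - p) has converged to zero (the dropped projection
    term vanishes).  Mode "exp1" keeps numerator and denominator separate
    (division left to the decrypting party); "exp2" divides via
    :func:`goldschmidt_inverse` with ``gs_iters`` iterations and the public
    bound ``d_bound`` (estimated from d itself when not supplied, which is
    only acceptable in plaintext use).

    SNPs with nonpositive d (monomorphic or fully covariate-explained) are
    flagged and get NaN statistics rather than raising.
    """
    if mode not in ("exp1", "exp2"):
        raise ValueError("mode must be 'exp1' or 'exp2'")
    S = np.asarray(S, dtype=float)
    fisher = modified_fisher_scoring(X, y, alpha=alpha, iters=iters,
                                     sigmoid_fn=sigmoid_fn)
    p, w = fisher.p_vec, fisher.W_diag
    adjU, detU = fisher.adjU, fisher.detU
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    c = S.T @ (y - p)
    V = (X * w[:, None]).T @ S                      # k x m
    diag_sws = np.einsum("ij,i,ij->j", S, w, S)     # diag(S^T W S)
    diag_vav = np.einsum("ij,jk,ki->i", V.T, adjU, V)
    d = detU * diag_sws - diag_vav
    numerator = detU * c * c

    # degenerate SNPs (monomorphic or covariate-collinear) have d collapsing
    # to rounding noise; flag against a relative floor anchored at the
    # always-positive first term rather than bare nonpositivity
    d_floor = 1e-9 * float(np.max(detU * diag_sws, initial=0.0))
    flagged = ~(d > d_floor) | ~np.isfinite(d)
    zsq = np.full_like(d, np.nan)
    ok = ~flagged
    if mode == "exp1":
        zsq[ok] = numerator[ok] / d[ok]
    else:
        if d_bound is None:
            d_bound = 2.0 ** math.ceil(math.log2(float(d[ok].max()) * 2.0)) \
                if ok.any() else 1.0
        inv = np.full_like(d, np.nan)
        inv[ok] = goldschmidt_inverse(d[ok], iters=gs_iters, bound=d_bound)
        zsq[ok] = numerator[ok] * inv[ok]
    pval = np.full_like(zsq, np.nan)
    pval[ok] = zsq_to_pvalue(np.maximum(zsq[ok], 0.0))
    return SemiParallelResult(c=c, d=d, numerator=numerator, denominator=d,
                              zsq=zsq, pval=pval, flagged=flagged,
                              fisher=fisher, mode=mode)
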