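"""Exact plaintext baselines for the association pipeline.

These are the unmodified algorithms the HE-friendly surrogates are judged
against: textbook IRLS (Fisher scoring with a true matrix solve), the
original semi-parallel GWAS statistic built from weighted projections, and
the naive per-SNP logistic regression.  They deliberately share the
chi-square(1) p-value conversion with the modified pipeline so that
comparisons isolate algorithmic differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .approx import sigmoid, zsq_to_pvalue


class SeparationError(RuntimeError):
    """Raised when the logistic MLE does not exist / IRLS breaks down."""


def fisher_scoring_exact(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                         tol: float = 1e-12):
    """Standard Fisher scoring (IRLS) for logistic regression.

    Iterates ``beta <- U^-1 X^T W v`` with the working response
    v = X beta + (y - p)/w until the step is below ``tol``.  Returns
    ``(beta, p, w)`` at convergence.

    Raises
    ------
    SeparationError
        if U becomes singular or the fit degenerates (complete separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise SeparationError("design matrix is rank deficient")
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = sigmoid(eta)
        w = p * (1.0 - p)
        if np.any(w < 1e-12):
            raise SeparationError(
                "fitted probabilities reached 0/1; MLE may not exist")
        U = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(U, X.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("IRLS failed to converge")
    p = sigmoid(X @ beta)
    w = p * (1.0 - p)
    return beta, p, w


@dataclass
class SemiParallelOracle:
    """Original semi-parallel statistics: z, z^2 and p-value per SNP."""

    z: np.ndarray
    zsq: np.ndarray
    pval: np.ndarray
    flagged: np.ndarray
    beta: np.ndarray


def semiparallel_original(X: np.ndarray, y: np.ndarray,
                          S: np.ndarray) -> SemiParallelOracle:
    """The original (projection-based) semi-parallel GWAS algorithm.

    Fits the covariate-only logistic model to full convergence, then scores
    every SNP at once through the weighted projections

        S* = S - X U^-1 V,   V = X^T W S
        v* = v - X U^-1 X^T W v,   v = X beta + (y - p)/w
        z_i = (S*^T W v*)_i / sqrt(diag(S*^T W S*)_i)

    with p-values from the chi-square(1) tail of z^2.  SNPs whose residual
    variance diag(S*^T W S*) is not positive (monomorphic or collinear with
    the covariates) are flagged with NaN statistics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    S = np.asarray(S, dtype=float)
    beta, p, w = fisher_scoring_exact(X, y)
    U = (X * w[:, None]).T @ X
    Uinv = np.linalg.inv(U)
    V = (X * w[:, None]).T @ S
    S_star = S - X @ (Uinv @ V)
    v = X @ beta + (y - p) / w
    v_star = v - X @ (Uinv @ (X.T @ (w * v)))
    num = S_star.T @ (w * v_star)
    den = np.einsum("ij,i,ij->j", S_star, w, S_star)
    scale = float(np.max(den)) if den.size else 1.0
    flagged = den <= 1e-12 * max(scale, 1.0)
    z = np.full(S.shape[1], np.nan)
    z[~flagged] = num[~flagged] / np.sqrt(den[~flagged])
    zsq = z * z
    pval = np.full_like(z, np.nan)
    pval[~flagged] = zsq_to_pvalue(zsq[~flagged])
    return SemiParallelOracle(z=z, zsq=zsq, pval=pval, flagged=flagged,
                              beta=beta)


def per_snp_logistic(X: np.ndarray, y: np.ndarray, S: np.ndarray,
                     ) -> np.ndarray:
    """Naive GWAS: one logistic regression per SNP, Wald p of its slope.

    Uses statsmodels as an independent maximum-likelihood implementation.
    SNPs whose fit fails (separation, collinearity) get NaN.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    S = np.asarray(S, dtype=float)
    m = S.shape[1]
    pvals = np.full(m, np.nan)
    for j in range(m):
        design = np.column_stack([X, S[:, j]])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            if fit.mle_retvals.get("converged", True):
                pvals[j] = fit.pvalues[-1]
        except Exception:
            pass
    return pvals


def f1_at_threshold(pval_ref, pval_test, threshold: float) -> float:
    """F1 of below-threshold classification, reference vs test p-values.

    A SNP is "positive" when its p-value is strictly below ``threshold``
    (the GWAS significance convention); the reference classification is
    treated as ground truth.  NaN p-values are never positive.  When both
    sides declare no positives the score is defined as 1.0; an empty test
    set against a nonempty reference scores 0.0.
    """
    pr = np.asarray(pval_ref, dtype=float)
    pt = np.asarray(pval_test, dtype=float)
    if pr.shape != pt.shape:
        raise ValueError("p-value vectors must have equal length")
    with np.errstate(invalid="ignore"):
        ref = pr < threshold
        test = pt < threshold
    tp = int(np.sum(ref & test))
    fp = int(np.sum(~ref & test))
    fn = int(np.sum(ref & ~test))
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)
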