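"""Association analysis: weighted multinomial regression and meta-analysis.

Phenotype membership from the multiple-imputation ensemble is probabilistic,
so the association stage fits a multinomial logistic regression in which
each subject contributes one pseudo-observation per phenotype, weighted by
its membership probability. Effects are reported as relative risk ratios
(exponentiated coefficients) against a reference phenotype with Wald 95%
confidence intervals. Per-cohort log effects are pooled with the
DerSimonian-Laird random-effects estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .consensus import MembershipMatrix
from .exceptions import ValidationError

__all__ = ["AssociationResult", "MetaResult", "weighted_multinomial", "dl_meta"]

_Z95 = 1.96
_SEPARATION_COEF = 15.0


@dataclass
class AssociationResult:
    """Relative risk ratios per non-reference phenotype and covariate term."""

    table: pd.DataFrame  # phenotype, term, coef, se, rrr, ci_low, ci_high, p_value
    reference: int
    loglik: float
    converged: bool
    separation_suspected: bool


def _loglik_grad_hess(B, X, W):
    n, p = X.shape
    k = W.shape[1]
    eta = np.zeros((n, k))
    eta[:, 1:] = X @ B.T  # column 0 = reference
    lse = logsumexp(eta, axis=1)
    ll = float((W * eta).sum() - lse.sum())
    P = np.exp(eta - lse[:, None])
    resid = W[:, 1:] - P[:, 1:]
    grad = (resid.T @ X).ravel()
    km1 = k - 1
    H = np.zeros((km1 * p, km1 * p))
    for c in range(km1):
        for d in range(c, km1):
            w = P[:, c + 1] * ((1.0 if c == d else 0.0) - P[:, d + 1])
            block = -(X.T @ (X * w[:, None]))
            H[c * p:(c + 1) * p, d * p:(d + 1) * p] = block
            if d != c:
                H[d * p:(d + 1) * p, c * p:(c + 1) * p] = block.T
    return ll, grad, H, P


def weighted_multinomial(
    memberships: MembershipMatrix | np.ndarray,
    covariates: pd.DataFrame,
    reference: int = 0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> AssociationResult:
    """Fit a membership-weighted multinomial logistic regression.

    Maximizes sum_i sum_c p_ic log P(c | x_i) by Newton iterations with
    step-halving (the weighted log-likelihood is non-decreasing across
    accepted steps). With hard 0/1 memberships this is exactly the ordinary
    multinomial fit. Covariates must be numeric (expand categoricals
    upstream; genotypes coded additively 0/1/2). An intercept is added.
    """
    W = memberships.probabilities if isinstance(memberships, MembershipMatrix) else np.asarray(memberships, dtype=float)
    if np.abs(W.sum(axis=1) - 1.0).max(initial=0.0) > 1e-8:
        raise ValidationError("membership rows must sum to 1")
    n, k = W.shape
    if len(covariates) != n:
        raise ValidationError("covariates and memberships misaligned")
    if not 0 <= reference < k:
        raise ValidationError(f"reference {reference} outside 0..{k - 1}")
    Xc = covariates.to_numpy(dtype=float)
    if np.isnan(Xc).any():
        raise ValidationError("covariates contain missing values")
    X = np.column_stack([np.ones(n), Xc])
    terms = ["intercept"] + list(covariates.columns)
    p = X.shape[1]

    # put the reference class in column 0
    order = [reference] + [c for c in range(k) if c != reference]
    Wo = W[:, order]

    B = np.zeros((k - 1, p))
    ll, grad, H, _ = _loglik_grad_hess(B, X, Wo)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(H.shape[0]), grad).reshape(k - 1, p)
        except np.linalg.LinAlgError:
            break
        # Newton direction is -H^{-1} g for a maximization with negative-definite H
        step = -step
        scale = 1.0
        improved = False
        for _half in range(30):
            ll_new, grad_new, H_new, _ = _loglik_grad_hess(B + scale * step, X, Wo)
            if ll_new >= ll - 1e-12:
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        B = B + scale * step
        delta = ll_new - ll
        ll, grad, H = ll_new, grad_new, H_new
        if abs(delta) <= tol * (abs(ll) + 1e-12) and np.abs(grad).max() < 1e-6:
            converged = True
            break

    try:
        cov = np.linalg.inv(-(H - 1e-12 * np.eye(H.shape[0])))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(k - 1, p)
    except np.linalg.LinAlgError:
        se = np.full((k - 1, p), np.nan)

    rows = []
    for ci, c in enumerate(order[1:]):
        for j in range(p):
            coef = B[ci, j]
            s = se[ci, j]
            z = coef / s if s > 0 else np.nan
            rows.append(
                {
                    "phenotype": c,
                    "term": terms[j],
                    "coef": coef,
                    "se": s,
                    "rrr": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - _Z95 * s)),
                    "ci_high": float(np.exp(coef + _Z95 * s)),
                    "p_value": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                }
            )
    separation = bool(np.abs(B).max(initial=0.0) > _SEPARATION_COEF)
    return AssociationResult(
        table=pd.DataFrame(rows),
        reference=reference,
        loglik=ll,
        converged=converged,
        separation_suspected=separation,
    )


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort log effects."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    n_studies: int


def dl_meta(effects, ses) -> MetaResult:
    """Pool per-cohort log effects with the DerSimonian-Laird estimator.

    Q is Cochran's heterogeneity statistic under fixed-effect weights
    w_i = 1/se_i^2; the between-study variance is the moment estimate
    tau^2 = max(0, (Q - (m-1)) / (sum w - sum w^2 / sum w)), and the pooled
    effect is the inverse-variance mean with weights 1/(se_i^2 + tau^2).
    """
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValidationError("need at least one study")
    if y.shape != se.shape:
        raise ValidationError("effects and ses misaligned")
    if (se <= 0).any():
        raise ValidationError("standard errors must be > 0")
    m = y.size
    w = 1.0 / se**2
    y_fe = float((w * y).sum() / w.sum())
    q = float((w * (y - y_fe) ** 2).sum())
    if m == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (m - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float((w_re * y).sum() / w_re.sum())
    pooled_se = float(np.sqrt(1.0 / w_re.sum()))
    return MetaResult(
        pooled=pooled,
        se=pooled_se,
        ci_low=pooled - 1.96 * pooled_se,
        ci_high=pooled + 1.96 * pooled_se,
        tau2=tau2,
        q=q,
        n_studies=m,
    )
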