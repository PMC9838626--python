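"""Latent class analysis of binary wheeze sequences (Bernoulli mixture).

The comparison arm models each subject's complete length-T sequence as a
finite mixture: class c has weight rho_c and, conditional on class, the
epochs are independent Bernoulli draws with probabilities theta_ct. Fitting
is by EM over the (at most 2^T) distinct sequence patterns with multiplicity
weights, restarted from several random initializations; subjects are
assigned by maximum posterior probability. Identical sequences therefore get
identical posteriors, but the maximum itself can be weak — the source of the
allocation inconsistency the spell-based arm avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .cohort import CohortTable
from .exceptions import ValidationError

__all__ = ["LCAParams", "fit_lca", "lca_posterior"]

_THETA_CLIP = 1e-6


@dataclass
class LCAParams:
    """Fitted Bernoulli-mixture parameters and fit statistics."""

    k: int
    class_weights: np.ndarray  # (k,)
    item_probs: np.ndarray  # (k, T)
    loglik: float
    bic: float
    n_params: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.class_weights.sum() - 1.0) > 1e-10:
            raise ValidationError("class weights must sum to 1")
        if ((self.item_probs < 0) | (self.item_probs > 1)).any():
            raise ValidationError("item probabilities must lie in [0, 1]")


def _pattern_counts(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    patterns, inverse, counts = np.unique(
        data.astype(int), axis=0, return_inverse=True, return_counts=True
    )
    return patterns, inverse, counts


def _log_component_lik(patterns: np.ndarray, theta: np.ndarray) -> np.ndarray:
    # (patterns, k): log P(pattern | class)
    lt = np.log(theta)
    l1t = np.log1p(-theta)
    return patterns @ lt.T + (1 - patterns) @ l1t.T


def fit_lca(
    table: CohortTable,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LCAParams:
    """Fit a k-class Bernoulli mixture by EM, best of ``n_starts`` restarts.

    Requires complete data (the latent-class arm is run on complete cases).
    Item probabilities are clipped to [1e-6, 1 - 1e-6]; convergence is a
    relative log-likelihood change below ``tol``. The returned trace is that
    of the winning restart and is non-decreasing (EM monotonicity).
    """
    if table.n_subjects == 0:
        raise ValidationError("empty table")
    if not table.complete_mask().all():
        raise ValidationError("latent class fit requires complete data")
    if k < 1:
        raise ValidationError("k must be >= 1")
    patterns, _, counts = _pattern_counts(table.data)
    n, T = table.n_subjects, table.n_epochs
    if k > patterns.shape[0]:
        warnings.warn(
            f"k={k} exceeds the {patterns.shape[0]} distinct sequences; "
            "some classes will be redundant",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, bool, list[float]] | None = None
    for _ in range(max(1, n_starts)):
        rho = np.full(k, 1.0 / k)
        theta = np.clip(rng.uniform(0.2, 0.8, size=(k, T)), _THETA_CLIP, 1 - _THETA_CLIP)
        trace: list[float] = []
        converged = False
        prev_ll = -np.inf
        for _it in range(max_iter):
            # E-step on patterns
            logp = _log_component_lik(patterns, theta) + np.log(rho)[None, :]
            norm = logsumexp(logp, axis=1)
            ll = float(counts @ norm)
            trace.append(ll)
            resp = np.exp(logp - norm[:, None]) * counts[:, None]
            # M-step
            nc = resp.sum(axis=0)
            rho = nc / n
            theta = np.clip((resp.T @ patterns) / nc[:, None], _THETA_CLIP, 1 - _THETA_CLIP)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
                converged = True
                break
            prev_ll = ll
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], rho, theta, converged, trace)

    ll, rho, theta, converged, trace = best
    n_params = (k - 1) + k * T
    return LCAParams(
        k=k,
        class_weights=rho,
        item_probs=theta,
        loglik=ll,
        bic=-2.0 * ll + n_params * np.log(n),
        n_params=n_params,
        converged=converged,
        loglik_trace=trace,
    )


def lca_posterior(params: LCAParams, table: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Posterior class responsibilities and maximum-posterior hard labels.

    Rows sum to 1; ties in the argmax go to the lowest class index.
    """
    if table.n_epochs != params.item_probs.shape[1]:
        raise ValidationError("table epoch count does not match fitted parameters")
    if not table.complete_mask().all():
        raise ValidationError("posterior requires complete data")
    patterns, inverse, _ = _pattern_counts(table.data)
    logp = _log_component_lik(patterns, params.item_probs) + np.log(params.class_weights)[None, :]
    post = np.exp(logp - logsumexp(logp, axis=1)[:, None])[inverse]
    return post, np.argmax(post, axis=1)
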