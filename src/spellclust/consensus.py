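"""Multiple-imputation consensus clustering.

Rather than discarding subjects with incomplete follow-up, the cohort is
completed M times by chained-equations imputation, the spell-feature PAM
pipeline is run on each completed dataset, cluster labels are aligned across
imputations by optimal matching, and each subject's phenotype membership is
summarized as the fraction of imputations assigning them to each (aligned)
cluster. The resulting membership probabilities feed the weighted
association stage directly, so no single completed dataset is privileged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort import CohortTable
from .distance import pairwise_distance
from .exceptions import ValidationError
from .features import derive_feature_table
from .pam import pam_fit, profile_silhouette

__all__ = [
    "ImputationEnsemble",
    "MembershipMatrix",
    "impute_chained",
    "align_labels",
    "consensus_cluster",
]

_RIDGE = 1e-3


@dataclass
class ImputationEnsemble:
    """M completed copies of one cohort; observed cells identical throughout."""

    completed_tables: list[CohortTable]
    seed: int

    @property
    def M(self) -> int:
        return len(self.completed_tables)


def _ridge_logistic(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """IRLS ridge-logistic fit, returning a posterior draw of the coefficients.

    The draw from N(beta_hat, (X'WX + lambda I)^-1) is what makes the M
    completions *proper* imputations rather than M copies of one model.
    """
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    H = np.eye(p_dim)
    for _ in range(25):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + _RIDGE * np.eye(p_dim)
        g = X.T @ (y - mu) - _RIDGE * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)
    return rng.multivariate_normal(beta, cov, method="cholesky")


def impute_chained(
    table: CohortTable, M: int = 10, seed: int = 0, cycles: int = 10
) -> ImputationEnsemble:
    """Complete the cohort M times by chained logistic-regression equations.

    Missing cells are initialized by draws from each epoch's observed
    margin; then for ``cycles`` sweeps, each epoch's missing values are
    redrawn from a ridge-logistic model (with coefficient posterior draw) on
    the other epochs' current values. Observed cells are never altered. A
    table with no missing data yields M identical copies.
    """
    data = table.data
    miss = np.isnan(data)
    if miss.all(axis=1).any():
        raise ValidationError("a subject has all epochs missing; filter upstream")
    if miss.all(axis=0).any():
        t = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValidationError(f"epoch {t + 1} has no observed values")

    children = np.random.SeedSequence(seed).spawn(M)
    completed: list[CohortTable] = []
    epoch_means = np.nanmean(data, axis=0)
    miss_cols = [t for t in range(table.n_epochs) if miss[:, t].any()]
    for m in range(M):
        rng = np.random.default_rng(children[m])
        work = data.copy()
        if miss_cols:
            init = (rng.random(data.shape) < epoch_means[None, :]).astype(float)
            work[miss] = init[miss]
            for _ in range(cycles):
                for t in miss_cols:
                    others = [c for c in range(table.n_epochs) if c != t]
                    obs = ~miss[:, t]
                    X = np.column_stack([np.ones(table.n_subjects), work[:, others]])
                    beta = _ridge_logistic(X[obs], data[obs, t], rng)
                    eta = np.clip(X[~obs] @ beta, -30, 30)
                    p = 1.0 / (1.0 + np.exp(-eta))
                    work[~obs, t] = (rng.random(p.shape) < p).astype(float)
        completed.append(
            CohortTable(table.grid, list(table.subject_ids), work, f"{table.name}[imp {m}]")
        )
    return ImputationEnsemble(completed_tables=completed, seed=seed)


def align_labels(
    results: list[np.ndarray], reference: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Permute each labeling to best agree with the reference.

    For each result the k x k overlap (contingency) matrix with the
    reference is built and the label permutation maximizing total agreement
    is found by optimal assignment. Returns the relabeled results and the
    permutations (``perm[old_label] = new_label``).
    """
    reference = np.asarray(reference)
    k = int(reference.max()) + 1
    aligned, perms = [], []
    for res in results:
        res = np.asarray(res)
        if res.shape != reference.shape:
            raise ValidationError("labelings must have equal length")
        if int(res.max()) + 1 != k:
            raise ValidationError(
                f"labelings differ in cluster count ({int(res.max()) + 1} vs {k})"
            )
        overlap = np.zeros((k, k))
        np.add.at(overlap, (res, reference), 1.0)
        rows, cols = linear_sum_assignment(-overlap)
        perm = np.empty(k, dtype=int)
        perm[rows] = cols
        aligned.append(perm[res])
        perms.append(perm)
    return aligned, perms


@dataclass
class MembershipMatrix:
    """Per-subject phenotype membership probabilities from the MI ensemble."""

    subject_ids: list[str]
    probabilities: np.ndarray  # (n, k), rows sum to 1
    consensus: np.ndarray  # argmax labels, ties -> lowest cluster index
    certainty: np.ndarray  # per-subject max probability

    def __post_init__(self) -> None:
        if np.abs(self.probabilities.sum(axis=1) - 1.0).max(initial=0.0) > 1e-10:
            raise ValidationError("membership rows must sum to 1")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValidationError("membership probabilities must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.probabilities.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probabilities,
            columns=[f"p_c{c + 1}" for c in range(self.k)],
        )
        df.insert(0, "subject_id", self.subject_ids)
        df["consensus"] = self.consensus
        df["certainty"] = self.certainty
        return df


def consensus_cluster(
    table: CohortTable,
    M: int = 10,
    seed: int = 0,
    k_range=range(2, 9),
    cycles: int = 10,
) -> tuple[MembershipMatrix, pd.DataFrame, int]:
    """Impute M times, cluster each completion, and pool memberships.

    Within each imputation the spell-feature pipeline is run for every
    candidate k and the silhouette-optimal k recorded; the pooled cluster
    count k* is the modal selection (ties toward the smaller k). Each
    imputation's k* fit is aligned to imputation 1 and membership
    probabilities are the per-cluster assignment fractions.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range is empty")
    ensemble = impute_chained(table, M=M, seed=seed, cycles=cycles)

    fits, selected, diag_rows = [], [], []
    for m, completed in enumerate(ensemble.completed_tables):
        D = pairwise_distance(derive_feature_table(completed))
        per_k = {k: pam_fit(D, k) for k in ks}
        if len(ks) == 1:
            k_sel = ks[0]
        else:
            sils = {k: profile_silhouette(D, per_k[k].assignment) for k in ks}
            k_sel = max(ks, key=lambda k: (sils[k], -k))
        selected.append(k_sel)
        fits.append(per_k)
        diag_rows.append(
            {
                "imputation": m,
                "selected_k": k_sel,
                "avg_silhouette": per_k[k_sel].avg_silhouette,
                "profile_silhouette": profile_silhouette(D, per_k[k_sel].assignment),
                "total_cost": per_k[k_sel].total_cost,
            }
        )

    counts = pd.Series(selected).value_counts()
    top = counts.max()
    k_star = int(min(k for k in counts.index if counts[k] == top))

    assignments = [fits[m][k_star].assignment for m in range(M)]
    aligned, _ = align_labels(assignments, reference=assignments[0])

    n = table.n_subjects
    probs = np.zeros((n, k_star))
    for a in aligned:
        probs[np.arange(n), a] += 1.0
    probs /= M
    membership = MembershipMatrix(
        subject_ids=list(table.subject_ids),
        probabilities=probs,
        consensus=np.argmax(probs, axis=1),
        certainty=probs.max(axis=1),
    )
    return membership, pd.DataFrame(diag_rows), k_star
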