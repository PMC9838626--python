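"""Partition-around-medoids (k-medoids) clustering on a distance matrix.

PAM minimizes the total dissimilarity of points to their cluster medoid. The
implementation uses the classic BUILD greedy initialization followed by
steepest-descent SWAP, with the per-candidate swap costs evaluated from the
nearest/second-nearest medoid distances so one SWAP sweep is O(n^2) rather
than O(k n^2). All tie-breaks go to the lowest index, making the fit fully
deterministic given the distance matrix.

Model selection over the cluster count uses the average silhouette width,
the standard companion criterion for PAM; the per-k diagnostics table is
returned so alternative criteria can be applied externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .exceptions import ValidationError

__all__ = [
    "PAMResult",
    "pam_fit",
    "silhouette_width",
    "profile_groups",
    "profile_silhouette",
    "select_k",
    "assign_nearest_medoid",
]

_SWAP_TOL = 1e-12


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    return DistanceMatrix(np.asarray(D, dtype=float)).values


@dataclass
class PAMResult:
    """A fitted k-medoids partition.

    ``medoid_indices`` are sorted ascending and cluster labels 0..k-1 follow
    that order; ``assignment`` maps each subject to its nearest medoid with
    ties broken toward the lowest medoid index.
    """

    k: int
    medoid_indices: np.ndarray
    assignment: np.ndarray
    total_cost: float
    avg_silhouette: float
    cost_trace: list[float] = field(default_factory=list)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


def _build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def pam_fit(D, k: int) -> PAMResult:
    """Fit PAM with BUILD initialization and SWAP local search.

    SWAP repeatedly applies the single medoid/non-medoid exchange that most
    reduces the total cost, until no exchange improves it. The cost trace of
    each accepted configuration is recorded (non-increasing by construction).
    """
    Dm = _as_matrix(D)
    n = Dm.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, n={n}]")

    medoids = _build(Dm, k)
    trace = [float(Dm[:, medoids].min(axis=1).sum())]

    if 1 < k < n:
        med = np.array(medoids)
        while True:
            Dmed = Dm[:, med]
            pos = np.argmin(Dmed, axis=1)
            d1 = Dmed[np.arange(n), pos]
            d2 = np.partition(Dmed, 1, axis=1)[:, 1]
            # swap-cost decomposition: points losing their nearest medoid
            # reassign to min(new candidate, second nearest); others may
            # only gain from the candidate.
            c_other = np.minimum(Dm - d1[:, None], 0.0)
            c_nearest_extra = (np.minimum(Dm, d2[:, None]) - d1[:, None]) - c_other
            delta = np.empty((k, n))
            delta[:] = c_other.sum(axis=0)[None, :]
            for i in range(k):
                mask = pos == i
                if mask.any():
                    delta[i] += c_nearest_extra[mask].sum(axis=0)
            delta[:, med] = np.inf
            flat = int(np.argmin(delta))
            i, h = divmod(flat, n)
            if delta[i, h] >= -_SWAP_TOL:
                break
            med[i] = h
            trace.append(float(Dm[:, med].min(axis=1).sum()))
        medoids = med.tolist()

    med_sorted = np.array(sorted(medoids))
    assignment = np.argmin(Dm[:, med_sorted], axis=1)
    total_cost = float(Dm[np.arange(n), med_sorted[assignment]].sum())
    avg_sil = np.nan
    if k >= 2:
        _, avg_sil = silhouette_width(Dm, assignment)
    return PAMResult(
        k=k,
        medoid_indices=med_sorted,
        assignment=assignment,
        total_cost=total_cost,
        avg_silhouette=avg_sil,
        cost_trace=trace,
    )


def silhouette_width(D, assignment) -> tuple[np.ndarray, float]:
    """Per-point silhouettes s(i) = (b-a)/max(a,b) and their average.

    a is the mean distance to the point's own cluster (excluding itself), b
    the smallest mean distance to another cluster. Singletons get s = 0, as
    do points at zero distance from both their own and the nearest foreign
    cluster.
    """
    Dm = _as_matrix(D)
    labels = np.asarray(assignment)
    if labels.shape[0] != Dm.shape[0]:
        raise ValidationError("assignment length does not match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    n = Dm.shape[0]
    sums = np.stack([Dm[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    own_size = sizes[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own_size > 1, sums[np.arange(n), own] / np.maximum(own_size - 1, 1), 0.0)
        mean_other = sums / sizes[None, :]
        mean_other[np.arange(n), own] = np.inf
        b = mean_other.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.where(own_size == 1, 0.0, s)
    return s, float(s.mean())


def profile_groups(D) -> tuple[np.ndarray, np.ndarray]:
    """Group subjects into zero-distance equivalence classes.

    With spell features a cohort collapses onto at most 2^T distinct
    profiles, and two subjects share a profile exactly when their distance
    is 0. Returns the representative index (lowest subject index) of each
    group and the group sizes.
    """
    Dm = _as_matrix(D)
    leader = np.argmax(Dm == 0.0, axis=1)  # first zero-distance column
    reps, counts = np.unique(leader, return_counts=True)
    return reps, counts


def profile_silhouette(D, assignment, min_profile_frac: float = 0.005) -> float:
    """Average silhouette over distinct (zero-distance) profiles.

    Massively duplicated profiles make the subject-level average silhouette
    increase monotonically with k — splitting any cluster that holds two
    common profiles always pays — so it cannot select a finite optimum.
    Evaluating the silhouette once per distinct profile restores the
    trade-off. Profiles carried by fewer than ``min_profile_frac`` of
    subjects are ignored (one-off sequences should not drive model
    selection) unless too few profiles would remain. On duplicate-free data
    this reduces exactly to the ordinary average silhouette.
    """
    Dm = _as_matrix(D)
    labels = np.asarray(assignment)
    reps, counts = profile_groups(Dm)
    n = Dm.shape[0]
    keep = counts >= max(1, int(np.ceil(min_profile_frac * n)))
    if keep.sum() < 2 or np.unique(labels[reps[keep]]).size < 2:
        keep = np.ones_like(keep)
    reps = reps[keep]
    lu = labels[reps]
    if np.unique(lu).size < 2:
        return -1.0
    _, avg = silhouette_width(Dm[np.ix_(reps, reps)], lu)
    return avg


def select_k(
    D,
    k_range,
    criterion: str = "profile",
    min_profile_frac: float = 0.005,
) -> tuple[int, pd.DataFrame]:
    """Pick the cluster count maximizing a silhouette criterion (ties: smallest k).

    ``criterion`` is ``"profile"`` (average silhouette over distinct
    zero-distance profiles, the default — appropriate when many subjects
    share identical feature vectors) or ``"subject"`` (the plain average
    silhouette over all points). The diagnostics table reports cost and both
    silhouettes for every candidate.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range is empty")
    if criterion not in ("profile", "subject"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    rows = []
    best_k, best_score = None, -np.inf
    for k in ks:
        res = pam_fit(D, k)
        psil = profile_silhouette(D, res.assignment, min_profile_frac) if k >= 2 else np.nan
        rows.append(
            {
                "k": k,
                "total_cost": res.total_cost,
                "avg_silhouette": res.avg_silhouette,
                "profile_silhouette": psil,
            }
        )
        score = psil if criterion == "profile" else res.avg_silhouette
        if np.isfinite(score) and score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValidationError("no candidate k produced a silhouette (need k >= 2)")
    return best_k, pd.DataFrame(rows)


def assign_nearest_medoid(dist_to_medoids) -> np.ndarray:
    """Label items by their nearest medoid (columns in medoid order).

    Ties go to the lowest medoid index, matching ``pam_fit``'s own
    assignment rule, so training items reproduce the fit's labels.
    """
    M = np.asarray(dist_to_medoids, dtype=float)
    if M.ndim != 2:
        raise ValidationError("expected an (items x medoids) distance array")
    return np.argmin(M, axis=1)
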