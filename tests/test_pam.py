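import itertools

import numpy as np
import pytest

from spellclust import (
    ValidationError,
    adjusted_rand,
    assign_nearest_medoid,
    pam_fit,
    profile_silhouette,
    select_k,
    silhouette_width,
)

LINE = np.abs(
    np.subtract.outer([0.0, 1.0, 2.0, 10.0, 11.0, 12.0], [0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
)


def brute_force_cost(D, k):
    n = D.shape[0]
    return min(
        D[:, list(s)].min(axis=1).sum() for s in itertools.combinations(range(n), k)
    )


def reference_silhouette(D, labels):
    """Independent per-point silhouette, straight from the definition."""
    out = []
    for i in range(len(labels)):
        own = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(len(labels)) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        out.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return np.array(out)


class TestPamFit:
    def test_two_clusters_on_a_line(self):
        # exhaustive search over all C(6,2) medoid pairs gives medoids at the
        # values 1 and 11 with total cost 4
        res = pam_fit(LINE, 2)
        assert list(res.medoid_indices) == [1, 4]
        assert res.total_cost == pytest.approx(4.0)
        assert res.total_cost == pytest.approx(brute_force_cost(LINE, 2))

    def test_k_equals_n_is_free(self):
        res = pam_fit(LINE, 6)
        assert res.total_cost == 0.0
        assert len(set(res.assignment)) == 6

    def test_cost_never_below_brute_force_on_random_instances(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            A = rng.random((10, 10))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0.0)
            for k in (2, 3):
                res = pam_fit(D, k)
                assert res.total_cost >= brute_force_cost(D, k) - 1e-9

    def test_optimal_on_clustered_instances(self):
        # on clearly clusterable data BUILD+SWAP reaches the global optimum
        centers = np.array([[0, 0], [4, 0], [2, 3.5]])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            P = centers[rng.integers(0, 3, 10)] + rng.normal(0, 0.4, (10, 2))
            D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
            res = pam_fit(D, 3)
            assert res.total_cost <= brute_force_cost(D, 3) * 1.05 + 1e-12

    def test_cost_trace_non_increasing(self):
        rng = np.random.default_rng(1)
        P = rng.random((40, 2))
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        res = pam_fit(D, 4)
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_trace, res.cost_trace[1:]))
        # reported cost equals recomputed assignment cost
        recomputed = D[np.arange(40), res.medoid_indices[res.assignment]].sum()
        assert res.total_cost == pytest.approx(recomputed, abs=1e-10)

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        P = rng.random((30, 2))
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        perm = rng.permutation(30)
        res = pam_fit(D, 3)
        res_p = pam_fit(D[np.ix_(perm, perm)], 3)
        back = np.empty(30, dtype=int)
        back[perm] = np.arange(30)
        assert adjusted_rand(res.assignment, res_p.assignment[back[np.arange(30)]]) == pytest.approx(1.0)
        assert res_p.total_cost == pytest.approx(res.total_cost, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            pam_fit(LINE, 7)
        with pytest.raises(ValidationError):
            pam_fit(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)


class TestSilhouette:
    def test_tight_separated_blobs_score_high(self):
        rng = np.random.default_rng(0)
        P = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(10, 0.05, (10, 2))])
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        _, avg = silhouette_width(D, np.repeat([0, 1], 10))
        assert avg > 0.9

    def test_equidistant_point_scores_zero(self):
        # point 2 sits exactly between the two clusters
        D = np.abs(np.subtract.outer([0.0, 0.0, 1.0, 2.0, 2.0], [0.0, 0.0, 1.0, 2.0, 2.0]))
        s, _ = silhouette_width(D, np.array([0, 0, 0, 1, 1]))
        assert s[2] == pytest.approx(0.0)

    def test_matches_reference_implementation_on_line(self):
        res = pam_fit(LINE, 2)
        s, avg = silhouette_width(LINE, res.assignment)
        ref = reference_silhouette(LINE, list(res.assignment))
        assert np.abs(s - ref).max() < 1e-12
        assert avg == pytest.approx(ref.mean(), abs=1e-12)

    def test_average_in_unit_interval_random_labels(self):
        rng = np.random.default_rng(7)
        P = rng.random((25, 2))
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        for _ in range(5):
            labels = rng.integers(0, 3, 25)
            if len(set(labels)) < 2:
                continue
            _, avg = silhouette_width(D, labels)
            assert -1.0 <= avg <= 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette_width(LINE, np.zeros(6, dtype=int))


class TestSelectK:
    def test_line_prefers_two_clusters(self):
        k, diag = select_k(LINE, range(2, 5))
        assert k == 2
        assert list(diag["k"]) == [2, 3, 4]

    def test_profile_criterion_reduces_to_subject_on_distinct_points(self):
        _, diag = select_k(LINE, range(2, 5))
        assert np.allclose(diag["avg_silhouette"], diag["profile_silhouette"])

    def test_single_blob_still_returns_argmax(self):
        rng = np.random.default_rng(11)
        P = rng.random((30, 2))
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        k, diag = select_k(D, range(2, 6))
        assert k in range(2, 6)
        assert diag["avg_silhouette"].max() < 0.7  # no real structure

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            select_k(LINE, [])

    def test_profile_silhouette_ignores_duplication_level(self):
        # replicating points must not change the profile criterion
        reps = np.repeat(np.arange(6), [5, 1, 1, 1, 1, 5])
        D_rep = LINE[np.ix_(reps, reps)]
        labels = (np.array([0, 0, 0, 1, 1, 1])[reps])
        assert profile_silhouette(D_rep, labels, min_profile_frac=0.0) == pytest.approx(
            profile_silhouette(LINE, np.array([0, 0, 0, 1, 1, 1]), min_profile_frac=0.0)
        )


class TestAssignNearestMedoid:
    def test_medoid_maps_to_own_cluster_and_ties_go_low(self):
        dist = np.array(
            [
                [0.0, 2.0],  # a medoid itself
                [1.5, 1.5],  # tie -> medoid 0
                [3.0, 0.5],
            ]
        )
        assert list(assign_nearest_medoid(dist)) == [0, 0, 1]

    def test_consistent_with_training_assignment(self):
        rng = np.random.default_rng(13)
        P = rng.random((40, 2))
        D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
        res = pam_fit(D, 3)
        again = assign_nearest_medoid(D[:, res.medoid_indices])
        assert np.array_equal(again, res.assignment)
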