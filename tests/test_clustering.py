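"""PCA, Ward linkage, elbow rule and ROC cut-point."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cst_recovery import (
    elbow_k,
    pca_scores,
    roc_cutoff,
    stratified_reanalysis,
    ward_cluster,
)


def exhaustive_ward(X):
    """Brute-force Ward oracle: recompute every candidate merge's ESS increase
    from scratch (centroids over members) and pick the cheapest, ties toward
    the lowest cluster-index pair in creation order."""
    X = np.asarray(X, dtype=float)
    clusters = [frozenset([i]) for i in range(len(X))]
    active = list(range(len(X)))
    merges = []

    def ess(members):
        pts = X[sorted(members)]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    while len(active) > 1:
        best = None
        for ia, ib in itertools.combinations(range(len(active)), 2):
            a, b = active[ia], active[ib]
            cost = ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        cost, a, b = best
        merges.append((clusters[a] | clusters[b], cost))
        clusters.append(clusters[a] | clusters[b])
        active = [c for c in active if c not in (a, b)] + [len(clusters) - 1]
    return merges


class TestPCA:
    def test_identical_columns_rank_one(self):
        x = np.arange(10.0)
        p = pca_scores(x, x)
        assert p.explained_shares[0] == pytest.approx(1.0)
        assert p.explained_shares[1] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_columns_split_evenly(self, rng):
        p = pca_scores(rng.normal(size=5000), rng.normal(size=5000))
        assert p.explained_shares[0] == pytest.approx(0.5, abs=0.05)

    def test_first_share_closed_form(self, rng):
        # for a 2x2 correlation matrix the eigenvalues are 1 +- r
        x = rng.normal(size=400)
        y = 0.8 * x + 0.6 * rng.normal(size=400)
        r = np.corrcoef(x, y)[0, 1]
        p = pca_scores(x, y)
        assert p.explained_shares[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-12)

    def test_strong_pair_share_value(self):
        # r = 0.789 gives a first-component share of (1 + 0.789)/2 ~ 0.894
        assert (1 + 0.789) / 2 == pytest.approx(0.8945)

    def test_component_scores_uncorrelated(self, rng):
        x = rng.normal(size=100)
        y = 0.7 * x + rng.normal(size=100)
        p = pca_scores(x, y)
        assert abs(np.corrcoef(p.scores.T)[0, 1]) < 1e-10

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_scores(np.ones(10), np.arange(10.0))


class TestWard:
    def test_separable_clouds_recovered(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + 0.2 * rng.normal(size=(15, 2)) for c in centers])
        sol = ward_cluster(X)
        labels = sol.labels_for_k(3)
        truth = np.repeat([1, 2, 3], 15)
        # same partition up to label names
        assert len(set(zip(labels, truth))) == 3

    def test_identical_points_zero_wss(self):
        X = np.ones((6, 2))
        sol = ward_cluster(X)
        assert np.allclose(sol.wss, 0.0)

    def test_wss_endpoints_and_monotonicity(self, rng):
        X = rng.normal(size=(20, 2))
        sol = ward_cluster(X)
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert sol.wss[0] == pytest.approx(tss)
        assert sol.wss[-1] == pytest.approx(0.0)
        assert np.all(np.diff(sol.wss) <= 1e-9)
        assert np.all(np.diff(sol.merges[:, 2]) >= -1e-9)  # Ward heights rise

    def test_merge_sequence_matches_exhaustive_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2))
            sol = ward_cluster(X)
            oracle = exhaustive_ward(X)
            # rebuild member sets from the linkage for comparison
            members = [frozenset([i]) for i in range(n)]
            for (a, b, h, _), (oracle_set, oracle_cost) in zip(sol.merges, oracle):
                merged = members[int(a)] | members[int(b)]
                members.append(merged)
                assert merged == oracle_set
                assert h == pytest.approx(oracle_cost, rel=1e-9, abs=1e-12)

    def test_matches_scipy_ward_heights(self, rng):
        scipy_hier = pytest.importorskip("scipy.cluster.hierarchy")
        X = rng.normal(size=(30, 2))
        sol = ward_cluster(X)
        Z = scipy_hier.linkage(X, method="ward")
        # scipy's ward heights h satisfy h^2 / 2 = ESS increase
        assert np.allclose(np.sort(Z[:, 2] ** 2 / 2), np.sort(sol.merges[:, 2]))
        labels = sol.labels_for_k(4)
        scipy_labels = scipy_hier.fcluster(Z, 4, criterion="maxclust")
        assert len(set(zip(labels, scipy_labels))) == 4


class TestElbow:
    def test_sharp_kink_at_three(self):
        assert elbow_k([100.0, 60.0, 20.0, 18.0, 16.0]) == 3
        assert elbow_k([100.0, 60.0, 20.0, 18.0, 16.0], method="second_difference") == 3

    def test_linear_profile_warns_and_returns_smallest(self):
        with pytest.warns(UserWarning, match="no clear elbow"):
            k = elbow_k(np.linspace(100, 10, 8))
        assert k == 2

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            elbow_k([10.0, 5.0])


class TestROC:
    def test_perfect_separation_at_boundary(self):
        scores = np.array([10, 20, 30, 34, 35, 40, 50])
        high = scores >= 35
        cut = roc_cutoff(scores, high)
        assert cut.threshold == 35 and cut.youden_j == pytest.approx(1.0)

    def test_hand_built_example(self):
        cut = roc_cutoff(np.array([5, 10, 20, 40, 50]), np.array([0, 0, 0, 1, 1], bool))
        assert cut.threshold == 40

    def test_equals_exhaustive_search_always(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 67, size=n).astype(float)
            high = rng.random(n) < 0.4
            if high.all() or not high.any():
                continue
            cut = roc_cutoff(scores, high)
            best_j, best_t = -np.inf, None
            for t in np.unique(scores):
                j = np.mean(scores[high] >= t) + np.mean(scores[~high] < t) - 1
                if j > best_j + 1e-12:
                    best_j, best_t = j, t
            assert cut.threshold == best_t
            assert cut.youden_j == pytest.approx(best_j)

    def test_identical_distributions_warn(self, rng):
        scores = np.tile(np.arange(10.0), 4)
        high = np.tile([True, False], 20)
        with pytest.warns(UserWarning, match="barely separable"):
            roc_cutoff(scores, high)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_cutoff(np.arange(5.0), np.ones(5, bool))


class TestStratifiedReanalysis:
    @staticmethod
    def null_cohort(rng, n=120):
        init = rng.integers(0, 60, size=n)
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "age": rng.integers(20, 90, size=n),
                "sex": rng.choice(["M", "F"], size=n),
                "lesion_location": rng.choice(["cortical", "subcortical"], size=n),
                "cst_injury": rng.integers(0, 16, size=n) / 16,
                "lesion_volume_mm3": rng.lognormal(9, 1, size=n),
                "initial_fma_ue": init,
                "followup_fma_ue": np.clip(init + rng.integers(0, 10, size=n), 0, 66),
            }
        )

    def test_null_injury_effect_propagates_through_strata(self, rng):
        cohort = self.null_cohort(rng)
        out = stratified_reanalysis(cohort, 35, "UE")
        for key in ("full", "severe"):
            screen = out[key]["screen"].table
            injury_row = screen[screen.covariate == "cst_injury"].iloc[0]
            assert not injury_row.significant
        assert out["n_full"] == out["n_severe"] + out["n_high"]

    def test_empty_stratum_rejected(self, rng):
        cohort = self.null_cohort(rng)
        with pytest.raises(ValueError, match="nonempty"):
            stratified_reanalysis(cohort, 100, "UE")
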