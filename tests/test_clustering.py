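"""State discovery: correlation-distance k-means, elbow selection, AMI
replicate choice, state naming, centroid dendrogram."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from statedyn.clustering import (
    adjusted_mutual_information,
    centroid_dendrogram,
    concatenate_scans,
    correlation_distance,
    explained_variance_curve,
    kmeans_correlation,
    name_states,
    replicated_clustering,
    select_k_elbow,
    select_partition_ami,
)
from statedyn.synthetic import generate_centroids, generate_network_templates
from statedyn.types import RoiTimeSeries


def _brute_force_two_partition(X):
    """Exhaustive minimum of total correlation distance over all 2-labelings."""
    def standardize(rows):
        rows = rows - rows.mean(axis=1, keepdims=True)
        return rows / np.linalg.norm(rows, axis=1)[:, None]

    Xn = standardize(X)
    best_cost, best_labels = np.inf, None
    F = X.shape[0]
    for bits in itertools.product([0, 1], repeat=F):
        labels = np.array(bits)
        if labels.min() == labels.max():
            continue
        cost = 0.0
        for j in (0, 1):
            members = Xn[labels == j]
            c = members.mean(axis=0)
            c = c - c.mean()
            cn = c / np.linalg.norm(c)
            cost += np.sum(1.0 - members @ cn)
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_cost, best_labels


class TestConcatenate:
    def _scan(self, data, sid, cond, censor=None):
        return RoiTimeSeries(data=data, tr_seconds=1.0, subject_id=sid,
                             condition=cond, censor_mask=censor)

    def test_uncensored_scans_stack_fully(self, rng):
        scans = [self._scan(rng.normal(size=(520, 8)), "s1", "PL"),
                 self._scan(rng.normal(size=(520, 8)), "s1", "MP")]
        X, idx = concatenate_scans(scans)
        assert X.shape == (1040, 8) and len(idx) == 1040

    def test_censored_frames_dropped_without_index_entries(self, rng):
        censor = np.ones(520, dtype=bool)
        censor[100:120] = False
        scans = [self._scan(rng.normal(size=(520, 8)), "s1", "PL", censor)]
        X, idx = concatenate_scans(scans)
        assert X.shape[0] == 500
        assert not idx["frame"].isin(range(100, 120)).any()

    def test_round_trip_reconstructs_kept_frames(self, rng):
        censor = rng.random(100) > 0.1
        scans = [self._scan(rng.normal(size=(100, 5)), "s1", "PL", censor),
                 self._scan(rng.normal(size=(100, 5)), "s2", "MP")]
        X, idx = concatenate_scans(scans)
        for s_i, ts in enumerate(scans):
            rows = idx.index[idx["scan"] == s_i].to_numpy()
            frames = idx.loc[rows, "frame"].to_numpy()
            assert np.array_equal(X[rows], ts.data[frames])

    def test_mixed_roi_counts_rejected(self, rng):
        scans = [self._scan(rng.normal(size=(10, 5)), "a", "PL"),
                 self._scan(rng.normal(size=(10, 6)), "b", "PL")]
        with pytest.raises(ValueError):
            concatenate_scans(scans)


class TestKmeansCorrelation:
    def test_distance_bounds(self, rng):
        x = rng.normal(size=12)
        assert correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert correlation_distance(x, -x) == pytest.approx(2.0, abs=1e-12)

    def test_separable_patterns_recovered_with_full_explained_variance(self, rng):
        a = rng.normal(size=16)
        b = rng.normal(size=16)
        b -= (b @ a) / (a @ a) * a  # orthogonalize
        rows, truth = [], []
        for i in range(40):
            sign = 1 if i % 2 else -1
            pattern = a if i % 4 < 2 else b
            rows.append(sign * pattern)
            truth.append((i % 4 < 2, sign))
        X = np.array(rows)
        res = kmeans_correlation(X, 4, n_restarts=20, seed=0)
        assert res.explained_variance == pytest.approx(1.0, abs=1e-10)
        # exact recovery up to label permutation
        groups = {}
        for lab, t in zip(res.labels, truth):
            groups.setdefault(t, set()).add(lab)
        assert all(len(g) == 1 for g in groups.values())
        assert len({next(iter(g)) for g in groups.values()}) == 4

    def test_six_frame_toy_matches_exhaustive_search(self, rng):
        u = np.array([1.0, -1.0, 0.5, -0.5])
        v = np.array([-0.2, 1.0, -1.0, 0.2])
        X = np.array([u, u, u, v, v, v]) + rng.normal(0, 0.01, size=(6, 4))
        res = kmeans_correlation(X, 2, n_restarts=20, seed=1)
        best_cost, best_labels = _brute_force_two_partition(X)
        assert res.inertia == pytest.approx(best_cost, abs=1e-9)
        same = (res.labels == best_labels).all() or (res.labels == 1 - best_labels).all()
        assert same

    def test_zero_variance_row_rejected_with_frame_number(self, rng):
        X = rng.normal(size=(10, 6))
        X[3] = 2.0
        with pytest.raises(ValueError, match="3"):
            kmeans_correlation(X, 2, n_restarts=2, seed=0)

    def test_assignment_is_fixed_point(self, rng):
        X = rng.normal(size=(60, 12))
        res = kmeans_correlation(X, 4, n_restarts=5, seed=3)
        Cn = res.centroids / np.linalg.norm(res.centroids, axis=1)[:, None]
        Xc = X - X.mean(axis=1, keepdims=True)
        Xn = Xc / np.linalg.norm(Xc, axis=1)[:, None]
        assert np.array_equal((Xn @ Cn.T).argmax(axis=1), res.labels)

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(50, 10))
        r1 = kmeans_correlation(X, 3, n_restarts=5, seed=11)
        r2 = kmeans_correlation(X, 3, n_restarts=5, seed=11)
        assert np.array_equal(r1.labels, r2.labels) and r1.inertia == r2.inertia


class TestExplainedVarianceAndElbow:
    def test_noiseless_planted_data_reaches_ev_one_at_k_true(self, rng):
        t = generate_network_templates(32, seed=0)
        cen = generate_centroids(t, 4)
        X = cen[rng.integers(0, 4, size=200)]
        curve = explained_variance_curve(X, 3, 6, n_restarts=10, seed=0)
        assert curve.loc[4] == pytest.approx(1.0, abs=1e-9)
        assert ((curve >= -1e-12) & (curve <= 1 + 1e-12)).all()

    def test_running_max_of_curve_nondecreasing(self, rng):
        X = rng.normal(size=(150, 12))
        curve = explained_variance_curve(X, 3, 8, n_restarts=8, seed=1)
        assert (np.diff(np.maximum.accumulate(curve.to_numpy())) >= -1e-12).all()

    def test_elbow_direct_rule(self):
        curve = pd.Series([0.80, 0.90, 0.95, 0.955, 0.957], index=range(3, 8))
        res = select_k_elbow(curve)
        assert res.k == 5 and not res.fell_back

    def test_elbow_fallback_when_gains_stay_large(self):
        curve = pd.Series([0.1, 0.3, 0.5, 0.7], index=range(3, 7))
        with pytest.warns(UserWarning):
            res = select_k_elbow(curve)
        assert res.k == 6 and res.fell_back


class TestAmiSelection:
    def test_identical_and_permuted_labelings_score_one(self, rng):
        p = rng.integers(0, 4, size=500)
        assert adjusted_mutual_information(p, p) == pytest.approx(1.0)
        perm = np.array([2, 3, 0, 1])
        assert adjusted_mutual_information(p, perm[p]) == pytest.approx(1.0)

    def test_independent_labelings_score_near_zero(self, rng):
        p1 = rng.integers(0, 4, size=1000)
        p2 = rng.integers(0, 4, size=1000)
        assert abs(adjusted_mutual_information(p1, p2)) < 0.05

    def test_matches_hypergeometric_oracle_on_small_labelings(self):
        # independent oracle: AMI = (MI - E[MI]) / (mean(H1,H2) - E[MI])
        from math import lgamma, log

        def ami_oracle(l1, l2):
            l1, l2 = np.asarray(l1), np.asarray(l2)
            n = len(l1)
            cats1, cats2 = np.unique(l1), np.unique(l2)
            a = np.array([(l1 == c).sum() for c in cats1])
            b = np.array([(l2 == c).sum() for c in cats2])
            mi = 0.0
            for i, c1 in enumerate(cats1):
                for j, c2 in enumerate(cats2):
                    nij = ((l1 == c1) & (l2 == c2)).sum()
                    if nij:
                        mi += nij / n * log(n * nij / (a[i] * b[j]))
            h1 = -sum(x / n * log(x / n) for x in a)
            h2 = -sum(x / n * log(x / n) for x in b)
            emi = 0.0
            for ai in a:
                for bj in b:
                    lo, hi = max(1, ai + bj - n), min(ai, bj)
                    for nij in range(lo, hi + 1):
                        term1 = nij / n * log(n * nij / (ai * bj))
                        term2 = np.exp(
                            lgamma(ai + 1) + lgamma(bj + 1) + lgamma(n - ai + 1)
                            + lgamma(n - bj + 1) - lgamma(n + 1) - lgamma(nij + 1)
                            - lgamma(ai - nij + 1) - lgamma(bj - nij + 1)
                            - lgamma(n - ai - bj + nij + 1))
                        emi += term1 * term2
            return (mi - emi) / ((h1 + h2) / 2 - emi)

        rng = np.random.default_rng(0)
        for _ in range(5):
            l1 = rng.integers(0, 3, size=30)
            l2 = rng.integers(0, 3, size=30)
            assert adjusted_mutual_information(l1, l2) == pytest.approx(
                ami_oracle(l1, l2), abs=1e-8)

    def test_replicate_with_highest_cumulative_ami_selected(self, rng):
        X = rng.normal(size=(80, 10))
        reps = [kmeans_correlation(X, 3, n_restarts=1, seed=s) for s in range(10)]
        chosen = select_partition_ami(reps)
        def cum(i):
            return sum(adjusted_mutual_information(reps[i].labels, reps[j].labels)
                       for j in range(10) if j != i)
        best = max(cum(i) for i in range(10))
        chosen_i = next(i for i, r in enumerate(reps) if r is chosen)
        assert cum(chosen_i) == pytest.approx(best)

    def test_identical_pair_beats_odd_one_out(self, rng):
        X = rng.normal(size=(60, 8))
        r1 = kmeans_correlation(X, 3, n_restarts=10, seed=4)
        r2 = kmeans_correlation(X, 3, n_restarts=10, seed=4)
        r3 = kmeans_correlation(X, 3, n_restarts=1, seed=99)
        chosen = select_partition_ami([r1, r2, r3])
        assert chosen in (r1, r2)

    def test_all_identical_ties_break_to_first(self, rng):
        X = rng.normal(size=(40, 6))
        reps = [kmeans_correlation(X, 2, n_restarts=5, seed=1) for _ in range(3)]
        assert select_partition_ami(reps) is reps[0]


@pytest.fixture(scope="module")
def templates():
    return generate_network_templates(64, seed=2)


class TestNaming:

    def test_pure_positive_indicator_named_net_plus(self, templates):
        c = templates.indicator("FPN")
        catalog = name_states(c[None, :], templates)
        assert catalog.names == ["FPN+"]

    def test_pure_negative_indicator_named_net_minus(self, templates):
        c = -templates.indicator("VIS")
        catalog = name_states(c[None, :], templates)
        assert catalog.names == ["VIS-"]

    def test_zero_centroid_unnameable(self, templates):
        with pytest.raises(ValueError):
            name_states(np.zeros((1, templates.n_rois)), templates)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_negation_flips_sign_suffix(self, templates, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=templates.n_rois)
        n1 = name_states(c[None, :], templates).names[0]
        n2 = name_states(-c[None, :], templates).names[0]
        assert n1[:-1] == n2[:-1]
        assert {n1[-1], n2[-1]} == {"+", "-"}


class TestDendrogram:
    def test_planted_pairs_split_into_association_vs_sensorimotor_groups(self):
        t = generate_network_templates(232, seed=0)
        cen = generate_centroids(t, 6)
        names = ["FPN+", "FPN-", "SOM+", "SOM-", "VIS+", "VIS-"]
        groups, corr, _ = centroid_dendrogram(cen)
        by_group = {}
        for nm, g in zip(names, groups):
            by_group.setdefault(g, set()).add(nm)
        assert set(map(frozenset, by_group.values())) == {
            frozenset({"FPN+", "SOM-", "VIS-"}), frozenset({"FPN-", "SOM+", "VIS+"})}

    def test_two_centroids_one_per_group(self, rng):
        cen = rng.normal(size=(2, 10))
        groups, corr, _ = centroid_dendrogram(cen)
        assert set(groups) == {1, 2}

    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        cen = rng.normal(size=(5, 20))
        _, corr, _ = centroid_dendrogram(cen)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)


class TestLabelPermutationInvariance:
    def test_inertia_and_ev_invariant_under_relabeling(self, rng):
        X = rng.normal(size=(60, 10))
        res = kmeans_correlation(X, 3, n_restarts=5, seed=2)
        perm = np.array([2, 0, 1])
        permuted_labels = perm[res.labels]
        # recompute inertia under the permuted labeling with permuted centroids
        inv = np.argsort(perm)
        C = res.centroids[inv]
        Cn = C / np.linalg.norm(C, axis=1)[:, None]
        Xc = X - X.mean(axis=1, keepdims=True)
        Xn = Xc / np.linalg.norm(Xc, axis=1)[:, None]
        inertia = np.sum(1.0 - (Xn @ Cn.T)[np.arange(60), permuted_labels])
        assert inertia == pytest.approx(res.inertia, abs=1e-9)
        assert adjusted_mutual_information(res.labels, permuted_labels) == pytest.approx(1.0)
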