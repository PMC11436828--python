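import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parcelfuse as pf
from parcelfuse.emission import prepare_dataset
from parcelfuse.metrics import (
    DistanceBinning,
    adjusted_rand_index,
    dcbc,
    inter_subject_variability,
    mds_embed,
    prediction_error,
    profile_matrix,
    reliability_adjusted_ari,
)
from parcelfuse.spaces import make_symmetric_grid
from parcelfuse.synthetic import random_voronoi_labels, sample_smooth_noise


def ari_pair_counting(a, b):
    """Exhaustive oracle: count agreeing/disagreeing voxel pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += not same_a and same_b
        dd += not (same_a or same_b)
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


class TestARI:
    @pytest.mark.parametrize(
        "a,b,value",
        [
            ([0, 0, 1, 1], [1, 1, 0, 0], 1.0),
            ([0, 0, 1, 1], [0, 0, 1, 1], 1.0),
            ([0, 0, 1, 1], [0, 1, 0, 1], -0.5),
        ],
    )
    def test_known_values(self, a, b, value):
        assert adjusted_rand_index(a, b) == pytest.approx(value, abs=1e-12)

    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=60
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_pair_counting_oracle(self, labels):
        a = [x for x, _ in labels]
        b = [y for _, y in labels]
        assert adjusted_rand_index(a, b) == pytest.approx(ari_pair_counting(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([], [])


class TestReliabilityAdjustedARI:
    def test_self_comparison_is_one(self, rng):
        # a consistent ladder: each level refines a common base partition
        base = rng.integers(0, 4, 60)
        ladder = [base] + [base * 2 + rng.integers(0, 2, 60) for _ in range(4)]
        assert reliability_adjusted_ari(ladder, ladder) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        a = [rng.integers(0, 3, 40) for _ in range(3)]
        b = [np.concatenate([x[5:], x[:5]]) for x in a]
        between = np.mean(
            [adjusted_rand_index(x, y) for i, x in enumerate(a) for j, y in enumerate(b) if i != j]
        )
        wa = np.mean([adjusted_rand_index(x, y) for x, y in itertools.combinations(a, 2)])
        wb = np.mean([adjusted_rand_index(x, y) for x, y in itertools.combinations(b, 2)])
        expected = between / np.sqrt(wa * wb)
        assert reliability_adjusted_ari(a, b) == pytest.approx(expected, abs=1e-12)

    def test_unreliable_set_rejected(self, rng):
        # within-set ARI ~ 0 for independent random ladders
        a = [rng.integers(0, 2, 10) for _ in range(3)]
        bad = [np.array([0, 1] * 5), np.array([1, 0] * 5), np.array([0, 0, 1, 1, 0] * 2)]
        with pytest.raises(ValueError):
            reliability_adjusted_ari(bad, a)


class TestDCBC:
    def test_single_parcel_rejected(self, rng):
        space = make_symmetric_grid(4, 4)
        with pytest.raises(ValueError, match="no boundaries"):
            dcbc(np.zeros(16, dtype=int), rng.standard_normal((16, 5)), space)

    def test_invariant_to_joint_relabeling(self, rng):
        space = make_symmetric_grid(6, 6)
        data = sample_smooth_noise(space, seed=rng)
        labels = random_voronoi_labels(space, 4, seed=rng)
        base = dcbc(labels, data, space)
        perm = rng.permutation(4)
        assert dcbc(perm[labels], data, space) == pytest.approx(base, abs=1e-12)

    def test_generating_parcellation_scores_positive(self, small_world):
        space, truth, datasets = small_world
        labels = np.argmax(truth.group_prob, axis=0)
        data = profile_matrix(prepare_dataset(datasets[0])[0])
        assert dcbc(labels, data, space) > 0.1

    def test_null_distribution_centered(self, rng):
        space = make_symmetric_grid(10, 10)
        binning = DistanceBinning(space)
        vals = [
            dcbc(
                random_voronoi_labels(space, 5, seed=rng),
                sample_smooth_noise(space, n_conditions=40, seed=rng),
                space,
                binning,
            )
            for _ in range(30)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_binning_excludes_far_pairs(self):
        space = make_symmetric_grid(10, 2)
        binning = DistanceBinning(space, bin_width=1.0, max_dist=3.0)
        d = space.pairwise_distances()
        assert np.all(d[binning.pair_i, binning.pair_j] < 3.0)
        assert binning.n_bins <= 3


class TestPredictionError:
    def test_parallel_prediction_is_zero(self):
        labels = np.array([0, 0, 1, 1])
        data = np.array([[1.0, 0], [2.0, 0], [0, 1.0], [0, 3.0]])
        assert prediction_error(labels, [data], data) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_prediction_is_one(self):
        labels = np.array([0, 0])
        train = np.array([[1.0, 0.0], [1.0, 0.0]])
        test = np.array([[0.0, 1.0], [0.0, 2.0]])
        assert prediction_error(labels, [train], test) == pytest.approx(1.0, abs=1e-12)

    def test_matches_weighted_mean_oracle(self, rng):
        P, N, K = 30, 6, 3
        labels = rng.integers(0, K, P)
        train = [rng.standard_normal((P, N)) for _ in range(4)]
        test = rng.standard_normal((P, N))
        result = prediction_error(labels, train, test)

        means = np.zeros((K, N))
        for k in range(K):
            means[k] = np.concatenate([X[labels == k] for X in train]).sum(axis=0)
        num = den = 0.0
        for i in range(P):
            w = np.linalg.norm(test[i])
            v = means[labels[i]]
            err = 1 - (v @ test[i]) / (np.linalg.norm(v) * w)
            num += w * err
            den += w
        assert result == pytest.approx(num / den, abs=1e-12)

    def test_empty_region_voxels_excluded(self):
        labels = np.array([0, 1])
        train = np.array([[1.0, 0.0], [1.0, 0.0]])
        train_labels = [np.array([0, 0])]  # region 1 never seen in training
        err = prediction_error(labels, [train], np.eye(2), train_labels=train_labels)
        assert err == pytest.approx(0.0, abs=1e-12)  # only voxel 0 scored


class TestInterSubjectVariability:
    def _dataset(self, data):
        import pandas as pd

        S, P, N = data.shape
        info = pd.DataFrame(
            {"session": 0, "run": np.repeat([0, 1], N // 2), "condition": list(range(N // 2)) * 2}
        )
        return pf.FunctionalDataset("iv", [f"s{i}" for i in range(S)], data, info)

    def test_identical_noise_free_subjects_give_one(self, rng):
        base = rng.standard_normal((1, 10, 4))
        data = np.tile(np.concatenate([base, base], axis=2), (4, 1, 1))
        out = inter_subject_variability(self._dataset(data))
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((3, 8, 6))
        ds = self._dataset(data)
        scaled = data.copy()
        scaled[1] *= 2.0
        assert np.allclose(
            inter_subject_variability(ds),
            inter_subject_variability(self._dataset(scaled)),
            atol=1e-10,
            equal_nan=True,
        )

    def test_independent_subjects_near_zero(self, rng):
        data = rng.standard_normal((6, 5, 40))
        # give every subject reliable (self-consistent) halves
        data[:, :, 20:] = data[:, :, :20] + 0.1 * rng.standard_normal((6, 5, 20))
        out = inter_subject_variability(self._dataset(data))
        assert abs(np.nanmean(out)) < 0.15


class TestMDS:
    def test_equidistant_triple_forms_equilateral_triangle(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        X = mds_embed(S, dims=2)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        off = d[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0], atol=1e-10)

    def test_euclidean_round_trip(self, rng):
        pts = rng.standard_normal((6, 2)) * 0.2
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        X = mds_embed(1.0 - D, dims=2)
        D2 = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_diagonal_shift_ignored(self, rng):
        pts = rng.standard_normal((5, 2)) * 0.1
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        S = 1.0 - D
        X1 = mds_embed(S, dims=2)
        X2 = mds_embed(S + np.eye(5) * 0.3, dims=2)
        assert np.allclose(X1, X2, atol=1e-8)

    def test_too_many_dims_rejected(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        with pytest.raises(ValueError):
            mds_embed(S, dims=3)
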