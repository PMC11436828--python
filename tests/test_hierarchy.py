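import numpy as np
import pytest
from scipy.stats import spearmanr

import parcelfuse as pf
from parcelfuse.arrangement import Arrangement
from parcelfuse.emission import VmfEmission
from parcelfuse.fusion import FusedModel
from parcelfuse.hierarchy import (
    _merge_pair,
    boundary_symmetry,
    build_domains,
    colormap_from_similarity,
    lateralization_index,
    merge_until_winners,
    parcel_similarity,
    profile_regression,
    region_size_asymmetry,
)
from parcelfuse.spaces import make_symmetric_grid
from parcelfuse.synthetic import (
    GroundTruth,
    make_true_emission,
    sample_dataset,
    sample_group_arrangement,
)


def toy_model(V_by_session, kappa, n_subjects=2, symmetric=False, space=None, eta=None):
    K = V_by_session[0].shape[0]
    P = space.n_voxels if space is not None else 6
    if eta is None:
        eta = np.zeros((K, P))
    emi = VmfEmission(K, [v.shape[1] for v in V_by_session], V=V_by_session, kappa=kappa)
    return FusedModel(
        Arrangement(eta, symmetric=symmetric, space=space),
        {"ds": emi},
        fit_info={"n_subjects": {"ds": n_subjects}},
    )


class TestParcelSimilarity:
    def test_identical_mean_vectors_give_one(self):
        v = np.tile([1.0, 0.0], (4, 1))
        model = toy_model([v], [5.0])
        sim = parcel_similarity(model, hemisphere_average=True)
        assert np.allclose(sim, 1.0)

    def test_session_weights_scale_linearly(self, rng):
        V = [rng.standard_normal((4, 5)) for _ in range(2)]
        V = [v / np.linalg.norm(v, axis=1, keepdims=True) for v in V]
        m1 = toy_model(V, [3.0, 3.0])
        m2 = toy_model(V, [6.0, 3.0])
        s_equal = parcel_similarity(m1, hemisphere_average=True)
        s_weighted = parcel_similarity(m2, hemisphere_average=True)

        def sess_sim(v):
            u = 0.5 * (v[:2] + v[2:])
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
            return u @ u.T

        s0, s1 = sess_sim(V[0]), sess_sim(V[1])
        assert np.allclose(s_equal, (s0 + s1) / 2, atol=1e-12)
        assert np.allclose(s_weighted, (2 * s0 + s1) / 3, atol=1e-12)

    def test_matches_weighted_sum_oracle(self, fitted):
        _, _, _, model = fitted
        sim = parcel_similarity(model, hemisphere_average=True)
        K = model.K
        num = np.zeros((K // 2, K // 2))
        den = 0.0
        for ds_id, emi in model.emissions.items():
            N = model.fit_info["n_subjects"][ds_id]
            for n, v in enumerate(emi.V):
                u = 0.5 * (v[: K // 2] + v[K // 2 :])
                u = u / np.linalg.norm(u, axis=1, keepdims=True)
                w = emi.kappa[n] * N
                num += w * (u @ u.T)
                den += w
        assert np.allclose(sim, num / den, atol=1e-12)


class TestMerging:
    def test_merged_probability_is_sum_of_children(self, fitted):
        _, _, _, model = fitted
        before = model.group_prob()
        merged = _merge_pair(model, 0, 1, symmetric=True)
        after = merged.group_prob()
        assert np.allclose(after[0], before[0] + before[1], atol=1e-9)
        assert np.allclose(after.sum(axis=0), 1.0, atol=1e-9)

    def test_planted_empty_parcels_are_absorbed(self):
        """A world with 4 real parcel pairs plus 2 planted never-winning pairs:
        merging removes exactly the empty ones and leaves the partition intact."""
        space = make_symmetric_grid(12, 12)
        rng = np.random.default_rng(4)
        K_real, K_tot = 8, 12
        gp_real = sample_group_arrangement(space, K_real, smoothness=6.0, symmetric=True, seed=rng)
        gp = np.full((K_tot, space.n_voxels), 1e-8)
        gp[[0, 1, 2, 3]] = gp_real[[0, 1, 2, 3]]  # left parcels
        gp[[6, 7, 8, 9]] = gp_real[[4, 5, 6, 7]]  # right parcels
        gp /= gp.sum(axis=0, keepdims=True)
        truth = GroundTruth(
            group_prob=gp_real,
            true_V={"ds": make_true_emission(K_real, [8, 8], seed=rng)},
            true_kappa={"ds": [20.0, 20.0]},
        )
        ds = sample_dataset(truth, space, "ds", n_subjects=3, n_runs=2, seed=rng)
        V12 = make_true_emission(K_tot, [8, 8], seed=rng)
        for v12, v8 in zip(V12, truth.true_V["ds"]):
            v12[[0, 1, 2, 3]] = v8[[0, 1, 2, 3]]
            v12[[6, 7, 8, 9]] = v8[[4, 5, 6, 7]]
        model = FusedModel(
            Arrangement(np.log(gp), symmetric=True, space=space),
            {"ds": VmfEmission(K_tot, [8, 8], V=V12, kappa=[20.0, 20.0])},
            fit_info={"n_subjects": {"ds": 3}},
        )
        labels_before = model.hard_labels()
        merged, log = merge_until_winners(model, [ds])
        assert merged.K == K_real
        assert len(log.merge_tree) == 2  # two empty pairs absorbed
        # both merge sources were the planted empty pairs (index 4, then the
        # renumbered remaining empty pair, again 4)
        assert [src for (src, _), _ in log.merge_tree] == [4, 4]
        # partition essentially unchanged (exact-tie voxels on the lattice may
        # legitimately flip when an absorbed parcel's epsilon mass breaks a tie)
        ari = pf.adjusted_rand_index(labels_before, merged.hard_labels())
        assert ari > 0.9

    def test_two_parcel_collapse_stops_at_one_pair(self, fitted):
        space, _, datasets, model = fitted
        # make pair 1 never win by crushing its potentials
        eta = model.arrangement.eta.copy()
        eta[[1, 3]] -= 60.0
        crushed = FusedModel(
            Arrangement(eta, symmetric=True, space=space),
            {k: v.copy() for k, v in model.emissions.items()},
            fit_info=model.fit_info,
        )
        merged, log = merge_until_winners(crushed, datasets)
        assert merged.K == 2
        assert len(log.merge_tree) == 1


class TestDomains:
    def test_block_structure_recovered(self):
        S = np.full((6, 6), 0.1)
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.9
        np.fill_diagonal(S, 1.0)
        hier = build_domains(S, 2)
        d = hier.levels["domain"]
        assert len(set(d[:3])) == 1 and len(set(d[3:])) == 1 and d[0] != d[3]

    def test_each_parcel_its_own_domain(self):
        S = np.eye(4)
        hier = build_domains(S, 4)
        assert len(set(hier.levels["domain"])) == 4

    def test_nesting_exact(self, rng):
        S = rng.random((8, 8))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        hier = build_domains(S, 3)
        dom, med = hier.levels["domain"], hier.levels["medium"]
        for m in np.unique(med):
            assert len(np.unique(dom[med == m])) == 1

    def test_too_many_domains_rejected(self):
        with pytest.raises(ValueError):
            build_domains(np.eye(3), 4)

    def test_names_follow_domain_letter_scheme(self):
        S = np.eye(4) * 0.5 + 0.5
        hier = build_domains(S, 1)
        assert all(n.startswith("A") for n in hier.names)
        assert sorted(hier.names) == ["A1", "A2", "A3", "A4"]


class TestColormap:
    def _block_similarity(self, sizes, hi=0.95, lo=0.05):
        m = sum(sizes)
        S = np.full((m, m), lo)
        start = 0
        for s in sizes:
            S[start : start + s, start : start + s] = hi
            start += s
        np.fill_diagonal(S, 1.0)
        return S

    def test_identical_parcels_share_color(self):
        S = self._block_similarity([2, 2, 2], hi=1.0)
        colors = colormap_from_similarity(S, {0: (0, 1, 0), 2: (1, 0, 0), 4: (1, 1, 0)})
        assert np.allclose(colors[0], colors[1], atol=1e-8)

    def test_anchors_approached_and_output_in_unit_cube(self):
        S = self._block_similarity([3, 3, 3])
        anchors = {0: (0.0, 0.8, 0.0), 3: (0.8, 0.0, 0.0), 6: (0.8, 0.8, 0.0)}
        colors = colormap_from_similarity(S, anchors)
        assert np.all((colors >= 0) & (colors <= 1))
        for k, c in anchors.items():
            assert np.linalg.norm(colors[k] - c) < 0.35

    def test_similarity_ordering_preserved_in_rgb(self):
        # similarity generated from planted 3-D points (exactly embeddable);
        # graded rather than tied, so ordering is well defined
        rng = np.random.default_rng(8)
        pts = rng.random((9, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        S = 1.0 - D / (D.max() * 1.1)
        np.fill_diagonal(S, 1.0)
        colors = colormap_from_similarity(S, {0: tuple(pts[0]), 4: tuple(pts[4]), 8: tuple(pts[8])})
        sims, dists = [], []
        for i in range(9):
            for j in range(i + 1, 9):
                sims.append(S[i, j])
                dists.append(np.linalg.norm(colors[i] - colors[j]))
        rho, _ = spearmanr(sims, -np.array(dists))
        assert rho > 0.8

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            colormap_from_similarity(np.eye(4), {0: (1, 0, 0), 1: (0, 1, 0)})


class TestLateralization:
    def _sym_model(self, space, V, kappa=10.0):
        K = V[0].shape[0]
        gp = sample_group_arrangement(space, K, smoothness=50.0, symmetric=True, seed=1)
        return FusedModel(
            Arrangement(np.log(np.maximum(gp, 1e-12)), symmetric=True, space=space),
            {"ds": VmfEmission(K, [v.shape[1] for v in V], V=V, kappa=[kappa] * len(V))},
            fit_info={"n_subjects": {"ds": 3}},
        )

    def test_mirrored_identical_profiles_give_one(self):
        space = make_symmetric_grid(6, 4)
        v = make_true_emission(2, [5], seed=0)[0]
        v[1] = v[0]  # right parcel mean equals left counterpart
        model = self._sym_model(space, [v])
        li = lateralization_index(model, space)
        assert np.allclose(li[np.isfinite(li)], 1.0, atol=1e-9)

    def test_sign_flipped_profiles_give_minus_one(self):
        space = make_symmetric_grid(6, 4)
        v = make_true_emission(2, [5], seed=0)[0]
        v[1] = -v[0]
        model = self._sym_model(space, [v])
        li = lateralization_index(model, space)
        assert np.allclose(li[np.isfinite(li)], -1.0, atol=1e-9)

    def test_planted_lateralized_parcel_is_the_minimum(self):
        space = make_symmetric_grid(8, 8)
        K = 6
        V = make_true_emission(K, [7], seed=2)
        v = V[0]
        for k in range(K // 2):
            v[k + K // 2] = v[k]
        rng = np.random.default_rng(9)
        odd = rng.standard_normal(7)
        v[0 + K // 2] = odd / np.linalg.norm(odd)  # break symmetry for pair 0 only
        model = self._sym_model(space, [v])
        li = lateralization_index(model, space)
        labels = model.hard_labels()
        region_mean = [
            np.nanmean(li[(labels == k) | (labels == k + K // 2)]) for k in range(K // 2)
        ]
        assert int(np.argmin(region_mean)) == 0


class TestBoundarySymmetry:
    def test_identical_models_give_one(self, fitted):
        _, _, _, model = fitted
        bs = boundary_symmetry(model, model)
        assert np.allclose(bs[np.isfinite(bs)], 1.0, atol=1e-10)

    def test_shifted_boundary_detected_exactly_at_changed_voxels(self):
        space = make_symmetric_grid(4, 4)
        P = space.n_voxels
        eta_sym = np.full((4, P), -30.0)
        left, right = space.left, space.right
        upper = space.coords[:, 1] > 0
        for vox in range(P):
            if vox in left:
                eta_sym[0 if upper[vox] else 1, vox] = 0.0
            else:
                eta_sym[2 if upper[vox] else 3, vox] = 0.0
        eta_asym = eta_sym.copy()
        moved = [v for v in left if abs(space.coords[v, 1] - 0.5) < 0.01][:2]
        for vox in moved:
            eta_asym[0, vox], eta_asym[1, vox] = -30.0, 0.0
        sym = FusedModel(Arrangement(eta_sym, symmetric=True, space=space), {})
        asym = FusedModel(
            Arrangement(eta_asym, hemisphere_locked=True, space=space), {}
        )
        bs = boundary_symmetry(sym, asym)
        assert np.all(bs[moved] < 0.999)
        untouched = [v for v in range(P) if v not in moved]
        assert np.allclose(bs[untouched], 1.0, atol=1e-9)

    def test_individual_level_requires_datasets(self, fitted):
        _, _, _, model = fitted
        with pytest.raises(ValueError):
            boundary_symmetry(model, model, level="individual")


class TestProfileRegression:
    def test_matches_closed_form_oracle(self, rng):
        C, F, R = 20, 4, 3
        X = rng.standard_normal((C, F))
        Y = rng.standard_normal((C, R))
        B = profile_regression(Y, X, l2=2.5)

        def z(M):
            return (M - M.mean(0)) / M.std(0)

        Xz, Yz = z(X), z(Y)
        oracle = np.linalg.solve(Xz.T @ Xz + 2.5 * np.eye(F), Xz.T @ Yz)
        assert np.allclose(B, oracle, atol=1e-10)

    def test_single_column_profile_dominated_by_its_coefficient(self, rng):
        C = 30
        X = rng.standard_normal((C, 3))
        Y = X[:, [1]].copy()
        B = profile_regression(Y, X, l2=0.01)
        assert np.argmax(np.abs(B[:, 0])) == 1

    def test_rank_deficient_without_penalty_rejected(self, rng):
        X = np.ones((10, 2))  # duplicated columns after z-scoring -> singular
        X[:, 1] = X[:, 0]
        X = X * rng.standard_normal((10, 1))
        with pytest.raises(ValueError):
            profile_regression(rng.standard_normal((10, 2)), X, l2=0.0)


class TestRegionSizeAsymmetry:
    def test_symmetric_model_has_equal_counts(self, fitted):
        _, _, _, model = fitted
        table = region_size_asymmetry(model)
        assert np.array_equal(table["left_count"], table["right_count"])
        assert table["left_count"].sum() + table["right_count"].sum() == model.arrangement.P
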