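"""GPA, shape PCA, allometry, thin-plate splines, t-SNE, metric PCA."""

import math

import numpy as np
import pytest

from toothmarks.morphometrics import (
    allometry_test,
    centroid_size,
    gpa,
    metric_pca,
    oa_to_linear,
    pca_shapes,
    procrustes_distance,
    tps_grid,
    tsne_embed,
)
from toothmarks.synthetic_data import GroupSpec, simulate_pits


def _rot2(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _pit_spec(n, slope=0.0, seed=0):
    return GroupSpec(label="pits", n=n, oa_mean_deg=150.0, oa_kappa=20.0,
                     wis_central=2.5, wis_spread=1.0, depth_central=0.35,
                     depth_spread=0.15, allometry_slope=slope, seed=seed)


class TestGpa:
    def test_transformed_copies_align_exactly(self, rng):
        base = rng.normal(size=(7, 2))
        configs = []
        for _ in range(6):
            c = base @ _rot2(rng.uniform(0, 2 * np.pi)).T
            c = c * rng.uniform(0.5, 3.0) + rng.normal(size=2)
            configs.append(c)
        aligned = gpa(np.stack(configs), scale=True)
        dmax = max(procrustes_distance(aligned.coords[i], aligned.coords[j])
                   for i in range(6) for j in range(i))
        assert dmax < 1e-6

    def test_unit_square_centroid_size(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert centroid_size(square) == pytest.approx(math.sqrt(2))

    def test_two_triangle_distance_matches_closed_form_opa(self):
        a = np.array([[0, 0], [1, 0], [0.4, 0.9]])
        b = np.array([[0, 0], [1.2, 0.1], [0.1, 0.7]])
        # oracle: closed-form OPA via the cross-covariance SVD,
        # d^2 = 2 (1 - sum of proper singular values) for unit-size configs
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        ac /= np.sqrt((ac ** 2).sum())
        bc /= np.sqrt((bc ** 2).sum())
        u, sv, vt = np.linalg.svd(ac.T @ bc)
        if np.linalg.det(u @ vt) < 0:
            sv[-1] *= -1
        oracle = math.sqrt(max(2 * (1 - sv.sum()), 0.0))
        assert procrustes_distance(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_input_pose(self, rng):
        base = rng.normal(size=(10, 5, 2))
        al1 = gpa(base, scale=True)
        moved = np.stack([
            (c @ _rot2(rng.uniform(0, 7)).T) * rng.uniform(0.3, 2.0)
            + rng.normal(size=2)
            for c in base
        ])
        al2 = gpa(moved, scale=True)
        d = max(procrustes_distance(al1.coords[i], al2.coords[i])
                for i in range(10))
        assert d < 1e-6

    def test_unit_centroid_sizes_when_scaled(self, rng):
        aligned = gpa(rng.normal(size=(5, 6, 3)), scale=True)
        sizes = [centroid_size(c) for c in aligned.coords]
        np.testing.assert_allclose(sizes, 1.0, atol=1e-8)
        np.testing.assert_allclose(aligned.mean_shape.mean(axis=0), 0.0,
                                   atol=1e-9)

    def test_form_space_keeps_size_ordering(self, rng):
        raw = rng.normal(size=(5, 6, 2)) * \
            np.array([1, 2, 3, 4, 5.0])[:, None, None]
        aligned = gpa(raw, scale=False)
        sizes = [centroid_size(c) for c in aligned.coords]
        assert sizes == sorted(sizes)

    def test_degenerate_configuration_rejected(self):
        bad = np.zeros((3, 4, 2))
        with pytest.raises(ValueError):
            gpa(bad)


class TestShapePca:
    def test_single_coordinate_variation(self, rng):
        base = np.tile(rng.normal(size=(5, 2)), (20, 1, 1))
        base[:, 0, 0] += rng.normal(size=20) * 0.01
        aligned = gpa(base, scale=False)
        res = pca_shapes(aligned)
        assert res.variance_fraction[0] > 0.999

    def test_isotropic_noise_has_no_dominant_component(self, rng):
        base = np.tile(rng.normal(size=(7, 2)), (500, 1, 1))
        base += rng.normal(scale=0.01, size=base.shape)
        res = pca_shapes(gpa(base, scale=True))
        frac = res.variance_fraction
        assert frac.max() < 3 * frac.mean()

    def test_lossless_reconstruction_and_conservation(self, rng):
        base = np.tile(rng.normal(size=(6, 2)), (15, 1, 1))
        base += rng.normal(scale=0.05, size=base.shape)
        aligned = gpa(base, scale=True)
        res = pca_shapes(aligned)
        np.testing.assert_allclose(res.reconstruct(), aligned.tangent,
                                   atol=1e-9)
        total_dev = ((aligned.tangent - aligned.tangent.mean(0)) ** 2).sum()
        assert (res.scores ** 2).sum() == pytest.approx(total_dev)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        # components orthonormal
        np.testing.assert_allclose(res.loadings @ res.loadings.T,
                                   np.eye(res.loadings.shape[0]), atol=1e-9)


class TestAllometry:
    def test_null_covariate_is_calibrated(self, rng):
        ds = simulate_pits(_pit_spec(30, seed=5))
        aligned = gpa(ds, scale=True)
        ps = []
        for i in range(60):
            cov = rng.normal(size=30)  # independent of shape by construction
            ps.append(allometry_test(aligned, covariate=cov, n_perm=199,
                                     seed=i).p)
        ps = np.asarray(ps)
        assert np.mean(ps <= 0.05) <= 0.12
        assert 0.25 < np.median(ps) < 0.75

    def test_built_in_slope_recovered(self):
        ds = simulate_pits(_pit_spec(100, slope=0.4, seed=3))
        aligned = gpa(ds, scale=True)
        res = allometry_test(aligned, n_perm=499, seed=0)
        assert res.p <= 0.01
        from toothmarks.synthetic_data import _allometry_direction
        direction = _allometry_direction()
        cos = abs(res.slope @ direction) / np.linalg.norm(res.slope)
        assert cos > 0.9

    def test_determinism_under_fixed_seed(self, rng):
        ds = simulate_pits(_pit_spec(25, seed=9))
        aligned = gpa(ds, scale=True)
        r1 = allometry_test(aligned, n_perm=199, seed=4)
        r2 = allometry_test(aligned, n_perm=199, seed=4)
        assert (r1.F, r1.p) == (r2.F, r2.p)

    def test_group_interaction_reported(self, rng):
        ds = simulate_pits(_pit_spec(40, seed=2))
        aligned = gpa(ds, scale=True)
        groups = np.repeat(["a", "b"], 20)
        res = allometry_test(aligned, groups=groups, n_perm=199, seed=1)
        assert res.F_interaction is not None and 0 <= res.p_interaction <= 1
        assert set(res.diagnostics) == {"W", "p", "skew", "kurtosis"}

    def test_constant_covariate_rejected(self, rng):
        ds = simulate_pits(_pit_spec(12, seed=1))
        aligned = gpa(ds, scale=True)
        with pytest.raises(ValueError):
            allometry_test(aligned, covariate=np.ones(12), n_perm=99)


class TestTps:
    def test_identity_map(self, rng):
        ref = rng.normal(size=(6, 2))
        warp = tps_grid(ref, ref, grid=8)
        assert warp.bending_energy == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(warp.transform(ref), ref, atol=1e-9)

    def test_affine_target_has_zero_bending(self, rng):
        ref = rng.normal(size=(7, 2))
        A = np.array([[1.3, 0.2], [-0.1, 0.8]])
        tgt = ref @ A.T + np.array([2.0, -1.0])
        warp = tps_grid(ref, tgt, grid=5)
        assert warp.bending_energy == pytest.approx(0.0, abs=1e-8)

    def test_single_displacement_interpolates_and_localises(self):
        ref = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1],
                        [0, 2], [1, 2], [2, 2]], float)
        tgt = ref.copy()
        tgt[4] += [0.0, 0.3]  # displace the centre landmark
        warp = tps_grid(ref, tgt, grid=9, margin=0.0)
        np.testing.assert_allclose(warp.transform(ref), tgt, atol=1e-9)
        assert warp.bending_energy > 0
        near = warp.transform(np.array([[1.0, 1.1]]))[0]
        far = warp.transform(np.array([[0.0, 2.0]]))[0]
        assert abs(near[1] - 1.1) > abs(far[1] - 2.0)

    def test_matches_direct_radial_basis_solve(self, rng):
        ref = rng.normal(size=(8, 2))
        tgt = ref + rng.normal(scale=0.1, size=(8, 2))
        warp = tps_grid(ref, tgt, grid=4)
        # oracle: independent least-squares solve of the augmented system
        k = len(ref)
        d2 = ((ref[:, None] - ref[None]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
        P = np.hstack([np.ones((k, 1)), ref])
        L = np.block([[K, P], [P.T, np.zeros((3, 3))]])
        sol, *_ = np.linalg.lstsq(L, np.vstack([tgt, np.zeros((3, 2))]),
                                  rcond=None)
        pts = rng.normal(size=(5, 2))
        u = ((pts[:, None] - ref[None]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(u > 0, u * np.log(u), 0.0)
        oracle = U @ sol[:k] + \
            np.hstack([np.ones((5, 1)), pts]) @ sol[k:]
        np.testing.assert_allclose(warp.transform(pts), oracle, atol=1e-8)

    def test_collinear_reference_rejected(self):
        ref = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            tps_grid(ref, ref + 1)


class TestTsne:
    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        X = np.vstack([rng.normal(0, 0.3, (100, 5)),
                       rng.normal(6, 0.3, (100, 5))])
        labels = np.repeat([0, 1], 100)
        emb = tsne_embed(X, seed=0)
        assert emb.shape == (200, 3)
        assert silhouette_score(emb, labels) > 0.5

    def test_duplicates_co_cluster_and_determinism(self, rng):
        """Identical rows need not coincide in the embedding (the repulsive
        term keeps any two points apart), but each duplicate must land on the
        same side of a well-separated cluster structure as its twin."""
        m = 30
        X = np.vstack([rng.normal(0, 0.3, (m, 4)),
                       rng.normal(10, 0.3, (m, 4))])
        X2 = np.vstack([X, X])
        labels = np.tile(np.repeat([0, 1], m), 2)
        emb = tsne_embed(X2, seed=1)
        twin = np.linalg.norm(emb[:2 * m] - emb[2 * m:], axis=1)
        within = [np.linalg.norm(emb[i] - emb[j])
                  for i in range(2 * m) for j in range(i)
                  if labels[i] == labels[j] and j != i - 2 * m]
        assert np.median(twin) < 0.5 * np.median(within)
        emb2 = tsne_embed(X2, seed=1)
        np.testing.assert_array_equal(emb, emb2)

    def test_small_sample_guidance(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.normal(size=(11, 3)), seed=0)


class TestMetricPca:
    def test_oa_transform_values(self):
        assert oa_to_linear(90.0) == pytest.approx(1.0, abs=1e-12)
        assert oa_to_linear(45.0) == pytest.approx(math.sqrt(2), abs=1e-9)
        assert oa_to_linear(180.0) == pytest.approx(-1.0, abs=1e-12)
        for bad in (0.0, -5.0, 181.0):
            with pytest.raises(ValueError):
                oa_to_linear(bad)

    def test_two_factor_structure_recovered(self, rng):
        import pandas as pd

        n = 400
        width_factor = rng.normal(0, 0.3, n)
        da_factor = rng.normal(0, 0.08, n)
        df = pd.DataFrame({
            "WIS": 0.5 + width_factor + rng.normal(0, 0.01, n),
            "WIM": 0.33 + 0.66 * width_factor + rng.normal(0, 0.01, n),
            "WIB": 0.17 + 0.33 * width_factor + rng.normal(0, 0.01, n),
            "LDC": 0.27 + 0.5 * width_factor + rng.normal(0, 0.01, n),
            "RDC": 0.27 + 0.5 * width_factor + rng.normal(0, 0.01, n),
            "D": 0.1 + da_factor + rng.normal(0, 0.005, n),
        })
        # OA anticorrelated with the depth factor, on its linearised scale
        oa_lin = -0.3 - 2.0 * da_factor + rng.normal(0, 0.01, n)
        df["OA"] = np.degrees(
            2 * np.arctan2(np.sqrt(2) - oa_lin,
                           np.sqrt(np.clip(2 - oa_lin ** 2, 1e-9, None))))
        df["OA"] = df["OA"].clip(1, 179)
        res = metric_pca(df)
        cols = np.array(res.columns)
        pc1 = np.abs(res.loadings[0])
        pc2 = np.abs(res.loadings[1])
        width_idx = [list(cols).index(c)
                     for c in ("WIS", "WIM", "WIB", "LDC", "RDC")]
        da_idx = [list(cols).index(c) for c in ("D", "OA")]
        assert pc1[width_idx].sum() > pc1[da_idx].sum()
        assert pc2[da_idx].sum() > pc2[width_idx].sum()

    def test_identical_rows_flagged(self):
        import pandas as pd

        df = pd.DataFrame([[0.5, 0.3, 0.2, 0.1, 0.3, 0.3, 120.0]] * 5,
                          columns=["WIS", "WIM", "WIB", "D", "LDC", "RDC",
                                   "OA"])
        with pytest.raises(ValueError):
            metric_pca(df)

    def test_standardisation_toggle_keeps_rank_one_recovery(self, rng):
        import pandas as pd

        f = rng.normal(size=300)
        df = pd.DataFrame({
            "WIS": 1 + 0.5 * f, "WIM": 2 + 0.2 * f, "WIB": 0.5 + 0.1 * f,
            "D": 0.1 + 0.02 * f, "LDC": 1 + 0.3 * f, "RDC": 2 + 0.4 * f,
        })
        for standardize in (False, True):
            res = metric_pca(df, standardize=standardize)
            assert res.variance_fraction[0] > 0.999
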