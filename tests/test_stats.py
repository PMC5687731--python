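"""Vertex-wise GLM, cluster permutation correction, effect sizes, reliability."""

import numpy as np
import pandas as pd
import pytest

from surfconn import (
    DesignMatrix,
    VertexMap,
    cluster_effect_size,
    clusters_to_table,
    find_clusters,
    fit_glm,
    forming_threshold_from_p,
    make_icosphere,
    make_replicate_stacks,
    permutation_cluster_correction,
    reliability,
)
from surfconn.stats import stack_maps


def _maps_from_array(Y):
    return [VertexMap(row, np.ones(Y.shape[1], bool)) for row in Y]


def _design(n_per_group, rng=None, covariates=True):
    n = 2 * n_per_group
    rng = rng or np.random.default_rng(0)
    cov = pd.DataFrame({
        "age": rng.uniform(6, 28, n),
        "sex": rng.integers(0, 2, n).astype(float),
    }) if covariates else pd.DataFrame()
    return DesignMatrix(
        subjects=[f"s{i}" for i in range(n)],
        group=np.repeat([0, 1], n_per_group),
        covariates=cov,
    )


class TestFitGlm:
    def test_identical_groups_give_zero_t(self):
        Y = np.ones((8, 5))
        res = fit_glm(_maps_from_array(Y), _design(4, covariates=False))
        assert np.allclose(res.t.values, 0.0)

    def test_separated_groups_t_diverges_with_sign(self):
        rng = np.random.default_rng(1)
        design = _design(3, covariates=False)
        t_prev = None
        for eps in (1e-1, 1e-3):
            Y = np.repeat([[0.0], [1.0]], 3, axis=0) + rng.normal(0, eps, (6, 1))
            t = fit_glm(_maps_from_array(Y), design).t.values[0]
            assert t > 0  # group coded 1 has the higher values
            if t_prev is not None:
                assert t > t_prev
            t_prev = t

    def test_matches_closed_form_ols(self):
        """Independent oracle: explicit normal-equations solve per vertex."""
        rng = np.random.default_rng(2)
        design = _design(10, rng=rng)
        X = design.matrix()
        Y = rng.normal(50, 5, size=(20, 7))
        res = fit_glm(_maps_from_array(Y), design)
        for v in range(7):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
            resid = Y[:, v] - X @ beta
            df = 20 - 4
            sigma2 = resid @ resid / df
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res.beta.values[v] == pytest.approx(beta[1], rel=1e-9)
            assert res.t.values[v] == pytest.approx(beta[1] / se, rel=1e-9)
        assert res.df == 16

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        design = _design(8, rng=rng)
        X = design.matrix()
        Y = rng.normal(size=(16, 1))
        fit = sm.OLS(Y[:, 0], X).fit()
        res = fit_glm(_maps_from_array(Y), design)
        assert res.t.values[0] == pytest.approx(fit.tvalues[1], rel=1e-9)
        assert res.p.values[0] == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_t_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(4)
        design = _design(10, rng=rng)
        Y = rng.normal(size=(20, 6))
        t0 = fit_glm(_maps_from_array(Y), design).t.values
        design2 = DesignMatrix(design.subjects, design.group,
                               design.covariates * [365.25, 2.0] + [100.0, 1.0])
        t1 = fit_glm(_maps_from_array(Y), design2).t.values
        assert np.allclose(t0, t1, atol=1e-9)

    def test_orthogonal_covariate_changes_t_only_via_df(self):
        rng = np.random.default_rng(5)
        base = _design(10, covariates=False)
        X = base.matrix()
        Y = rng.normal(size=(20, 3))
        res0 = fit_glm(_maps_from_array(Y), base)
        # column orthogonal to the design AND to each map
        M = np.hstack([X, Y])
        q, _ = np.linalg.qr(np.hstack([M, rng.normal(size=(20, 1))]))
        z = q[:, -1]
        assert np.allclose(M.T @ z, 0, atol=1e-10)
        plus = DesignMatrix(base.subjects, base.group,
                            pd.DataFrame({"z": z}))
        res1 = fit_glm(_maps_from_array(Y), plus)
        assert np.allclose(res1.beta.values, res0.beta.values, atol=1e-9)
        # residuals unchanged, so t scales exactly with sqrt(df ratio)
        assert np.allclose(res1.t.values,
                           res0.t.values * np.sqrt(res1.df / res0.df), atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        design = _design(5, covariates=False)
        design.covariates = pd.DataFrame({"dup": design.group})
        with pytest.raises(ValueError, match="collinear.*group|group.*collinear"):
            fit_glm(_maps_from_array(np.random.default_rng(0).normal(size=(10, 2))),
                    design)

    def test_vertex_invalid_in_one_subject_excluded(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(8, 4))
        maps = _maps_from_array(Y)
        maps[3].valid[2] = False
        maps[3].values[2] = np.nan
        res = fit_glm(maps, _design(4, covariates=False))
        assert not res.t.valid[2]
        assert res.t.valid[[0, 1, 3]].all()

    def test_too_few_subjects_per_group_rejected(self):
        Y = np.random.default_rng(0).normal(size=(3, 2))
        design = DesignMatrix(["a", "b", "c"], np.array([0, 1, 1]))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_glm(_maps_from_array(Y), design)


class TestFindClusters:
    def test_no_suprathreshold_vertices(self, icosphere_small):
        t = VertexMap.full(icosphere_small.n_vertices, 0.5)
        assert find_clusters(t, icosphere_small, 2.0) == []

    def test_single_vertex_cluster_area(self, icosphere_small):
        vals = np.zeros(icosphere_small.n_vertices)
        vals[17] = 5.0
        t = VertexMap(vals, np.ones_like(vals, bool))
        clusters = find_clusters(t, icosphere_small, 2.0)
        assert len(clusters) == 1
        assert clusters[0].vertex_set.tolist() == [17]
        assert clusters[0].area == pytest.approx(icosphere_small.vertex_areas[17])
        assert clusters[0].peak_vertex == 17

    def test_two_planted_patches_recovered(self, icosphere_medium):
        """Flood-fill over the planted labels is the oracle."""
        from surfconn import geodesic_patch

        mesh = icosphere_medium
        p1 = set(geodesic_patch(mesh, 0, 12.0))
        p2 = set(geodesic_patch(mesh, 400, 12.0))
        assert not (p1 & p2)
        vals = np.zeros(mesh.n_vertices)
        vals[list(p1)] = 4.0
        vals[list(p2)] = -4.0
        t = VertexMap(vals, np.ones_like(vals, bool))
        clusters = find_clusters(t, mesh, 2.0)
        assert len(clusters) == 2
        found = {frozenset(c.vertex_set.tolist()) for c in clusters}
        assert found == {frozenset(p1), frozenset(p2)}
        signs = {c.sign for c in clusters}
        assert signs == {1, -1}

    def test_opposite_sign_patches_never_merge(self, icosphere_small):
        vals = np.zeros(icosphere_small.n_vertices)
        v = 30
        vals[v] = 5.0
        vals[icosphere_small.neighbors(v)] = -5.0
        t = VertexMap(vals, np.ones_like(vals, bool))
        clusters = find_clusters(t, icosphere_small, 2.0)
        assert {c.sign for c in clusters} == {1, -1}
        pos = [c for c in clusters if c.sign == 1]
        assert len(pos) == 1 and pos[0].vertex_set.tolist() == [v]


class TestPermutationCorrection:
    def test_same_seed_reproduces_p_values(self, icosphere_small):
        rng = np.random.default_rng(7)
        Y = rng.normal(50, 5, size=(16, icosphere_small.n_vertices))
        Y[8:, :20] += 8.0
        maps = _maps_from_array(Y)
        design = _design(8, covariates=False)
        out = []
        for _ in range(2):
            clusters, _, _ = permutation_cluster_correction(
                maps, design, icosphere_small, n_permutations=120, seed=42)
            out.append([c.corrected_p for c in clusters])
        assert out[0] == out[1]

    def test_dominant_cluster_reaches_minimum_p(self, icosphere_small):
        from surfconn import geodesic_patch

        rng = np.random.default_rng(8)
        mesh = icosphere_small
        patch = geodesic_patch(mesh, 50, 20.0)
        Y = rng.normal(50, 3, size=(24, mesh.n_vertices))
        Y[12:, :][:, patch] -= 30.0
        clusters, _, _ = permutation_cluster_correction(
            _maps_from_array(Y), _design(12, covariates=False), mesh,
            n_permutations=200, seed=0)
        assert clusters[0].corrected_p == pytest.approx(1.0 / 201.0)

    def test_corrected_p_nonincreasing_in_area(self, icosphere_medium):
        rng = np.random.default_rng(9)
        mesh = icosphere_medium
        Y = rng.normal(0, 1, size=(20, mesh.n_vertices))
        from surfconn import geodesic_patch

        big = geodesic_patch(mesh, 0, 14.0)
        small = geodesic_patch(mesh, 500, 6.0)
        Y[10:, big] += 2.5
        Y[10:, small] += 2.5
        clusters, _, _ = permutation_cluster_correction(
            _maps_from_array(Y), _design(10, covariates=False), mesh,
            n_permutations=150, seed=3)
        areas = [c.area for c in clusters]
        ps = [c.corrected_p for c in clusters]
        assert areas == sorted(areas, reverse=True)
        assert ps == sorted(ps)

    def test_too_few_permutations_rejected(self, icosphere_small):
        with pytest.raises(ValueError, match="100"):
            permutation_cluster_correction(
                _maps_from_array(np.zeros((8, icosphere_small.n_vertices))),
                _design(4, covariates=False), icosphere_small, n_permutations=50)


class TestEffectSize:
    def test_identical_group_means_give_zero(self, icosphere_small):
        rng = np.random.default_rng(10)
        base = rng.normal(size=icosphere_small.n_vertices)
        Y = np.tile(base, (8, 1)) + rng.normal(0, 1, size=(8, 1))
        Y[:4] = Y[4:]  # mirror the groups
        from surfconn.stats import ClusterResult

        cluster = ClusterResult(vertex_set=np.arange(10), area=1.0,
                                peak_vertex=0, peak_stat=0.0, sign=1)
        d = cluster_effect_size(_maps_from_array(Y), _design(4, covariates=False),
                                cluster)
        assert d == pytest.approx(0.0)

    def test_sign_positive_when_controls_exceed_patients(self):
        Y = np.repeat([[10.0], [4.0]], 4, axis=0)
        Y += np.random.default_rng(11).normal(0, 0.5, Y.shape)
        from surfconn.stats import ClusterResult

        cluster = ClusterResult(vertex_set=np.array([0]), area=1.0,
                                peak_vertex=0, peak_stat=0.0, sign=1)
        d = cluster_effect_size(_maps_from_array(Y), _design(4, covariates=False),
                                cluster)
        assert d > 5  # controls (first group) higher -> positive d

    def test_recovers_one_pooled_sd_shift(self):
        """Parameter recovery: a planted 1.0-SD cluster-mean shift at
        n=50/group must give d near 1."""
        rng = np.random.default_rng(12)
        n = 50
        V = 30
        shift = 1.0
        Y = rng.normal(0, 1, size=(2 * n, 1)) + np.zeros((2 * n, V))
        Y[n:] -= shift
        Y += rng.normal(0, 0.05, size=Y.shape)  # vertex noise, tiny
        from surfconn.stats import ClusterResult

        cluster = ClusterResult(vertex_set=np.arange(V), area=1.0,
                                peak_vertex=0, peak_stat=0.0, sign=1)
        d = cluster_effect_size(_maps_from_array(Y), _design(n, covariates=False),
                                cluster)
        assert 0.8 <= d <= 1.2

    def test_cluster_table_columns(self, icosphere_small):
        vals = np.zeros(icosphere_small.n_vertices)
        vals[3] = 5.0
        t = VertexMap(vals, np.ones_like(vals, bool))
        clusters = find_clusters(t, icosphere_small, 2.0)
        table = clusters_to_table(clusters, icosphere_small)
        assert {"area_mm2", "peak_t", "corrected_p", "cohens_d"} <= set(table.columns)


class TestReliability:
    def test_identical_replicates_icc_one_cv_zero(self):
        rng = np.random.default_rng(13)
        base = rng.normal(50, 10, size=(20, 15))
        stacks = [[VertexMap(base[i], np.ones(15, bool)) for i in range(20)]
                  for _ in range(2)]
        rel = reliability(stacks)
        assert np.allclose(rel.icc.values, 1.0)
        assert np.allclose(rel.cv.values, 0.0)

    def test_pure_noise_icc_near_zero(self):
        stacks = make_replicate_stacks(60, 40, 2, sigma_between=0.0,
                                       sigma_within=1.0, seed=14)
        rel = reliability(stacks)
        assert abs(np.nanmean(rel.icc.values)) < 0.1

    @pytest.mark.parametrize("sb,sw", [(1.0, 1.0), (2.0, 1.0)])
    def test_variance_component_recovery(self, sb, sw):
        expected = sb**2 / (sb**2 + sw**2)
        stacks = make_replicate_stacks(50, 80, 2, sigma_between=sb,
                                       sigma_within=sw, seed=15)
        rel = reliability(stacks)
        assert np.nanmean(rel.icc.values) == pytest.approx(expected, abs=0.05)

    def test_matches_pingouin_icc2_single_vertex(self):
        pg = pytest.importorskip("pingouin")
        stacks = make_replicate_stacks(12, 1, 3, sigma_between=1.0,
                                       sigma_within=0.7, seed=16)
        rel = reliability(stacks)
        data = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": np.concatenate([
                [stacks[r][i].values[0] for r in range(3)] for i in range(12)
            ]),
        })
        icc = pg.intraclass_corr(data, targets="subject", raters="rater",
                                 ratings="score")
        # absolute-agreement single-measure ICC, labelled ICC2 or ICC(A,1)
        # depending on the pingouin version
        ref = icc.loc[icc["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].item()
        assert rel.icc.values[0] == pytest.approx(ref, abs=1e-6)

    def test_single_replicate_rejected(self):
        stacks = make_replicate_stacks(5, 3, 2, 1.0, 1.0, seed=17)
        with pytest.raises(ValueError, match="2 replicates"):
            reliability(stacks[:1])

    def test_cv_matches_direct_formula(self):
        stacks = make_replicate_stacks(10, 4, 3, 1.0, 0.5, mean=20.0, seed=18)
        rel = reliability(stacks)
        Y = np.stack([stack_maps(s)[0] for s in stacks], axis=-1)
        v = 2
        cv_direct = np.mean([
            100 * Y[i, v].std(ddof=1) / abs(Y[i, v].mean()) for i in range(10)
        ])
        assert rel.cv.values[v] == pytest.approx(cv_direct)
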