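import math

import numpy as np
import pandas as pd
import pytest

from germdiv import (
    bartlett_sphericity,
    cluster_accessions,
    component_scores,
    composite_score,
    correlation_matrix,
    kmo_statistic,
    pca_correlation,
    profile_groups,
    range_standardize,
    rank_accessions,
    select_components,
    zscore_standardize,
)
from germdiv.multivariate import PCAResult
from germdiv import datasets


def kmo_regression_oracle(r: np.ndarray) -> float:
    """KMO via explicit Schur-complement regression partial correlations."""
    p = len(r)
    q = np.zeros_like(r)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                roo = r[np.ix_(others, others)]
                ri = r[i, others]
                rj = r[j, others]
                si = np.linalg.solve(roo, ri)
                sj = np.linalg.solve(roo, rj)
                q[i, j] = (r[i, j] - ri @ sj) / math.sqrt(
                    (1 - ri @ si) * (1 - rj @ sj))
            else:
                q[i, j] = r[i, j]
    off = ~np.eye(p, dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return r2 / (r2 + q2)


def random_spd_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((p + 3, p))
    s = a.T @ a
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


class TestCorrelation:
    def test_fixed_multiple_is_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        yield_pp = rng.uniform(0.3, 1.4, 33)
        df = pd.DataFrame({"yield per plant": yield_pp,
                           "yield": 4.878 * yield_pp})
        res = correlation_matrix(df)
        assert res.r.loc["yield per plant", "yield"] == pytest.approx(1.0)
        assert res.r2.loc["yield per plant", "yield"] == pytest.approx(1.0)
        assert res.p.loc["yield per plant", "yield"] == 0.0

    def test_negated_column_gives_minus_one(self):
        x = np.arange(10.0)
        res = correlation_matrix(pd.DataFrame({"x": x, "neg": -x}))
        assert res.r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_independent_normals_are_uncorrelated(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((10000, 2)), columns=["a", "b"])
        res = correlation_matrix(df)
        assert abs(res.r.loc["a", "b"]) < 0.05

    def test_pvalues_match_scipy_on_complete_data(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        y = 0.4 * x + rng.standard_normal(30)
        res = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        r_ref, p_ref = pearsonr(x, y)
        assert res.r.loc["x", "y"] == pytest.approx(r_ref)
        assert res.p.loc["x", "y"] == pytest.approx(p_ref, rel=1e-9)

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0, 5.0],
                           "b": [2.0, 1.0, 3.0, np.nan, 6.0]})
        res = correlation_matrix(df)
        assert res.n_pairs.loc["a", "b"] == 3

    def test_constant_trait_flagged_not_raised(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        res = correlation_matrix(df)
        assert res.constant_traits == ["c"]
        assert np.isnan(res.r.loc["a", "c"])


class TestStandardization:
    def test_range_maps_extremes_to_unit_interval(self, small_matrix):
        std = range_standardize(small_matrix, ["plant height"])
        col = std["plant height"]
        assert col.min() == 0.0 and col.max() == 1.0
        assert ((0 <= col) & (col <= 1)).all()

    def test_range_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 50, 20)
        a = range_standardize(pd.DataFrame({"t": x}))
        b = range_standardize(pd.DataFrame({"t": 3.5 * x + 7}))
        assert np.allclose(a["t"], b["t"])

    def test_range_constant_trait_named(self):
        with pytest.raises(ValueError, match="flat"):
            range_standardize(pd.DataFrame({"flat": [1.0, 1.0]}))

    def test_zscore_moments_and_idempotence(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"t": rng.normal(20, 5, 40)})
        z = zscore_standardize(df)
        assert abs(z["t"].mean()) < 1e-12
        assert z["t"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(zscore_standardize(z)["t"], z["t"], atol=1e-12)


class TestKMO:
    def test_equicorrelated_matches_regression_oracle(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        assert kmo_statistic(r) == pytest.approx(kmo_regression_oracle(r),
                                                 abs=1e-10)

    def test_near_identity_is_half(self):
        r = np.eye(4) + 1e-6 * (np.ones((4, 4)) - np.eye(4))
        assert kmo_statistic(r) == pytest.approx(0.5, abs=1e-3)

    def test_random_spd_matrices_match_oracle(self):
        rng = np.random.default_rng(17)
        for p in (3, 4, 5, 6):
            r = random_spd_correlation(p, rng)
            assert kmo_statistic(r) == pytest.approx(
                kmo_regression_oracle(r), abs=1e-10)

    def test_rank_deficient_rejected(self):
        r = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            kmo_statistic(r)


class TestBartlett:
    def test_identity_matrix(self):
        res = bartlett_sphericity(np.eye(5), n=30)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_two_variables(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = bartlett_sphericity(r, n=30)
        assert res.chi2 == pytest.approx(-27.5 * math.log(0.75), rel=1e-12)
        assert res.df == 1

    def test_monotone_in_correlation_strength(self):
        def chi2(rho):
            r = np.array([[1.0, rho], [rho, 1.0]])
            return bartlett_sphericity(r, n=30).chi2
        values = [chi2(rho) for rho in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_needs_more_observations_than_variables(self):
        with pytest.raises(ValueError):
            bartlett_sphericity(np.eye(5), n=5)


class TestPCA:
    def test_eigenvalue_sum_equals_trait_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((50, 6)))
        pca = pca_correlation(df)
        assert pca.eigenvalues.sum() == pytest.approx(6.0)
        assert pca.contribution.sum() == pytest.approx(100.0)

    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.standard_normal(4000)
        pca = pca_correlation(pd.DataFrame({"x": x, "y": y}))
        r = np.corrcoef(x, y)[0, 1]
        assert pca.eigenvalues == pytest.approx([1 + r, 1 - r], abs=1e-9)

    def test_eigenvectors_unit_norm_and_sign_fixed(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((40, 5)))
        pca = pca_correlation(df)
        norms = np.linalg.norm(pca.eigenvectors.values, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-8)
        for k in range(5):
            col = pca.eigenvectors.values[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_matches_sklearn_on_zscored_data(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(7)
        base = rng.standard_normal((60, 2))
        df = pd.DataFrame(base @ rng.standard_normal((2, 5))
                          + 0.5 * rng.standard_normal((60, 5)))
        z = zscore_standardize(df)
        ours = pca_correlation(z)
        ref = SkPCA().fit(z.values)
        assert ours.eigenvalues == pytest.approx(ref.explained_variance_,
                                                 rel=1e-8)

    def test_component_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((5000, 3))
        df = pd.DataFrame(base @ rng.standard_normal((3, 6))
                          + 0.3 * rng.standard_normal((5000, 6)))
        z = zscore_standardize(df)
        pca = pca_correlation(z)
        y = component_scores(z, pca, components=list(range(6)))
        assert np.allclose(y.var(ddof=1), pca.eigenvalues, rtol=1e-6)

    def test_reported_loading_columns_are_unit_norm(self):
        norms = np.linalg.norm(datasets.PCA_LOADINGS.values, axis=0)
        assert np.allclose(norms, 1.0, atol=0.01)

    def test_reported_contributions_sum_to_reported_cumulative(self):
        assert sum(datasets.PCA_CONTRIBUTIONS) == pytest.approx(
            datasets.PCA_CUMULATIVE[-1], abs=0.01)


class TestComponentSelection:
    def _pca(self, eigenvalues):
        p = len(eigenvalues)
        vecs = pd.DataFrame(np.eye(p), columns=[f"PC{k+1}" for k in range(p)])
        lam = np.asarray(eigenvalues, dtype=float)
        contribution = 100 * lam / p
        return PCAResult([f"t{i}" for i in range(p)], lam, vecs,
                         contribution, np.cumsum(contribution), [])

    def test_reported_eigenvalue_row_retains_six(self):
        pca = self._pca(datasets.PCA_EIGENVALUES + [0.6, 0.4])
        assert select_components(pca) == [0, 1, 2, 3, 4, 5]

    def test_exact_threshold_retained(self):
        assert select_components(self._pca([2.0, 1.0, 0.5])) == [0, 1]

    def test_fallback_retains_first_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_components(self._pca([0.9, 0.6])) == [0]
        assert "retaining" in caplog.text


class TestScoring:
    def test_zero_vector_scores_zero(self):
        pca = pca_correlation(pd.DataFrame(
            np.random.default_rng(0).standard_normal((30, 4))))
        z = pd.DataFrame(np.zeros((1, 4)), columns=pca.traits)
        y = component_scores(z, pca)
        assert np.allclose(y.values, 0.0)

    def test_unit_vector_projects_to_reported_loading(self):
        loadings = datasets.PCA_LOADINGS
        traits = list(loadings.index)
        pca = PCAResult(traits, np.array(datasets.PCA_EIGENVALUES),
                        loadings, np.array(datasets.PCA_CONTRIBUTIONS),
                        np.array(datasets.PCA_CUMULATIVE), list(range(6)))
        unit = pd.DataFrame(np.zeros((1, 15)), columns=traits)
        unit.loc[0, "plant height (cm)"] = 1.0
        y = component_scores(unit, pca)
        assert y.loc[0, "Y1"] == pytest.approx(0.3041)

    def test_dimension_mismatch_rejected(self):
        pca = pca_correlation(pd.DataFrame(
            np.random.default_rng(1).standard_normal((20, 3))))
        bad = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            component_scores(bad, pca)

    def test_reported_component_rows_reproduce_reported_scores(self):
        y = datasets.COMPONENT_SCORES[[f"Y{k}" for k in range(1, 7)]]
        scores = composite_score(y, datasets.PCA_CONTRIBUTIONS)
        for acc, expected in [("76", 2.582355156), ("137", 2.065784387)]:
            assert scores.loc[acc, "z"] == pytest.approx(expected, abs=1e-4)

    def test_zero_components_score_zero(self):
        y = pd.DataFrame(np.zeros((3, 2)), columns=["Y1", "Y2"])
        assert np.allclose(composite_score(y, [60, 40])["z"], 0.0)

    def test_invariant_to_contribution_rescaling(self):
        y = datasets.COMPONENT_SCORES[[f"Y{k}" for k in range(1, 7)]]
        a = composite_score(y, datasets.PCA_CONTRIBUTIONS)
        b = composite_score(y, [c / 100 for c in datasets.PCA_CONTRIBUTIONS])
        assert np.allclose(a["z"], b["z"])

    def test_contribution_length_mismatch(self):
        y = pd.DataFrame(np.zeros((2, 3)), columns=["Y1", "Y2", "Y3"])
        with pytest.raises(ValueError):
            composite_score(y, [50, 50])


class TestRanking:
    def test_full_reported_ranking_reproduced(self):
        y = datasets.COMPONENT_SCORES[[f"Y{k}" for k in range(1, 7)]]
        scores = composite_score(y, datasets.PCA_CONTRIBUTIONS)
        assert (scores["rank"] == datasets.COMPONENT_SCORES["rank"]).all()
        ranked = rank_accessions(scores)
        assert list(ranked.index[:3]) == ["76", "137", "97"]

    def test_single_accession_rank_one(self):
        y = pd.DataFrame([[1.0]], columns=["Y1"], index=["only"])
        assert composite_score(y, [100])["rank"].tolist() == [1]

    def test_ties_broken_by_accession_id(self):
        y = pd.DataFrame([[1.0], [1.0]], columns=["Y1"], index=["b", "a"])
        scores = composite_score(y, [100])
        assert scores.loc["a", "rank"] == 1 and scores.loc["b", "rank"] == 2


class TestClustering:
    def test_k_one_collapses_everything(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.standard_normal((12, 4)))
        assignment = cluster_accessions(df, 1)
        assert set(assignment.groups) == {1}

    def test_two_well_separated_clusters_recovered(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (15, 3))
        b = rng.normal(20, 1, (10, 3))   # 10 within-cluster sds apart
        df = pd.DataFrame(np.vstack([a, b]))
        groups = cluster_accessions(df, 2).groups
        assert groups.iloc[:15].nunique() == 1
        assert groups.iloc[15:].nunique() == 1
        assert groups.iloc[0] != groups.iloc[20]

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((6, 3)))
        df.loc[6] = df.loc[0]
        groups = cluster_accessions(df, 3).groups
        assert groups.loc[0] == groups.loc[6]

    def test_k_larger_than_n_rejected(self):
        df = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            cluster_accessions(df, 4)


class TestGroupProfiles:
    def test_whole_population_group_is_neutral(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.standard_normal((8, 2)), columns=["a", "b"])
        assignment = cluster_accessions(df, 1)
        prof = profile_groups(df, assignment)
        assert (prof["direction"] == "neutral").all()

    def test_high_yield_group_flagged_higher(self):
        rng = np.random.default_rng(14)
        low = rng.normal(1.0, 0.05, (10, 1))
        high = rng.normal(5.0, 0.05, (5, 1))
        df = pd.DataFrame(np.vstack([low, high]), columns=["yield"])
        assignment = cluster_accessions(df, 2)
        prof = profile_groups(df, assignment)
        high_group = assignment.groups.iloc[-1]
        row = prof[(prof["group"] == high_group) & (prof["trait"] == "yield")]
        assert row["direction"].item() == "higher"

    def test_flags_invariant_to_trait_scaling(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        assignment = cluster_accessions(df, 2)
        p1 = profile_groups(df, assignment)
        p2 = profile_groups(df * 100 + 7, assignment)
        assert (p1["direction"] == p2["direction"]).all()


class TestFactorRecovery:
    def test_planted_two_factor_structure_recovered(self):
        from scipy.linalg import subspace_angles
        rng = np.random.default_rng(16)
        p, n = 10, 1000
        loadings = np.zeros((p, 2))
        loadings[:5, 0] = 0.85
        loadings[5:, 1] = 0.85
        factors = rng.standard_normal((n, 2))
        x = factors @ loadings.T + 0.5 * rng.standard_normal((n, p))
        pca = pca_correlation(pd.DataFrame(x))
        assert len(pca.retained) == 2
        top = pca.eigenvectors.values[:, :2]
        angle = np.degrees(subspace_angles(top, loadings).max())
        assert angle < 10.0
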