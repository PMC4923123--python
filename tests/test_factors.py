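"""Correlation-matrix PCA, scree selection and Varimax rotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from agefit.factors import (
    FactorSolution, _varimax_criterion, fit_pca, loading_report,
    score_regression, select_components, varimax, varimax_rotate,
)
from agefit.simulate import SyntheticSpec, generate_cohort, generate_volumes
from agefit.volumes import adjust_volume, analysis_volumes, combine_hemispheres


class TestPCA:
    def test_two_perfectly_correlated_regions(self, rng):
        x = rng.normal(size=200)
        vols = pd.DataFrame({"a": x, "b": 2 * x + 5})
        sol = fit_pca(vols)
        np.testing.assert_allclose(sol.eigenvalues, [2.0, 0.0], atol=1e-10)

    def test_independent_regions_eigenvalues_near_one(self, rng):
        vols = pd.DataFrame(rng.normal(size=(20000, 4)), columns=list("abcd"))
        sol = fit_pca(vols)
        np.testing.assert_allclose(sol.eigenvalues, np.ones(4), atol=0.05)

    def test_trace_conservation(self, analysis54):
        sol = fit_pca(analysis54)
        assert sol.eigenvalues.sum() == pytest.approx(len(analysis54.columns), abs=1e-8)

    def test_scores_are_standardized_and_uncorrelated(self, analysis54):
        sol = fit_pca(analysis54, k=5)
        cov = np.cov(sol.scores.to_numpy(), rowvar=False)
        np.testing.assert_allclose(cov, np.eye(5), atol=1e-8)

    def test_reconstruction_error_bounded_by_discarded_mass(self, analysis54):
        k = 5
        sol = fit_pca(analysis54, k=k)
        z = (analysis54 - analysis54.mean()) / analysis54.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        recon = sol.loadings.to_numpy() @ sol.loadings.to_numpy().T
        discarded = sol.eigenvalues[k:].sum()
        assert np.linalg.norm(corr - recon, "fro") <= discarded + 1e-8

    def test_non_finite_volumes_rejected(self):
        vols = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="finite"):
            fit_pca(vols)


class TestSelectComponents:
    def test_override_wins(self):
        assert select_components(np.array([5.0, 3, 1, 0.5]), k_override=5 - 3) == 2
        assert select_components(np.array([5.0, 3, 1, 0.5, 0.2]), k_override=5) == 5

    def test_elbow_after_two_large_eigenvalues(self):
        assert select_components(np.array([3.0, 2.9, 0.1, 0.05, 0.01])) == 2

    def test_single_dominant_eigenvalue(self):
        assert select_components(np.array([5.0, 0.5, 0.45, 0.4])) == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            select_components(np.array([1.0, 2.0]))


class TestVarimax:
    def test_block_diagonal_unchanged_up_to_sign_permutation(self):
        L = np.array(
            [[0.9, 0.0], [0.85, 0.0], [0.8, 0.0], [0.0, 0.9], [0.0, 0.85], [0.0, 0.8]]
        )
        Lr, R = varimax(L, kaiser_normalize=False)
        # columns may swap or flip; compare as sets of absolute columns
        got = sorted(np.abs(Lr).sum(axis=0))
        want = sorted(np.abs(L).sum(axis=0))
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_rotation_matrix_orthogonal(self, analysis54):
        sol = varimax_rotate(fit_pca(analysis54, k=5))
        np.testing.assert_allclose(
            sol.rotation.T @ sol.rotation, np.eye(5), atol=1e-10
        )

    def test_communalities_preserved(self, analysis54):
        pca = fit_pca(analysis54, k=5)
        rot = varimax_rotate(pca)
        np.testing.assert_allclose(
            pca.communalities(), rot.communalities(), atol=1e-8
        )

    def test_criterion_not_decreased(self, rng):
        L = rng.normal(size=(10, 3))
        Lr, _ = varimax(L, kaiser_normalize=False)
        assert _varimax_criterion(Lr) >= _varimax_criterion(L) - 1e-10

    def test_k2_matches_grid_search_oracle(self, rng):
        L = rng.normal(size=(6, 2))
        Lr, _ = varimax(L, kaiser_normalize=False)
        # exhaustive rotation-angle search in 0.1-degree steps
        best = -np.inf
        for deg in np.arange(0.0, 90.0, 0.1):
            t = np.deg2rad(deg)
            R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            best = max(best, _varimax_criterion(L @ R))
        assert _varimax_criterion(Lr) == pytest.approx(best, abs=1e-4)

    def test_k1_returns_input(self, analysis54):
        pca = fit_pca(analysis54, k=1)
        rot = varimax_rotate(pca)
        np.testing.assert_allclose(
            np.abs(rot.loadings.to_numpy()), np.abs(pca.loadings.to_numpy())
        )


class TestLoadingReport:
    def _solution(self, loadings):
        lo = pd.DataFrame(loadings)
        return FactorSolution(
            loadings=lo,
            eigenvalues=np.ones(lo.shape[1]),
            scores=pd.DataFrame(np.zeros((2, lo.shape[1])), columns=lo.columns),
            k=lo.shape[1],
        )

    def test_threshold_boundary(self):
        sol = self._solution({"F1": pd.Series({"a": 0.29, "b": 0.31})})
        report = loading_report(sol)
        assert list(report["region"]) == ["b"]

    def test_negative_loading_kept_and_marked_high(self):
        sol = self._solution({"F1": pd.Series({"LatV": -0.73, "x": 0.4})})
        report = loading_report(sol).set_index("region")
        assert report.loc["LatV", "loading"] == -0.73
        assert bool(report.loc["LatV", "high"])
        assert not bool(report.loc["x", "high"])

    def test_empty_factor_gets_notice(self):
        sol = self._solution({"F1": pd.Series({"a": 0.1, "b": 0.05})})
        report = loading_report(sol)
        assert "(none over threshold)" in report["region"].tolist()


class TestScoreRegression:
    def test_planted_factor_drivers_recovered(self, cohort54, design54, rng):
        x = design54.set_index("id")
        scores = pd.DataFrame(
            {
                "F1": x["age_score"] / x["age_score"].std()
                + 0.3 * rng.normal(size=len(x)),
                "F2": x["fitness_score"] + 0.3 * rng.normal(size=len(x)),
                "F3": rng.normal(size=len(x)),
            },
            index=x.index,
        )
        sol = FactorSolution(
            loadings=pd.DataFrame(np.eye(3), columns=scores.columns),
            eigenvalues=np.ones(3), scores=scores, k=3,
        )
        out = score_regression(sol, design54)
        assert out.loc["F1", "p_age"] < 0.01
        assert out.loc["F2", "p_fitness"] < 0.01
        assert out.loc["F2", "p_age"] > 0.01
        assert out.loc["F3", "p_age"] > 0.001

    def test_pure_noise_factor_rarely_significant(self, design54, rng):
        hits = 0
        runs = 40
        for _ in range(runs):
            scores = pd.DataFrame(
                {"F1": rng.normal(size=len(design54))},
                index=design54["id"],
            )
            sol = FactorSolution(
                loadings=pd.DataFrame(np.eye(1), columns=["F1"]),
                eigenvalues=np.ones(1), scores=scores, k=1,
            )
            out = score_regression(sol, design54)
            hits += int(out.loc["F1", "p_age"] < 0.05)
        assert hits <= 8  # one-tailed nominal 5% rate, generous band


class TestBlockRecovery:
    def test_five_planted_blocks_recovered(self, atlas):
        spec = SyntheticSpec(
            n=500, seed=0, factor_loading=800.0, sd_total=None, noise_sd=400.0
        )
        cohort = generate_cohort(spec)
        native, truth = generate_volumes(cohort, spec, atlas)
        vols = analysis_volumes(adjust_volume(combine_hemispheres(native, atlas)))
        rot = varimax_rotate(fit_pca(vols, k=5))
        assigned = (
            rot.loadings.abs().idxmax(axis=1).str.removeprefix("F").astype(int) - 1
        )
        tab = (
            pd.crosstab(assigned, truth.factor_block)
            .reindex(index=range(5), columns=range(5), fill_value=0)
            .to_numpy()
        )
        rows, cols = linear_sum_assignment(-tab)
        assert tab[rows, cols].sum() / len(atlas.regions) >= 0.9
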