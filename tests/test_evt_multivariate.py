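"""TPDM estimation and extreme PCA: exact identities and oracle recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from extremenorm import (
    MaxLinearSpec,
    estimate_tpdm,
    extreme_pca,
    gen_maxlinear_frechet,
    loadings_contributions,
    polar_decompose_threshold,
    project_scores,
    to_pseudo_frechet,
    tpdm_from_zscores,
)
from extremenorm.evt_multivariate import TPDM


class TestPseudoFrechet:
    def test_rank_cdf_small_sample(self):
        x = to_pseudo_frechet(np.array([[3.0, 1.0], [1.0, 2.0], [2.0, 3.0]]),
                              min_distinct=1)
        # ranks of [3, 1, 2] are [3, 1, 2]; F = rank/(n+1)
        expected_F = np.array([0.75, 0.25, 0.50])
        np.testing.assert_allclose(x.values[:, 0],
                                   (-np.log(expected_F)) ** -0.5)

    def test_closed_form_inverse_points(self):
        # F = e^-1 -> x = 1; F = e^(-1/4) -> x = 2
        assert (-np.log(np.exp(-1.0))) ** -0.5 == pytest.approx(1.0)
        assert (-np.log(np.exp(-0.25))) ** -0.5 == pytest.approx(2.0)

    def test_marginal_law(self):
        rng = np.random.default_rng(30)
        x = to_pseudo_frechet(rng.standard_normal((50000, 1)))
        p = (x.values[:, 0] <= 1.0).mean()
        se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / 50000)
        assert abs(p - np.exp(-1)) < 3 * se

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"good": np.arange(30.0), "flat": np.ones(30)})
        with pytest.raises(ValueError, match="flat"):
            to_pseudo_frechet(df)

    def test_missing_rows_dropped_with_count(self):
        Z = np.random.default_rng(31).standard_normal((100, 2))
        Z[3, 0] = np.nan
        with pytest.warns(UserWarning, match="dropping 1 rows"):
            x = to_pseudo_frechet(Z)
        assert x.n_subjects == 99
        assert x.n_dropped_rows == 1


class TestPolar:
    def test_three_four_five(self):
        from extremenorm.evt_multivariate import PseudoFrechetMatrix

        x = PseudoFrechetMatrix(values=np.array([[3.0, 4.0]] * 50),
                                columns=("a", "b"))
        polar = polar_decompose_threshold(x, quantile=0.5, min_exceedances=0)
        np.testing.assert_allclose(polar.radius, 5.0)
        np.testing.assert_allclose(polar.angles, [[0.6, 0.8]] * 50)

    def test_exceedance_count_at_95(self):
        rng = np.random.default_rng(32)
        x = to_pseudo_frechet(rng.standard_normal((1000, 3)))
        polar = polar_decompose_threshold(x, quantile=0.95)
        assert polar.n_exceedances == 50

    def test_reconstruction(self):
        rng = np.random.default_rng(33)
        x = to_pseudo_frechet(rng.standard_normal((200, 4)))
        polar = polar_decompose_threshold(x)
        np.testing.assert_allclose(polar.radius[:, None] * polar.angles,
                                   x.values, rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(polar.angles, axis=1), 1.0,
                                   rtol=1e-12)

    def test_bad_quantile(self):
        x = to_pseudo_frechet(np.random.default_rng(0).standard_normal((50, 2)))
        with pytest.raises(ValueError):
            polar_decompose_threshold(x, quantile=1.2)


class TestTPDM:
    def test_single_exceedance_printed_mode(self):
        from extremenorm.evt_multivariate import PolarDecomposition

        mask = np.array([False, True])
        polar = PolarDecomposition(radius=np.array([1.0, 5.0]),
                                   angles=np.array([[1.0, 0.0], [0.6, 0.8]]),
                                   radial_threshold=2.0, quantile=0.5,
                                   exceedance_mask=mask, columns=("a", "b"))
        t = estimate_tpdm(polar, normalization="printed")
        np.testing.assert_allclose(t.matrix, [[0.72, 0.96], [0.96, 1.28]])
        assert np.trace(t.matrix) == pytest.approx(2.0)

    @pytest.mark.parametrize("d", [2, 3, 7])
    def test_trace_identities_exact(self, d):
        rng = np.random.default_rng(35 + d)
        x = to_pseudo_frechet(rng.standard_normal((500, d)))
        polar = polar_decompose_threshold(x)
        assert np.trace(estimate_tpdm(polar, "printed").matrix) == pytest.approx(
            2.0, abs=1e-12)
        assert np.trace(estimate_tpdm(polar, "unit").matrix) == pytest.approx(
            float(d), abs=1e-12)

    def test_oracle_recovery(self, twofactor_spec, twofactor_zscores):
        t, _, _ = tpdm_from_zscores(twofactor_zscores)
        np.testing.assert_allclose(t.matrix, twofactor_spec.oracle_tpdm(),
                                   atol=0.07)

    def test_independent_factors_bias_shrinks_with_threshold(self):
        # for tail-independent data the off-diagonal estimate carries a
        # finite-threshold bias of order 1/r0; it must shrink monotonically
        # as the radial quantile rises
        spec = MaxLinearSpec(np.eye(2))
        X = gen_maxlinear_frechet(200000, spec, seed=36)
        offs = [tpdm_from_zscores(X, quantile=q)[0].matrix[0, 1]
                for q in (0.90, 0.99, 0.999)]
        assert offs[0] > offs[1] > offs[2] > 0
        assert offs[2] < 0.5 * offs[0]

    def test_complete_dependence_limit(self):
        spec = MaxLinearSpec(np.array([[1.0], [1.0]]))
        X = gen_maxlinear_frechet(5000, spec, seed=37)
        t, _, _ = tpdm_from_zscores(X)
        assert t.matrix[0, 1] == pytest.approx(t.matrix[0, 0], abs=1e-10)

    def test_error_shrinks_with_n(self, twofactor_spec):
        # consistency holds when the radial threshold grows with n (the
        # exceedance fraction shrinks): mean oracle error drops from
        # (n=5000, q=0.95) to (n=80000, q=0.9875)
        from extremenorm import gen_tail_dependent_zscores

        oracle = twofactor_spec.oracle_tpdm()
        e_small, e_large = [], []
        for r in range(10):
            z_s = gen_tail_dependent_zscores(5000, twofactor_spec, seed=400 + r)
            z_l = gen_tail_dependent_zscores(80000, twofactor_spec, seed=500 + r)
            e_small.append(np.abs(
                tpdm_from_zscores(z_s, quantile=0.95)[0].matrix - oracle).max())
            e_large.append(np.abs(
                tpdm_from_zscores(z_l, quantile=0.9875)[0].matrix - oracle).max())
        assert np.mean(e_large) < np.mean(e_small)
        assert np.mean(e_large) < 0.04

    @given(seed=st.integers(0, 100))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_monotone_marginal_invariance(self, seed):
        # strictly monotone per-column transforms cannot change the TPDM
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((300, 3))
        t0, _, _ = tpdm_from_zscores(Z)
        W = np.column_stack([np.exp(Z[:, 0]), Z[:, 1]**3, 2 * Z[:, 2] + 5])
        t1, _, _ = tpdm_from_zscores(W)
        np.testing.assert_allclose(t0.matrix, t1.matrix, atol=1e-12)

    def test_symmetric_psd(self, twofactor_zscores):
        t, _, _ = tpdm_from_zscores(twofactor_zscores)
        np.testing.assert_allclose(t.matrix, t.matrix.T)
        assert np.linalg.eigvalsh(t.matrix).min() >= -1e-10


class TestExtremePCA:
    def test_diagonal_proportions(self):
        t = TPDM(matrix=np.diag([2.0, 1.0, 1.0]), normalization="unit",
                 radial_threshold=1.0, n_exceedances=10)
        basis = extreme_pca(t)
        np.testing.assert_allclose(basis.scale_proportions, [0.5, 0.25, 0.25])
        np.testing.assert_allclose(basis.eigenvectors.T @ basis.eigenvectors,
                                   np.eye(3), atol=1e-10)

    def test_mode_invariance(self, twofactor_zscores):
        t_p, _, _ = tpdm_from_zscores(twofactor_zscores, normalization="printed")
        t_u, _, _ = tpdm_from_zscores(twofactor_zscores, normalization="unit")
        b_p, b_u = extreme_pca(t_p), extreme_pca(t_u)
        np.testing.assert_allclose(b_p.eigenvectors, b_u.eigenvectors, atol=1e-10)
        np.testing.assert_allclose(b_p.scale_proportions, b_u.scale_proportions,
                                   atol=1e-10)

    def test_nonsymmetric_rejected(self):
        t = TPDM(matrix=np.array([[1.0, 0.5], [0.1, 1.0]]), normalization="unit",
                 radial_threshold=1.0, n_exceedances=10)
        with pytest.raises(ValueError, match="symmetric"):
            extreme_pca(t)

    def test_planted_direction_recovery(self):
        # one dominant factor column: leading eigenvector aligns with it
        B = np.array([[1.0, 0.05], [0.9, 0.05], [0.8, 0.1]])
        spec = MaxLinearSpec(B)
        from extremenorm import gen_tail_dependent_zscores

        z = gen_tail_dependent_zscores(20000, spec, seed=38)
        t, _, _ = tpdm_from_zscores(z)
        u1 = extreme_pca(t).eigenvectors[:, 0]
        truth = np.linalg.eigh(spec.oracle_tpdm())[1][:, -1]
        angle = np.degrees(np.arccos(min(1.0, abs(u1 @ truth))))
        assert angle < 10.0


class TestLoadingsContributions:
    def test_printed_formulas(self):
        from extremenorm.evt_multivariate import ExtremeEigenBasis

        basis = ExtremeEigenBasis(eigenvalues=np.array([2.0, 1.0]),
                                  eigenvectors=np.eye(2),
                                  scale_proportions=np.array([2 / 3, 1 / 3]))
        f, c = loadings_contributions(basis, 2, mode="printed")
        np.testing.assert_allclose(f[:, 0], [2.0, 0.0])
        np.testing.assert_allclose(c[:, 0], [2.0, 0.0])

    def test_conventional_contributions_sum_to_one(self):
        from extremenorm.evt_multivariate import ExtremeEigenBasis

        basis = ExtremeEigenBasis(eigenvalues=np.array([2.0, 1.0]),
                                  eigenvectors=np.eye(2),
                                  scale_proportions=np.array([2 / 3, 1 / 3]))
        f, c = loadings_contributions(basis, 2, mode="conventional")
        np.testing.assert_allclose(f[:, 0], [np.sqrt(2), 0.0])
        np.testing.assert_allclose(c.sum(axis=0), [1.0, 1.0])

    def test_ranking_agrees_between_modes(self, twofactor_zscores):
        t, _, _ = tpdm_from_zscores(twofactor_zscores)
        basis = extreme_pca(t)
        _, c_p = loadings_contributions(basis, 2, mode="printed")
        _, c_c = loadings_contributions(basis, 2, mode="conventional")
        for l in range(2):
            assert np.array_equal(np.argsort(c_p[:, l]), np.argsort(c_c[:, l]))

    def test_factor_support_recovery(self):
        # two disjoint planted factors: top contributors match their supports
        B = np.zeros((6, 2))
        B[:3, 0] = [1.0, 0.9, 0.8]
        B[3:, 1] = [0.7, 0.6, 0.5]
        B += 0.01
        from extremenorm import gen_tail_dependent_zscores

        z = gen_tail_dependent_zscores(20000, MaxLinearSpec(B), seed=39)
        t, _, _ = tpdm_from_zscores(z)
        basis = extreme_pca(t)
        _, c = loadings_contributions(basis, 2)
        top1 = set(np.argsort(c[:, 0])[-3:])
        top2 = set(np.argsort(c[:, 1])[-3:])
        assert top1 == {0, 1, 2}
        assert top2 == {3, 4, 5}


class TestProjection:
    def test_round_trip(self, twofactor_zscores):
        t, _, x = tpdm_from_zscores(twofactor_zscores)
        basis = extreme_pca(t)
        scores = project_scores(x, basis, 2, score_map="log")
        recon = scores @ basis.eigenvectors.T
        np.testing.assert_allclose(recon, np.log(x.values), atol=1e-10)

    def test_row_on_eigenvector_loads_one_component(self):
        from extremenorm.evt_multivariate import ExtremeEigenBasis, PseudoFrechetMatrix

        U = np.linalg.qr(np.random.default_rng(40).standard_normal((3, 3)))[0]
        basis = ExtremeEigenBasis(eigenvalues=np.array([3.0, 2.0, 1.0]),
                                  eigenvectors=U,
                                  scale_proportions=np.array([0.5, 1 / 3, 1 / 6]))
        row = 2.5 * U[:, 0]
        x = PseudoFrechetMatrix(values=np.exp(row)[None, :],
                                columns=("a", "b", "c"))
        s = project_scores(x, basis, 3, score_map="log")
        np.testing.assert_allclose(s, [[2.5, 0.0, 0.0]], atol=1e-10)

    def test_extreme_subjects_have_large_leading_scores(self):
        B = np.array([[1.0, 0.02], [0.9, 0.02], [0.02, 0.3]])
        from extremenorm import gen_tail_dependent_zscores

        z = gen_tail_dependent_zscores(10000, MaxLinearSpec(B), seed=41)
        t, polar, x = tpdm_from_zscores(z)
        basis = extreme_pca(t)
        s = np.abs(project_scores(x, basis, 1)[:, 0])
        r = polar.radius
        top = s[r >= np.quantile(r, 0.9)]
        mid = s[(r >= np.quantile(r, 0.45)) & (r <= np.quantile(r, 0.55))]
        assert stats.mannwhitneyu(top, mid, alternative="greater").pvalue < 1e-6

    def test_component_count_validated(self, twofactor_zscores):
        t, _, x = tpdm_from_zscores(twofactor_zscores)
        basis = extreme_pca(t)
        with pytest.raises(ValueError):
            project_scores(x, basis, 3)
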