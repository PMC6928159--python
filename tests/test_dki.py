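import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nervedki.dki import (
    TensorFit,
    build_design_matrix,
    dti_scalars,
    apparent_kurtosis,
    fa_from_ratio,
    fit_volume,
    fit_wlls,
    full_to_w15,
    kurtosis_scalars,
    predict_signal,
    w15_to_full,
)
from nervedki.gradients import GradientScheme, make_gradient_scheme
from nervedki.synthetic import cylindrical_truth


def random_truth(rng, s0=100.0):
    """Random positive-definite D with modest anisotropy and random W."""
    A = rng.standard_normal((3, 3)) * 0.25
    D = A @ A.T + 0.6 * np.eye(3)
    w15 = rng.standard_normal(15) * 0.2
    return TensorFit(s0=s0, D=D, w15=w15)


class TestPredictSignal:
    def test_hand_values_prolate_tensor(self):
        # D = diag(1.5, 0.5, 0.5) um^2/ms, W = 0, b = 2 ms/um^2:
        # along x -> exp(-2*1.5) = e^-3, along y -> exp(-2*0.5) = e^-1
        fit = TensorFit(1.0, np.diag([1.5, 0.5, 0.5]), np.zeros(15))
        scheme = GradientScheme(
            bvalues=np.array([0.0, 2000.0, 2000.0]),
            directions=np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]),
        )
        sig = predict_signal(fit, scheme)
        assert sig[0] == pytest.approx(1.0)
        assert sig[1] == pytest.approx(np.exp(-3.0), rel=1e-12)
        assert sig[2] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_isotropic_signal_direction_independent(self):
        # isotropic D and isotropic K0: identical along any direction
        truth = cylindrical_truth(1.0, 1.0, ak=0.9, rk=0.9)
        dirs = np.vstack([np.zeros(3), np.eye(3),
                          [np.ones(3) / np.sqrt(3)]])
        scheme = GradientScheme(
            bvalues=np.array([0.0, 2000.0, 2000.0, 2000.0, 2000.0]),
            directions=dirs,
        )
        sig = predict_signal(truth.as_fit(), scheme)
        expected = np.exp(-2.0 * 1.0 + (4.0 / 6.0) * 1.0 * 0.9)
        np.testing.assert_allclose(sig[1:], expected, rtol=1e-14)

    def test_nonpositive_s0_rejected(self, study_scheme):
        fit = TensorFit(0.0, np.eye(3), np.zeros(15))
        with pytest.raises(ValueError, match="S0"):
            predict_signal(fit, study_scheme)


class TestDesignMatrix:
    def test_b0_row_is_intercept_only(self, study_scheme):
        A = build_design_matrix(study_scheme)
        row0 = A[study_scheme.b0_mask][0]
        assert row0[0] == 1.0
        np.testing.assert_array_equal(row0[1:], 0.0)

    def test_x_direction_isolates_dxx(self):
        scheme = GradientScheme(
            bvalues=np.array([0.0, 2000.0]),
            directions=np.array([[0, 0, 0], [1.0, 0, 0]]),
        )
        row = build_design_matrix(scheme)[1]
        assert row[1] == pytest.approx(-2.0)  # -b in ms/um^2 on Dxx
        np.testing.assert_array_equal(row[2:7], 0.0)
        assert row[7] == pytest.approx(4.0 / 6.0)  # (b^2/6) on Wxxxx
        np.testing.assert_array_equal(row[8:], 0.0)

    def test_study_scheme_full_rank(self, study_scheme):
        A = build_design_matrix(study_scheme)
        assert A.shape == (41, 22)
        assert np.linalg.matrix_rank(A) == 22


class TestFitWlls:
    def test_noise_free_round_trip(self, study_scheme, rng):
        truth = random_truth(rng)
        fit = fit_wlls(predict_signal(truth, study_scheme), study_scheme)
        np.testing.assert_allclose(fit.D, truth.D, atol=1e-8)
        np.testing.assert_allclose(fit.w15, truth.w15, atol=1e-6)
        assert fit.s0 == pytest.approx(truth.s0, rel=1e-8)

    def test_constant_signal_gives_zero_tensor(self, study_scheme):
        fit = fit_wlls(np.full(41, 5.0), study_scheme)
        np.testing.assert_allclose(fit.D, 0.0, atol=1e-10)
        assert fit.md_nonpositive
        assert np.all(np.isnan(fit.w15))

    def test_rician_noise_fa_bias_shrinks_with_snr(self, study_scheme):
        # Monte-Carlo robustness at truth FA 0.603: the rectified-noise
        # floor at b = 4000 s/mm^2 biases FA downward, so the median error
        # is bias-dominated, bounded, and must shrink as SNR rises
        from nervedki.synthetic import simulate_voxel_signal, NerveGroundTruth

        truth = NerveGroundTruth(
            D=np.diag([1.5, 0.5, 0.5]), w15=np.zeros(15), s0=1.0
        )
        truth_fa = dti_scalars(truth.D).fa
        assert truth_fa == pytest.approx(0.603, abs=5e-4)
        medians = {}
        for snr in (30, 150):
            errors = [
                abs(dti_scalars(
                    fit_wlls(
                        simulate_voxel_signal(truth, study_scheme, snr=snr,
                                              seed=i),
                        study_scheme,
                    ).D
                ).fa - truth_fa)
                for i in range(300)
            ]
            medians[snr] = np.median(errors)
        assert medians[30] < 0.15
        assert medians[150] < 0.05
        assert medians[150] < medians[30]

    def test_rank_deficient_design_rejected(self):
        scheme = make_gradient_scheme(6, [1000.0], n_b0=1, seed=0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_wlls(np.ones(7), scheme)

    def test_nonpositive_signals_clamped_and_flagged(self, study_scheme, rng):
        truth = random_truth(rng)
        sig = predict_signal(truth, study_scheme)
        sig[5] = -1.0
        fit = fit_wlls(sig, study_scheme)
        assert fit.n_clamped == 1

    def test_wlls_equals_ols_under_constant_weights(self, study_scheme):
        # constant signals -> pass-1 prediction constant -> equal weights,
        # so the second pass must reproduce the OLS solution
        sig = np.full(41, 3.0)
        one_pass = fit_wlls(sig, study_scheme, n_passes=1)
        two_pass = fit_wlls(sig, study_scheme, n_passes=2)
        np.testing.assert_allclose(two_pass.D, one_pass.D, atol=1e-10)


class TestDtiScalars:
    def test_hand_values(self):
        sc = dti_scalars(np.diag([1.5, 0.5, 0.5]))
        assert sc.ad == pytest.approx(1.5)
        assert sc.rd == pytest.approx(0.5)
        assert sc.md == pytest.approx(2.5 / 3.0, abs=1e-12)
        assert sc.fa == pytest.approx(0.60302, abs=1e-5)

    @pytest.mark.parametrize("d", [0.3, 1.0, 2.5])
    def test_isotropic(self, d):
        sc = dti_scalars(d * np.eye(3))
        assert sc.fa == pytest.approx(0.0, abs=1e-12)
        assert sc.md == pytest.approx(d)
        assert sc.e1_undefined

    def test_stick_limit(self):
        assert dti_scalars(np.diag([1.0, 0, 0])).fa == pytest.approx(1.0)

    def test_zero_tensor_flagged(self):
        sc = dti_scalars(np.zeros((3, 3)))
        assert sc.fa == 0.0
        assert sc.e1_undefined

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_md_identity_and_ordering(self, seed):
        # MD = (AD + 2 RD)/3 and AD >= RD for any symmetric tensor
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        D = (A + A.T) / 2.0
        sc = dti_scalars(D)
        assert sc.md == pytest.approx((sc.ad + 2 * sc.rd) / 3.0, abs=1e-12)
        assert sc.ad >= sc.rd - 1e-12
        assert 0.0 <= sc.fa  # FA in [0, sqrt(3/2)] for indefinite tensors


class TestApparentKurtosis:
    def test_even_in_direction(self, rng):
        truth = random_truth(rng)
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        k1 = apparent_kurtosis(truth.D, truth.w15, n[None, :])
        k2 = apparent_kurtosis(truth.D, truth.w15, -n[None, :])
        assert k1[0] == pytest.approx(k2[0], abs=1e-14)

    def test_zero_w_gives_zero(self, rng):
        n = np.array([[0.0, 0.0, 1.0]])
        assert apparent_kurtosis(np.eye(3), np.zeros(15), n)[0] == 0.0

    def test_w15_full_round_trip(self, rng):
        w15 = rng.standard_normal(15)
        np.testing.assert_array_equal(full_to_w15(w15_to_full(w15)), w15)


class TestKurtosisScalars:
    def test_isotropic_k0(self):
        truth = cylindrical_truth(1.2, 1.2, ak=0.8, rk=0.8)
        mk, ak, rk = kurtosis_scalars(truth.D, truth.w15)
        assert mk == pytest.approx(0.8, abs=1e-10)
        assert ak == pytest.approx(0.8, abs=1e-10)
        assert rk == pytest.approx(0.8, abs=1e-10)

    def test_zero_w(self):
        mk, ak, rk = kurtosis_scalars(np.diag([1.5, 0.5, 0.5]), np.zeros(15))
        assert (mk, ak, rk) == (0.0, 0.0, 0.0)

    def test_cylindrical_targets_recovered(self):
        truth = cylindrical_truth(1.6, 0.4, ak=0.6, rk=1.3)
        mk, ak, rk = kurtosis_scalars(truth.D, truth.w15)
        assert ak == pytest.approx(0.6, abs=1e-10)
        assert rk == pytest.approx(1.3, abs=1e-10)

    def test_radial_quadrature_converged_at_default(self, rng):
        # the in-plane integrand is degree 4, so 64 points are already exact
        truth = cylindrical_truth(1.7, 0.4, ak=0.7, rk=1.1)
        w_perturbed = truth.w15 + rng.standard_normal(15) * 0.05
        rk_64 = kurtosis_scalars(truth.D, w_perturbed, n_radial=64)[2]
        rk_4096 = kurtosis_scalars(truth.D, w_perturbed, n_radial=4096)[2]
        assert abs(rk_64 - rk_4096) < 1e-10


class TestFaFromRatio:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.40, 0.5222), (1.0, 0.0), (0.0, 1.0)],
    )
    def test_reference_points(self, ratio, expected):
        assert fa_from_ratio(ratio) == pytest.approx(expected, abs=5e-5)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.0, 3.0, 301)
        vals = fa_from_ratio(grid)
        assert np.all(np.diff(vals) < 0)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            fa_from_ratio(-0.1)

    def test_matches_eigenvalue_fa_for_cylindrical_tensors(self):
        for ratio in np.arange(0.0, 1.0001, 0.05):
            D = np.diag([1.0, ratio, ratio])
            assert dti_scalars(D).fa == pytest.approx(
                fa_from_ratio(ratio), abs=1e-12
            )


class TestScaleCovariance:
    def test_b_rescaling_leaves_signal_unchanged(self, rng):
        # b -> c b with D -> D/c (W unchanged: K_app is dimensionless)
        truth = random_truth(rng)
        c = 2.5
        scheme = make_gradient_scheme(20, [2000.0, 4000.0], n_b0=1, seed=3)
        scaled_scheme = GradientScheme(
            bvalues=scheme.bvalues * c, directions=scheme.directions
        )
        scaled_truth = TensorFit(truth.s0, truth.D / c, truth.w15)
        np.testing.assert_allclose(
            predict_signal(truth, scheme),
            predict_signal(scaled_truth, scaled_scheme),
            rtol=1e-12,
        )


class TestFitVolume:
    def test_noise_free_phantom_round_trip(self, study_scheme):
        truths = [cylindrical_truth(1.6, 0.3 + 0.05 * z, s0=50.0)
                  for z in range(4)]
        from nervedki.synthetic import simulate_nerve_volume

        img, mask, _ = simulate_nerve_volume(
            truths, study_scheme, radius=1.5, matrix=(6, 6),
            injury_start=1, injury_end=2,
        )
        maps = fit_volume(img, mask, study_scheme)
        for z, truth in enumerate(truths):
            expected = dti_scalars(truth.D).fa
            got = maps["fa"][:, :, z][mask[:, :, z]]
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_empty_mask_rejected(self, study_scheme):
        img = np.ones((4, 4, 2, 41))
        with pytest.raises(ValueError, match="empty mask"):
            fit_volume(img, np.zeros((4, 4, 2), dtype=bool), study_scheme)

    def test_shape_mismatch_reports_shapes(self, study_scheme):
        img = np.ones((4, 4, 2, 40))
        mask = np.ones((4, 4, 2), dtype=bool)
        with pytest.raises(ValueError, match="40"):
            fit_volume(img, mask, study_scheme)

    def test_voxel_conservation(self, study_scheme, rng):
        # every masked voxel is either finite in FA or flagged
        truths = [cylindrical_truth(1.6, 0.4, s0=1.0) for _ in range(2)]
        from nervedki.synthetic import simulate_nerve_volume

        img, mask, _ = simulate_nerve_volume(
            truths, study_scheme, radius=1.5, matrix=(6, 6),
            injury_start=0, injury_end=0, snr=5, seed=0,
        )
        maps = fit_volume(img, mask, study_scheme)
        finite = np.isfinite(maps["fa"]) & mask
        flagged = maps["flag"] & mask
        assert finite.sum() + flagged.sum() >= mask.sum()
        assert np.all(finite | flagged | ~mask)
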