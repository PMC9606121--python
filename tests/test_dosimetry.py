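"""Dose-point-kernel convolution and the limited-slice methods."""

import numpy as np
import pytest

from alphadose.dosimetry import (GY_PER_S_TO_MGY_PER_H, MEV_TO_J, MediumModel,
                                 central_slice, cloning_dose_rate,
                                 convolve_dose_rate,
                                 fit_contribution_correction,
                                 slice_contribution_curve)
from alphadose.kernel import DoseKernel
from alphadose.registration import ActivityStack

VOX = (26.0, 26.0, 12.0)
MASS_KG = np.prod(VOX) * 1e-12 * 1e-3  # water voxel


def mk_stack(values):
    return ActivityStack(np.asarray(values, float), VOX)


def mk_kernel(values):
    v = np.asarray(values, float)
    return DoseKernel(v, VOX, 1, np.zeros_like(v))


def brute_force(stackv, kernv):
    """Direct triple-loop summation oracle (same units pipeline)."""
    nz, ny, nx = stackv.shape
    kz, ky, kx = kernv.shape
    hz, hy, hx = kz // 2, ky // 2, kx // 2
    out = np.zeros_like(stackv)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = stackv[z, y, x]
                if a == 0:
                    continue
                for dz in range(-hz, hz + 1):
                    for dy in range(-hy, hy + 1):
                        for dx in range(-hx, hx + 1):
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                out[zz, yy, xx] += a * kernv[dz + hz,
                                                             dy + hy, dx + hx]
    return out * MEV_TO_J / MASS_KG * GY_PER_S_TO_MGY_PER_H


class TestConvolveDoseRate:
    def test_delta_kernel_closed_form(self):
        A = np.zeros((3, 5, 5))
        A[1, 2, 2] = 1.0  # 1 Bq
        K = np.zeros((1, 1, 1))
        K[0, 0, 0] = 6.0  # MeV per emission
        dmap = convolve_dose_rate(mk_stack(A), mk_kernel(K))
        expect = 6.0 * MEV_TO_J / MASS_KG * GY_PER_S_TO_MGY_PER_H
        assert dmap.values[1, 2, 2] == pytest.approx(expect, rel=1e-12)

    def test_matches_brute_force_summation(self, rng):
        A = rng.random((5, 16, 16))
        K = rng.random((5, 5, 5))
        dmap = convolve_dose_rate(mk_stack(A), mk_kernel(K))
        ref = brute_force(A, K)
        np.testing.assert_allclose(dmap.values, ref, rtol=1e-9)

    def test_charged_particle_equilibrium_limit(self, rng):
        """Uniform activity much larger than the kernel: central dose rate
        equals a·ΣK/m (all emitted energy absorbed locally)."""
        K = rng.random((5, 5, 5))
        a = 0.7
        A = np.full((15, 31, 31), a)
        dmap = convolve_dose_rate(mk_stack(A), mk_kernel(K))
        cpe = a * K.sum() * MEV_TO_J / MASS_KG * GY_PER_S_TO_MGY_PER_H
        assert dmap.values[7, 15, 15] == pytest.approx(cpe, rel=5e-3)

    def test_linearity_in_activity(self, rng):
        A1, A2 = rng.random((3, 8, 8)), rng.random((3, 8, 8))
        K = rng.random((3, 3, 3))
        kern = mk_kernel(K)
        d1 = convolve_dose_rate(mk_stack(A1), kern).values
        d2 = convolve_dose_rate(mk_stack(A2), kern).values
        d12 = convolve_dose_rate(mk_stack(2 * A1 + 3 * A2), kern).values
        np.testing.assert_allclose(d12, 2 * d1 + 3 * d2, rtol=1e-9)

    def test_voxel_mismatch_and_even_kernel_rejected(self, rng):
        A = rng.random((3, 8, 8))
        K = rng.random((3, 3, 3))
        bad = DoseKernel(K, (10.0, 10.0, 12.0), 1, np.zeros_like(K))
        with pytest.raises(ValueError, match="rebin"):
            convolve_dose_rate(mk_stack(A), bad)
        even = DoseKernel(np.ones((2, 3, 3)), VOX, 1, np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="odd"):
            convolve_dose_rate(mk_stack(A), even)


class TestCentralSlice:
    def test_odd_depths(self, rng):
        for depth, idx in [(21, 10), (1, 0)]:
            A = rng.random((depth, 4, 4))
            dmap = convolve_dose_rate(mk_stack(A), mk_kernel(np.ones((1, 1, 1))))
            np.testing.assert_array_equal(central_slice(dmap).values,
                                          dmap.values[idx])

    def test_even_depth_rejected(self, rng):
        dmap = convolve_dose_rate(mk_stack(rng.random((4, 4, 4))),
                                  mk_kernel(np.ones((1, 1, 1))))
        with pytest.raises(ValueError, match="central"):
            central_slice(dmap)

    def test_z_mirror_symmetry(self, rng):
        A = rng.random((7, 6, 6))
        K = rng.random((3, 5, 5))
        K = K + K[::-1]  # z-symmetric kernel
        d1 = central_slice(convolve_dose_rate(mk_stack(A), mk_kernel(K)))
        d2 = central_slice(convolve_dose_rate(mk_stack(A[::-1]), mk_kernel(K)))
        np.testing.assert_allclose(d1.values, d2.values, rtol=1e-9)


class TestSliceContribution:
    def test_flat_kernel_no_out_of_slice_contribution(self, rng):
        A = rng.random((7, 8, 8))
        K = rng.random((1, 3, 3))  # single z-plane kernel
        res = slice_contribution_curve(mk_stack(A), mk_kernel(K))
        np.testing.assert_allclose(res.ratios, 1.0, rtol=1e-9)

    def test_ratio_reaches_one_at_n_max(self, rng):
        A = rng.random((7, 8, 8))
        K = rng.random((5, 3, 3))
        res = slice_contribution_curve(mk_stack(A), mk_kernel(K))
        assert res.ratios[-1] == pytest.approx(1.0, rel=1e-9)

    def test_monotone_non_decreasing_in_n(self, rng):
        A = rng.random((9, 8, 8))
        K = rng.random((7, 3, 3))
        res = slice_contribution_curve(mk_stack(A), mk_kernel(K))
        assert np.all(np.diff(res.dose_rate_N) >= -1e-12)

    def test_matches_manually_zeroed_oracle(self, rng):
        A = rng.random((5, 6, 6))
        K = rng.random((5, 3, 3))
        res = slice_contribution_curve(mk_stack(A), mk_kernel(K))
        for N, got in zip(res.N_values, res.dose_rate_N):
            Az = np.zeros_like(A)
            c, h = 2, (N - 1) // 2
            Az[c - h:c + h + 1] = A[c - h:c + h + 1]
            ref = brute_force(Az, K)[2].sum()
            assert got == pytest.approx(ref, rel=1e-9)


class TestContributionCorrection:
    def _result(self, alpha, beta, Nmax=15):
        from alphadose.dosimetry import SliceMinimizationResult
        N = np.arange(1, Nmax + 1, 2)
        ratios = 1 - alpha * np.exp(-beta * (N - 1))
        return SliceMinimizationResult(N, ratios * 100.0, 100.0)

    def test_noiseless_parameter_recovery(self):
        fitted = fit_contribution_correction(self._result(0.3, 0.4))
        alpha, beta = fitted.correction_fit
        assert alpha == pytest.approx(0.3, rel=1e-6)
        assert beta == pytest.approx(0.4, rel=1e-6)
        np.testing.assert_allclose(fitted.corrected, 100.0, rtol=1e-6)

    def test_unity_ratios_give_unit_correction(self):
        fitted = fit_contribution_correction(self._result(0.0, 1.0))
        np.testing.assert_allclose(fitted.corrected, fitted.dose_rate_N,
                                   rtol=1e-6)

    def test_chi2_reported_with_errors(self):
        res = self._result(0.2, 0.5)
        fitted = fit_contribution_correction(
            res, errors=np.full(res.N_values.size, 0.01))
        assert fitted.chi2_nu == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points(self):
        from alphadose.dosimetry import SliceMinimizationResult
        res = SliceMinimizationResult(np.array([1]), np.array([50.0]), 100.0)
        with pytest.raises(ValueError):
            fit_contribution_correction(res)


class TestCloning:
    def test_depth_uniform_stack_is_exact_for_every_n(self, rng):
        plane = rng.random((8, 8))
        A = np.stack([plane] * 7)
        K = rng.random((5, 3, 3))
        full = central_slice(convolve_dose_rate(mk_stack(A), mk_kernel(K)))
        for N in (1, 3, 5, 7):
            est = cloning_dose_rate(mk_stack(A), N, mk_kernel(K))
            np.testing.assert_allclose(est.values, full.values, rtol=1e-9)

    def test_n_equal_depth_matches_full_when_range_covered(self, rng):
        # stack much deeper than the kernel z-extent: cloning pads only
        # zero-influence slices
        A = np.zeros((9, 6, 6))
        A[3:6] = rng.random((3, 6, 6))
        K = rng.random((3, 3, 3))
        kern = DoseKernel(K, VOX, 1, np.zeros_like(K))
        full = central_slice(convolve_dose_rate(mk_stack(A), kern))
        est = cloning_dose_rate(mk_stack(A), 9, kern)
        np.testing.assert_allclose(est.values, full.values, rtol=1e-9)

    def test_hot_central_slice_overestimates(self, rng):
        """A feature present only in the measured slice is overemphasised:
        cloning copies it through depth, inflating the central dose rate."""
        A = np.full((7, 10, 10), 0.1)
        A[3, 4:6, 4:6] = 5.0  # hot blob only in the central slice
        K = np.ones((5, 3, 3))
        est = cloning_dose_rate(mk_stack(A), 1, mk_kernel(K))
        full = central_slice(convolve_dose_rate(mk_stack(A), mk_kernel(K)))
        hot = np.zeros((10, 10), bool)
        hot[4:6, 4:6] = True
        assert np.all(est.values[hot] > full.values[hot])

    def test_cold_central_slice_underestimates(self):
        A = np.full((7, 10, 10), 5.0)
        A[3] = 0.1  # central slice colder than its neighbours
        K = np.ones((5, 3, 3))
        est = cloning_dose_rate(mk_stack(A), 1, mk_kernel(K))
        full = central_slice(convolve_dose_rate(mk_stack(A), mk_kernel(K)))
        assert est.values.sum() < full.values.sum()

    def test_even_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cloning_dose_rate(mk_stack(np.ones((5, 4, 4))), 2,
                              mk_kernel(np.ones((3, 3, 3))))
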