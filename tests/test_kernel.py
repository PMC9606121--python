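"""Monte Carlo energy-deposition kernel: transport, averaging, rebinning."""

import numpy as np
import pytest

from alphadose.kernel import (DoseKernel, generate_kernel,
                              kernel_uncertainty_summary, radial_average,
                              rebin_kernel)
from alphadose.kernel import _branch_profile
from alphadose.physics import (AT211, ENERGY_CUTOFF_MEV, NuclideData,
                               csda_range)


def naive_resimulation(nuclide, model, n_events, voxel_um, half_extent_um, seed):
    """Independent per-step Python oracle consuming the same RNG stream."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(nuclide.branch_fractions)
    branch = np.searchsorted(cum, rng.random(n_events), side="right")
    cos_t = 1.0 - 2.0 * rng.random(n_events)
    phi = 2.0 * np.pi * rng.random(n_events)
    half_n = int(round(half_extent_um / voxel_um))
    n_side = 2 * half_n + 1
    grid = np.zeros((n_side, n_side, n_side))
    step = min(voxel_um / 5.0, 0.2)

    def deposit(p, e):
        ix = int(np.floor(p[0] / voxel_um + half_n + 0.5))
        iy = int(np.floor(p[1] / voxel_um + half_n + 0.5))
        iz = int(np.floor(p[2] / voxel_um + half_n + 0.5))
        grid[iz, iy, ix] += e

    for ev in range(n_events):
        E = nuclide.alpha_energies_MeV[branch[ev]]
        st = np.sqrt(max(0.0, 1.0 - cos_t[ev] ** 2))
        u = np.array([st * np.cos(phi[ev]), st * np.sin(phi[ev]), cos_t[ev]])
        s = 0.0
        while E > ENERGY_CUTOFF_MEV:
            dE = model.stopping(E) * step
            if dE >= E:
                break
            deposit(u * (s + 0.5 * step), dE)
            E -= dE
            s += step
        deposit(u * s, E)
    return grid / n_events


class TestGenerateKernel:
    def test_single_branch_energy_conservation_exact(self, water):
        nuc = NuclideData(alpha_energies_MeV=(5.87,), branch_fractions=(1.0,))
        k = generate_kernel(nuc, water, 500, seed=7)
        assert k.total_MeV == pytest.approx(5.87, abs=1e-9)

    def test_chain_total_is_branch_weighted_mean_of_sampled(self, water):
        k = generate_kernel(AT211, water, 2000, seed=3)
        # exact conservation of the *sampled* energies
        assert abs(k.total_MeV - AT211.mean_alpha_energy_MeV) < 0.05
        # and exactly a lattice point of the two branch energies
        n0 = round((AT211.alpha_energies_MeV[1] - k.total_MeV) * 2000
                   / (AT211.alpha_energies_MeV[1] - AT211.alpha_energies_MeV[0]))
        expect = (n0 * 5.87 + (2000 - n0) * 7.45) / 2000
        assert k.total_MeV == pytest.approx(expect, abs=1e-9)

    def test_single_event_deposits_along_one_ray(self, water):
        k = generate_kernel(AT211, water, 1, seed=11)
        nz = np.array(np.nonzero(k.values)).T - 75
        # all non-zero voxels are collinear with the origin (cross product ~ 0)
        far = nz[np.argmax(np.linalg.norm(nz, axis=1))]
        cross = np.cross(nz, far)
        assert np.all(np.linalg.norm(cross, axis=1)
                      <= 2.0 * np.linalg.norm(far))
        assert min(abs(k.total_MeV - 5.87), abs(k.total_MeV - 7.45)) < 1e-9

    def test_matches_naive_per_step_oracle(self, water):
        k = generate_kernel(AT211, water, 150, seed=99)
        oracle = naive_resimulation(AT211, water, 150, 1.0, 75.0, 99)
        np.testing.assert_allclose(k.values, oracle, rtol=1e-12, atol=1e-15)

    def test_same_seed_is_bitwise_identical(self, water):
        a = generate_kernel(AT211, water, 300, seed=5)
        b = generate_kernel(AT211, water, 300, seed=5)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.rel_uncertainty, b.rel_uncertainty)

    def test_support_bound(self, small_kernel, water):
        """No deposition beyond max CSDA range + one voxel diagonal."""
        rmax = csda_range(7.45, water) + np.sqrt(3.0)
        nz, ny, nx = small_kernel.shape
        z, y, x = np.ogrid[:nz, :ny, :nx]
        r = np.sqrt((z - 75.) ** 2 + (y - 75.) ** 2 + (x - 75.) ** 2)
        assert small_kernel.values[r > rmax].sum() == 0.0

    def test_refuses_truncating_grid(self, water):
        with pytest.raises(ValueError, match="truncate"):
            generate_kernel(AT211, water, 10, half_extent_um=30.0)
        k = generate_kernel(AT211, water, 10, half_extent_um=30.0,
                            truncate=True, seed=1)
        assert k.total_MeV <= AT211.alpha_energies_MeV[1]

    def test_invalid_event_count(self, water):
        with pytest.raises(ValueError):
            generate_kernel(AT211, water, 0)

    def test_branch_profile_conserves_energy(self, water):
        _, dep = _branch_profile(7.45, water, 0.2)
        assert dep.sum() == pytest.approx(7.45, abs=1e-12)


class TestRadialAverage:
    def test_fixed_point_on_spherically_symmetric_kernel(self):
        n = 11
        z, y, x = np.ogrid[:n, :n, :n]
        r = np.sqrt((z - 5.) ** 2 + (y - 5.) ** 2 + (x - 5.) ** 2)
        vals = np.exp(-np.floor(r))  # constant within each radial bin
        k = DoseKernel(vals, (1., 1., 1.), 1, np.zeros_like(vals))
        out = radial_average(k)
        np.testing.assert_allclose(out.values, vals, rtol=1e-12)

    def test_total_preserved(self, small_kernel):
        out = radial_average(small_kernel)
        assert out.total_MeV == pytest.approx(small_kernel.total_MeV,
                                              rel=1e-9)

    def test_matches_brute_force_grouping(self, rng):
        vals = rng.random((5, 5, 5))
        k = DoseKernel(vals, (1., 1., 1.), 1, np.zeros_like(vals))
        out = radial_average(k)
        z, y, x = np.ogrid[:5, :5, :5]
        r = np.sqrt((z - 2.) ** 2 + (y - 2.) ** 2 + (x - 2.) ** 2)
        for b in np.unique(np.floor(r)):
            sel = np.floor(r) == b
            np.testing.assert_allclose(out.values[sel], vals[sel].mean(),
                                       rtol=1e-12)

    def test_octahedral_symmetry_after_averaging(self, small_kernel_avg):
        v = small_kernel_avg.values
        for axes in [(0, 2, 1), (1, 0, 2), (2, 1, 0)]:
            np.testing.assert_allclose(v, np.transpose(v, axes), rtol=1e-9)
        np.testing.assert_allclose(v, v[::-1], rtol=1e-9)

    def test_rejects_non_cubic_voxels(self):
        k = DoseKernel(np.ones((3, 3, 3)), (1., 1., 2.), 1, np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            radial_average(k)

    def test_bragg_peak_radial_profile(self, small_kernel_avg):
        """Profile falls as ~1/r² at small radii, rises into the ²¹¹Po Bragg
        peak just before the 70-µm cutoff, and vanishes beyond the range."""
        c = 75
        prof = small_kernel_avg.values[c, c, c:]
        assert prof[2] > prof[20] > prof[45]       # flux dispersion
        assert prof[69] > prof[60]                  # Bragg rise near cutoff
        assert prof[47] > prof[49]                  # 5.87-MeV branch cutoff
        assert prof[72] == 0.0                      # beyond the 70-µm range
        assert prof[71] <= 1e-3 * prof[70]          # sub-voxel edge leakage


class TestRebinKernel:
    def test_identity_at_source_size(self, small_kernel_avg):
        out = rebin_kernel(small_kernel_avg, 1.0, 1.0)
        np.testing.assert_array_equal(out.values, small_kernel_avg.values)

    def test_three_um_rebin_of_ones(self):
        vals = np.ones((9, 9, 9))
        k = DoseKernel(vals, (1., 1., 1.), 1, np.zeros_like(vals))
        out = rebin_kernel(k, 3.0, 3.0)
        assert out.shape == (3, 3, 3)
        np.testing.assert_array_equal(out.values, np.full((3, 3, 3), 27.0))

    def test_twelve_um_rebin_z_support_within_six_slices(self, small_kernel_avg):
        """Energy deposition falls to zero beyond the adjacent ±6 12-µm
        slices (72 µm covers the 70-µm maximum range)."""
        out = rebin_kernel(small_kernel_avg, 26.0, 12.0)
        cz = (out.shape[0] - 1) // 2
        assert out.total_MeV == pytest.approx(small_kernel_avg.total_MeV,
                                              rel=1e-9)
        beyond = np.concatenate([out.values[:cz - 6].ravel(),
                                 out.values[cz + 7:].ravel()])
        assert np.all(beyond <= 1e-12)
        assert out.values[cz - 6].sum() >= 0

    def test_rejects_non_integer_multiple(self, small_kernel_avg):
        with pytest.raises(ValueError):
            rebin_kernel(small_kernel_avg, 2.5, 12.0)


class TestUncertaintySummary:
    def test_uniform_relative_uncertainty(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 2.0
        vals[0, 1, 1] = 1.0
        rel = np.where(vals > 0, 0.05, 0.0)
        k = DoseKernel(vals, (1., 1., 1.), 10, rel)
        assert kernel_uncertainty_summary(k) == pytest.approx(5.0)

    def test_all_zero_kernel_is_undefined(self):
        k = DoseKernel(np.zeros((3, 3, 3)), (1., 1., 1.), 10,
                       np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            kernel_uncertainty_summary(k)

    def test_scales_as_inverse_sqrt_of_events(self, water):
        """Quadrupling histories halves the statistical uncertainty (checked
        on a truncated grid where every voxel is well sampled)."""
        a = generate_kernel(AT211, water, 100_000, seed=8,
                            half_extent_um=35.0, truncate=True)
        b = generate_kernel(AT211, water, 400_000, seed=9,
                            half_extent_um=35.0, truncate=True)
        for ka, kb in [(a, b), (radial_average(a), radial_average(b))]:
            ratio = (kernel_uncertainty_summary(ka)
                     / kernel_uncertainty_summary(kb))
            assert ratio == pytest.approx(2.0, rel=0.15)
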