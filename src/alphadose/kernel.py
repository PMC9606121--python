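"""Monte Carlo alpha-particle energy-deposition kernel (dose-point kernel).

The kernel K is the mean energy deposited per source alpha emission in each
voxel of a 3-D grid centred on the emission point, for the ²¹¹At chain in
water.  It is generated by straight-track CSDA transport: each simulated
emission samples a decay branch and an isotropic direction, then walks a
straight ray from the grid centre depositing S(E)·Δs per sub-voxel step and
the residual energy at the track endpoint, so per-track energy conservation
is exact.  Because CSDA transport has no straggling, every track of a given
branch shares one deposition profile along its path; only the direction is
random.

The raw kernel is radially averaged (1-voxel-wide spherical shells) and then
rebinned by summation to the autoradiograph voxel geometry (XY 10–30 µm,
Z 12 µm) before convolution with an activity stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .physics import (
    ENERGY_CUTOFF_MEV,
    NuclideData,
    StoppingPowerModel,
    csda_range,
)

__all__ = [
    "DoseKernel",
    "generate_kernel",
    "radial_average",
    "rebin_kernel",
    "kernel_uncertainty_summary",
]


@dataclass
class DoseKernel:
    """3-D mean energy deposition per source alpha emission.

    Attributes
    ----------
    values : ndarray, shape (nz, ny, nx)
        Mean energy deposited per emission in each voxel (MeV).
    voxel_xyz_um : tuple
        Voxel edge lengths (x, y, z) in µm.
    n_events : int
        Number of source emissions simulated.
    rel_uncertainty : ndarray
        Relative standard error of ``values`` (dimensionless); 0 where the
        value itself is 0.
    provenance : dict
        Nuclide, seed and processing metadata.
    """

    values: np.ndarray
    voxel_xyz_um: tuple
    n_events: int
    rel_uncertainty: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def total_MeV(self) -> float:
        """Total energy per emission; equals the branch-weighted mean initial
        alpha energy under the endpoint-deposition rule."""
        return float(self.values.sum())

    @property
    def shape(self):
        return self.values.shape

    @property
    def center_index(self):
        return tuple((n - 1) // 2 for n in self.values.shape)


def _branch_profile(E0: float, model: StoppingPowerModel, step_um: float,
                    cutoff_MeV: float = ENERGY_CUTOFF_MEV):
    """Deterministic CSDA deposition profile of one branch along its track.

    Explicit Euler walk: deposit S(E)·Δs per step at the step midpoint,
    residual energy at the final position.  Returns (positions_um, deposits_MeV)
    with exact energy conservation: deposits.sum() == E0.
    """
    positions, deposits = [], []
    E = E0
    s = 0.0
    while E > cutoff_MeV:
        dE = model.stopping(E) * step_um
        if dE >= E:
            break
        positions.append(s + 0.5 * step_um)
        deposits.append(dE)
        E -= dE
        s += step_um
    # residual (including the sub-cutoff remainder) deposited at the endpoint
    positions.append(s)
    deposits.append(E)
    return np.asarray(positions), np.asarray(deposits)


@njit(cache=False)
def _accumulate_tracks(sum_, sumsq, dirs, s_pos, dep, center, inv_voxel, n_side):
    """Accumulate per-voxel Σd and Σd² over straight tracks.

    Consecutive steps falling in the same voxel are merged before squaring so
    that sumsq holds per-event per-voxel deposits squared.
    """
    n_steps = s_pos.shape[0]
    for ev in range(dirs.shape[0]):
        ux, uy, uz = dirs[ev, 0], dirs[ev, 1], dirs[ev, 2]
        cur = -1
        run = 0.0
        for j in range(n_steps):
            s = s_pos[j]
            ix = int(np.floor(s * ux * inv_voxel[0] + center[0] + 0.5))
            iy = int(np.floor(s * uy * inv_voxel[1] + center[1] + 0.5))
            iz = int(np.floor(s * uz * inv_voxel[2] + center[2] + 0.5))
            if (ix < 0 or ix >= n_side or iy < 0 or iy >= n_side
                    or iz < 0 or iz >= n_side):
                # outside a (deliberately) truncated grid: drop the deposit
                if cur >= 0:
                    sum_[cur] += run
                    sumsq[cur] += run * run
                cur = -1
                continue
            lin = (iz * n_side + iy) * n_side + ix
            if lin != cur:
                if cur >= 0:
                    sum_[cur] += run
                    sumsq[cur] += run * run
                cur = lin
                run = dep[j]
            else:
                run += dep[j]
        if cur >= 0:
            sum_[cur] += run
            sumsq[cur] += run * run


def _sample_emissions(nuclide: NuclideData, n: int, rng: np.random.Generator):
    """Sample branch indices and isotropic unit directions for n emissions.

    RNG contract (consumed in this order, one array each): branch uniforms,
    cos-theta uniforms, phi uniforms.
    """
    cum = np.cumsum(nuclide.branch_fractions)
    branch = np.searchsorted(cum, rng.random(n), side="right")
    cos_t = 1.0 - 2.0 * rng.random(n)
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    dirs = np.empty((n, 3))
    dirs[:, 0] = sin_t * np.cos(phi)
    dirs[:, 1] = sin_t * np.sin(phi)
    dirs[:, 2] = cos_t
    return branch, dirs


def generate_kernel(nuclide: NuclideData, model: StoppingPowerModel,
                    n_events: int, voxel_um: float = 1.0,
                    half_extent_um: float = 75.0, seed: int = 0,
                    truncate: bool = False,
                    chunk_events: int = 1_000_000) -> DoseKernel:
    """Simulate the 3-D energy-deposition kernel of the decay chain.

    Tracks start at the exact centre of the central voxel.  The grid has
    ``2·round(half_extent_um/voxel_um) + 1`` voxels per side (151 at the
    default 75 µm half-extent and 1 µm voxels).  Per-voxel sums and sums of
    squares over emissions provide the relative standard error of each mean.

    Raises unless ``half_extent_um`` covers the maximum CSDA range (a smaller
    grid would truncate the kernel), or ``truncate=True`` is passed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if voxel_um <= 0:
        raise ValueError("voxel_um must be positive")
    max_range = max(csda_range(e, model) for e in nuclide.alpha_energies_MeV)
    if half_extent_um < max_range and not truncate:
        raise ValueError(
            f"half_extent_um={half_extent_um} is smaller than the maximum CSDA "
            f"range {max_range:.1f} µm; pass truncate=True to accept a "
            "truncated kernel"
        )
    step_um = min(voxel_um / 5.0, 0.2)
    profiles = [
        _branch_profile(e, model, step_um) for e in nuclide.alpha_energies_MeV
    ]
    half_n = int(round(half_extent_um / voxel_um))
    n_side = 2 * half_n + 1
    sum_ = np.zeros(n_side**3)
    sumsq = np.zeros(n_side**3)
    center = np.full(3, float(half_n))
    inv_voxel = np.full(3, 1.0 / voxel_um)

    rng = np.random.default_rng(seed)
    done = 0
    while done < n_events:
        m = min(chunk_events, n_events - done)
        branch, dirs = _sample_emissions(nuclide, m, rng)
        for b in range(len(nuclide.alpha_energies_MeV)):
            sel = branch == b
            if not np.any(sel):
                continue
            s_pos, dep = profiles[b]
            _accumulate_tracks(sum_, sumsq, dirs[sel], s_pos, dep,
                               center, inv_voxel, n_side)
        done += m

    n = float(n_events)
    values = (sum_ / n).reshape(n_side, n_side, n_side)
    if n_events > 1:
        var = np.maximum(sumsq - sum_**2 / n, 0.0) / (n * (n - 1.0))
        se = np.sqrt(var).reshape(n_side, n_side, n_side)
    else:
        se = np.zeros_like(values)
    rel = np.zeros_like(values)
    np.divide(se, values, out=rel, where=values > 0)
    provenance = {
        "nuclide": nuclide.name,
        "alpha_energies_MeV": list(nuclide.alpha_energies_MeV),
        "branch_fractions": list(nuclide.branch_fractions),
        "seed": seed,
        "step_um": step_um,
        "half_extent_um": half_extent_um,
        "radially_averaged": False,
    }
    return DoseKernel(values, (voxel_um,) * 3, n_events, rel, provenance)


def radial_average(kernel: DoseKernel) -> DoseKernel:
    """Replace each voxel value by the mean of its 1-voxel-wide radial shell.

    Voxels are grouped by the Euclidean distance of their centres from the
    source voxel centre into half-open bins [r, r+Δ) one voxel wide.  Group
    means preserve the kernel total exactly; the per-voxel relative
    uncertainty becomes the bin-pooled standard error of the shell mean,
    sqrt(Σ σ_i²)/M for a shell of M voxels.
    """
    vx = kernel.voxel_xyz_um
    if not (abs(vx[0] - vx[1]) < 1e-12 and abs(vx[1] - vx[2]) < 1e-12):
        raise ValueError("radial averaging requires cubic voxels "
                         "(average before rebinning)")
    nz, ny, nx = kernel.values.shape
    cz, cy, cx = [(n - 1) // 2 for n in (nz, ny, nx)]
    z, y, x = np.ogrid[:nz, :ny, :nx]
    r = np.sqrt((z - cz) ** 2.0 + (y - cy) ** 2.0 + (x - cx) ** 2.0)
    bins = np.floor(r).astype(np.int64).ravel()
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=kernel.values.ravel(), minlength=nbins)
    means = sums / counts
    sigma = kernel.rel_uncertainty * kernel.values
    var_sums = np.bincount(bins, weights=(sigma**2).ravel(), minlength=nbins)
    se_bin = np.sqrt(var_sums) / counts
    values = means[bins].reshape(kernel.values.shape)
    se = se_bin[bins].reshape(kernel.values.shape)
    rel = np.zeros_like(values)
    np.divide(se, values, out=rel, where=values > 0)
    provenance = dict(kernel.provenance, radially_averaged=True)
    return DoseKernel(values, kernel.voxel_xyz_um, kernel.n_events, rel,
                      provenance)


def rebin_kernel(kernel: DoseKernel, target_xy_um: float,
                 target_z_um: float) -> DoseKernel:
    """Rebin to coarser voxels by summation (energy is extensive).

    Target sizes must be integer multiples of the source voxel size.  The
    output grid is centred on the source voxel, with odd dimensions so a
    central voxel exists; the kernel total is preserved exactly.  Output
    uncertainties combine constituent variances in quadrature.
    """
    factors = []
    for tgt, src in zip((target_xy_um, target_xy_um, target_z_um),
                        kernel.voxel_xyz_um):
        f = tgt / src
        if abs(f - round(f)) > 1e-9:
            raise ValueError(
                f"target voxel {tgt} µm is not an integer multiple of the "
                f"source voxel {src} µm (resampling is not supported)"
            )
        factors.append(int(round(f)))
    fx, fy, fz = factors

    def _axis_bins(n, f):
        c = (n - 1) // 2
        i_rel = np.arange(n) - c
        q = (i_rel + f // 2) // f  # floor division; half-open blocks of f
        return q

    qz = _axis_bins(kernel.values.shape[0], fz)
    qy = _axis_bins(kernel.values.shape[1], fy)
    qx = _axis_bins(kernel.values.shape[2], fx)
    Q = [max(-q.min(), q.max()) for q in (qz, qy, qx)]
    shape = tuple(2 * Qi + 1 for Qi in Q)
    iz = (qz + Q[0])[:, None, None]
    iy = (qy + Q[1])[None, :, None]
    ix = (qx + Q[2])[None, None, :]
    lin = ((iz * shape[1] + iy) * shape[2] + ix).ravel()
    n_out = shape[0] * shape[1] * shape[2]
    values = np.bincount(lin, weights=kernel.values.ravel(),
                         minlength=n_out).reshape(shape)
    sigma2 = (kernel.rel_uncertainty * kernel.values) ** 2
    var = np.bincount(lin, weights=sigma2.ravel(),
                      minlength=n_out).reshape(shape)
    rel = np.zeros_like(values)
    np.divide(np.sqrt(var), values, out=rel, where=values > 0)
    provenance = dict(kernel.provenance,
                      rebinned_from_um=kernel.voxel_xyz_um)
    return DoseKernel(values, (target_xy_um, target_xy_um, target_z_um),
                      kernel.n_events, rel, provenance)


def kernel_uncertainty_summary(kernel: DoseKernel) -> float:
    """Mean relative statistical uncertainty over non-zero voxels, in percent."""
    mask = kernel.values > 0
    if not np.any(mask):
        raise ValueError("kernel has no non-zero voxels; summary undefined")
    return float(kernel.rel_uncertainty[mask].mean() * 100.0)
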