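"""Digital lymph-node phantoms and simulated acquisitions.

The generator produces the ground truth every pipeline stage can be tested
against without any external data: a 3-D activity distribution shaped like a
small lymph node (uniform background inside an ellipsoid with focal Gaussian
"hot" regions of elevated uptake), event-by-event acquisitions of each 12-µm
slice under ²¹¹At decay (Poisson counting, ~20 µm FWHM detector blur,
per-slice rigid misalignment, optional torn slices), and a pseudo-H&E
rendering of the tissue outline for fusion tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histofusion import HistologyImage
from .listmode import LISTMODE_COLUMNS, AcquisitionConfig, ListmodeData
from .physics import AT211, NuclideData
from .registration import ActivityStack

__all__ = [
    "PhantomSpec",
    "build_truth_stack",
    "simulate_acquisition",
    "render_pseudo_he",
]


@dataclass
class PhantomSpec:
    """Geometry and statistics of a synthetic lymph-node phantom.

    ``hot_foci`` is a list of (center_xyz_voxels, sigma_um, amplitude_Bq)
    isotropic Gaussian uptake foci; all centres must lie inside the
    ellipsoidal node.  Defaults follow the acquisition geometry of the
    autoradiography studies: 26-µm XY pixels, 12-µm slices, 20-µm FWHM blur.
    """

    shape_xyz: tuple = (48, 48, 9)          # (nx, ny, nz) voxels
    voxel_xyz_um: tuple = (26.0, 26.0, 12.0)
    semi_axes_voxels: tuple = (18.0, 14.0, 10.0)
    background_activity_Bq: float = 0.05
    hot_foci: list = field(default_factory=list)
    psf_fwhm_um: float = 20.0
    jitter_rotation_deg: float = 10.0       # per-slice rotation ~ U(-x, x)
    jitter_translation_px: float = 20.0     # per-slice shift ~ U(-x, x)
    torn_slices: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.background_activity_Bq < 0:
            raise ValueError("background activity must be non-negative")
        for center, sigma_um, amp in self.hot_foci:
            if amp < 0 or sigma_um <= 0:
                raise ValueError("focus amplitude must be >= 0, sigma > 0")
            if not self._inside_node(center):
                raise ValueError(f"focus centre {center} lies outside the node")

    def _inside_node(self, center_xyz) -> bool:
        nx, ny, nz = self.shape_xyz
        c = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
        rel = (np.asarray(center_xyz, float) - c) / np.asarray(self.semi_axes_voxels)
        return float(np.sum(rel**2)) <= 1.0


def build_truth_stack(spec: PhantomSpec):
    """Voxelise the phantom: (ActivityStack truth, list of per-focus masks).

    Activity is the uniform background inside the ellipsoid plus isotropic
    Gaussian foci; deterministic given the spec.  Focus masks cover 2σ around
    each focus centre (used as ground truth for hot-region recovery tests).
    """
    nx, ny, nz = spec.shape_xyz
    vx, vy, vz = spec.voxel_xyz_um
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    z, y, x = np.ogrid[:nz, :ny, :nx]
    ax, ay, az = spec.semi_axes_voxels
    inside = ((x - cx) ** 2 / ax**2 + (y - cy) ** 2 / ay**2
              + (z - cz) ** 2 / az**2) <= 1.0
    values = np.where(inside, spec.background_activity_Bq, 0.0)
    focus_masks = []
    for center, sigma_um, amp in spec.hot_foci:
        fx, fy, fz = center
        d2_um = (((x - fx) * vx) ** 2 + ((y - fy) * vy) ** 2
                 + ((z - fz) * vz) ** 2)
        values = values + inside * amp * np.exp(-0.5 * d2_um / sigma_um**2)
        focus_masks.append(inside & (d2_um <= (2.0 * sigma_um) ** 2))
    stack = ActivityStack(values, spec.voxel_xyz_um)
    return stack, focus_masks


def _tear_mask(shape_yx, rng):
    """Zeroed wedge (random half-plane through the centre) modelling a tear."""
    ny, nx = shape_yx
    theta = rng.uniform(0, 2 * np.pi)
    y, x = np.mgrid[:ny, :nx]
    return ((x - (nx - 1) / 2) * np.cos(theta)
            + (y - (ny - 1) / 2) * np.sin(theta)) > 0


def simulate_acquisition(truth: ActivityStack, config: AcquisitionConfig,
                         nuclide: NuclideData = AT211, seed: int = 0,
                         spec: PhantomSpec | None = None):
    """Simulate per-slice listmode acquisitions of a truth activity stack.

    Per voxel, the expected number of detections over [t_start, t_start+T] is
    ε·A·e^{−λ t_start}·(1 − e^{−λT})/λ; realised counts are Poisson, event
    times follow the truncated exponential (inverse-CDF sampling), and event
    positions are the voxel position, uniformly dithered within the voxel and
    blurred by the Gaussian detector PSF.  Each slice then receives its own
    rigid misalignment (rotation about the image centre plus translation);
    torn slices lose the events in a random wedge and are flagged.

    Returns (list of per-slice ListmodeData, manifest dict with the applied
    per-slice jitters and tear flags).
    """
    rng = np.random.default_rng(seed)
    lam = nuclide.decay_constant_per_s
    T = config.duration_s
    eps = config.efficiency
    fwhm_px = (spec.psf_fwhm_um if spec else 20.0) / config.pixel_size_um
    sigma_px = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rot_amp = spec.jitter_rotation_deg if spec else 0.0
    trans_amp = spec.jitter_translation_px if spec else 0.0
    torn = set(spec.torn_slices) if spec else set()

    nz, ny, nx = truth.values.shape
    slices, manifest = [], {"slices": []}
    decay_window = np.exp(-lam * config.t_start) * (1.0 - np.exp(-lam * T)) / lam
    for k in range(nz):
        mu = eps * truth.values[k] * decay_window
        counts = rng.poisson(mu)
        yy, xx = np.nonzero(counts)
        n_ev = counts[yy, xx]
        y0 = np.repeat(yy.astype(float), n_ev)
        x0 = np.repeat(xx.astype(float), n_ev)
        n_tot = y0.size
        u = rng.random(n_tot)
        t = -np.log(1.0 - u * (1.0 - np.exp(-lam * T))) / lam
        x_px = x0 + rng.random(n_tot) - 0.5 + rng.normal(0, sigma_px, n_tot)
        y_px = y0 + rng.random(n_tot) - 0.5 + rng.normal(0, sigma_px, n_tot)

        rot = rng.uniform(-rot_amp, rot_amp) if rot_amp else 0.0
        dx = rng.uniform(-trans_amp, trans_amp) if trans_amp else 0.0
        dy = rng.uniform(-trans_amp, trans_amp) if trans_amp else 0.0
        th = np.deg2rad(rot)
        cxp, cyp = (nx - 1) / 2, (ny - 1) / 2
        xr = np.cos(th) * (x_px - cxp) - np.sin(th) * (y_px - cyp) + cxp + dx
        yr = np.sin(th) * (x_px - cxp) + np.cos(th) * (y_px - cyp) + cyp + dy

        keep = (xr >= 0) & (xr < nx) & (yr >= 0) & (yr < ny)
        is_torn = k in torn
        if is_torn:
            wedge = _tear_mask((ny, nx), rng)
            ix = np.clip(np.floor(xr).astype(int), 0, nx - 1)
            iy = np.clip(np.floor(yr).astype(int), 0, ny - 1)
            keep &= ~wedge[iy, ix]
        xr, yr, t = xr[keep], yr[keep], t[keep]
        order = np.argsort(t, kind="stable")
        events = pd.DataFrame({
            "frame": np.floor(t[order] * config.frame_rate_hz).astype(int),
            "t_s": t[order],
            "x_px": xr[order],
            "y_px": yr[order],
            "area_px": np.full(order.size, 4, dtype=int),
            "intensity": np.ones(order.size),
        }, columns=LISTMODE_COLUMNS)
        slices.append(ListmodeData(events, config))
        manifest["slices"].append({
            "index": k, "rotation_deg": rot, "dx_px": dx, "dy_px": dy,
            "torn": is_torn, "n_events": int(order.size),
        })
    return slices, manifest


def render_pseudo_he(tissue_mask: np.ndarray, um_per_px: float,
                     scale: float = 1.0, rotation_deg: float = 0.0,
                     shear: float = 0.0, seed: int = 0):
    """Render a pseudo-H&E image of a tissue mask for fusion tests.

    The mask is upsampled by ``scale``, rotated/sheared, and painted as a
    pink-purple texture on a white background.  Returns (HistologyImage,
    ground-truth transform dict) so fusion recovery can be scored.
    """
    from skimage.transform import AffineTransform, rescale, warp

    rng = np.random.default_rng(seed)
    mask = np.asarray(tissue_mask, float)
    if scale != 1.0:
        mask = rescale(mask, scale, order=1, preserve_range=True,
                       anti_aliasing=scale < 1)
    ny, nx = mask.shape
    c = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])
    th = np.deg2rad(rotation_deg)
    lin = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) @ \
        np.array([[1.0, shear], [0.0, 1.0]])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = c - lin @ c
    tform = AffineTransform(matrix=m)
    warped = warp(mask, tform.inverse, order=1, preserve_range=True) >= 0.5

    rgb = np.full(warped.shape + (3,), 255, dtype=np.uint8)
    texture = 0.75 + 0.25 * rng.random(warped.shape)
    pink = np.array([199, 111, 160], dtype=float)
    for ch in range(3):
        band = 255 - (255 - pink[ch]) * texture
        rgb[..., ch] = np.where(warped, band.astype(np.uint8), 255)
    truth = {"scale": scale, "rotation_deg": rotation_deg, "shear": shear,
             "matrix": m}
    return HistologyImage(rgb, um_per_px), truth
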