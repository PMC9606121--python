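"""Co-registration of dose-rate maps with H&E-stained section images.

The H&E image and the autoradiograph show the same tissue at very different
pixel sizes.  Both are cast to binary masks — Otsu's threshold on the
(inverted-luminance) H&E, one-tenth of an Otsu threshold on the sparser
dose-rate map so the binary covers the whole tissue extent — brought to a
common µm/px scale using their pixel-size metadata, registered by coarse MSE
rotation search plus rigid refinement (optionally with a small shear, since
the stained section lies 50–100 µm away from the measured slice), and the
composite transform is mapped back to full-resolution H&E coordinates.  The
high-resolution H&E is processed at a 20× down-sample for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.measure import find_contours
from skimage.transform import AffineTransform, rescale, warp
from scipy import optimize

from .dosimetry import DoseRateMap
from .registration import RigidTransform2D, coarse_align
from .uniformity import RegionPartition

__all__ = [
    "HistologyImage",
    "FusionTransform",
    "otsu_binary",
    "iqid_binary",
    "fuse",
    "overlay_contours",
]


@dataclass
class HistologyImage:
    """RGB stained-section image with physical scale from its scale bar."""

    rgb: np.ndarray
    um_per_px: float
    stain: str = "H&E"

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def inverted_gray(self) -> np.ndarray:
        """Inverted luminance: tissue (darker than background) is foreground."""
        g = rgb2gray(self.rgb) if self.rgb.ndim == 3 else self.rgb.astype(float)
        return g.max() - g


@dataclass
class FusionTransform:
    """Composite map from dose-map pixel coords to full-resolution H&E coords."""

    scale: float                       # overall isotropic scale factor
    rigid: RigidTransform2D
    shear: float = 0.0
    reflect: bool = False
    matrix: np.ndarray = None          # 3×3 homogeneous, (x, y) convention
    dice: float = 0.0
    low_confidence: bool = False

    def __post_init__(self):
        if self.matrix is not None and abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("fusion transform is not invertible")


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance of the histogram."""
    counts, edges = np.histogram(values.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    omega0 = np.cumsum(w)
    mu = np.cumsum(w * centers)
    mu_t = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega0 - mu) ** 2 / (omega0 * omega1)
    between[~np.isfinite(between)] = -np.inf
    return float(centers[int(np.argmax(between))])


def otsu_binary(image: np.ndarray):
    """(threshold, mask) by Otsu's method over a 256-bin intensity histogram."""
    image = np.asarray(image, float)
    if np.unique(image).size < 2:
        raise ValueError("constant image has no Otsu threshold")
    thr = _otsu_threshold(image)
    return thr, image >= thr


def iqid_binary(dmap: DoseRateMap | np.ndarray) -> np.ndarray:
    """Binary mask of a dose-rate map at one-tenth of its Otsu threshold.

    The lower threshold captures the full spatial extent of the sparse map,
    so this mask always contains the plain-Otsu mask; scaling the map by a
    constant leaves the mask unchanged.
    """
    values = dmap.values if isinstance(dmap, DoseRateMap) else np.asarray(dmap, float)
    thr, _ = otsu_binary(values)
    return values >= thr / 10.0


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 0.0


def _affine_about_center(theta_deg, shear, tx, ty, center_xy):
    """Forward affine (rotation+shear about the centre, then translation)."""
    cx, cy = center_xy
    th = np.deg2rad(theta_deg)
    # same angle convention as registration._apply_rigid (row/col rotation)
    lin = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]) @ \
        np.array([[1.0, shear], [0.0, 1.0]])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = np.array([cx + tx, cy + ty]) - lin @ np.array([cx, cy])
    return AffineTransform(matrix=m)


def _warp_forward(image, tform, output_shape=None):
    return warp(image, tform.inverse, output_shape=output_shape, order=1,
                mode="constant", cval=0.0, preserve_range=True)


def _pad_offset(arr, shape):
    oy = (shape[0] - arr.shape[0]) // 2
    ox = (shape[1] - arr.shape[1]) // 2
    out = np.zeros(shape, dtype=float)
    out[oy:oy + arr.shape[0], ox:ox + arr.shape[1]] = arr
    return out, (ox, oy)


def fuse(iqid_map: DoseRateMap, hist: HistologyImage,
         allow_shear: bool = False, reflect: bool = False,
         downsample: int = 20, angle_step_deg: float = 1.0) -> FusionTransform:
    """Automatically co-register a dose-rate map with an H&E image.

    Threshold detection, scaling and 2-D transformations are computed on the
    20×-down-sampled H&E and composed back to full-resolution coordinates.
    ``reflect`` is a manual flag for face-down mounted slices (x-mirror of
    the dose map before registration).  A Dice overlap below 0.5 after
    registration sets ``low_confidence``.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    he_small = rescale(hist.inverted_gray, 1.0 / downsample,
                       anti_aliasing=True, preserve_range=True)
    _, he_bin = otsu_binary(he_small)
    target_um = hist.um_per_px * downsample

    mov = iqid_binary(iqid_map).astype(float)
    if reflect:
        mov = mov[:, ::-1]
    iqid_um = iqid_map.voxel_xyz_um[0]
    s = iqid_um / target_um
    mov_scaled = rescale(mov, s, anti_aliasing=s < 1, preserve_range=True)

    canvas = (max(he_bin.shape[0], mov_scaled.shape[0]),
              max(he_bin.shape[1], mov_scaled.shape[1]))
    ref, (rx, ry) = _pad_offset(he_bin.astype(float), canvas)
    movp, (mx, my) = _pad_offset(mov_scaled, canvas)

    theta0 = coarse_align(movp, ref, angle_step_deg)
    center = ((canvas[1] - 1) / 2.0, (canvas[0] - 1) / 2.0)

    def cost(params):
        th, tx, ty = params[:3]
        sh = params[3] if len(params) == 4 else 0.0
        t = _affine_about_center(th, sh, tx, ty, center)
        return float(np.mean((_warp_forward(movp, t) - ref) ** 2))

    x0 = [theta0, 0.0, 0.0]
    bounds = [(theta0 - 5, theta0 + 5),
              (-canvas[1] / 4, canvas[1] / 4), (-canvas[0] / 4, canvas[0] / 4)]
    res = optimize.minimize(cost, x0, method="Powell", bounds=bounds,
                            options={"xtol": 1e-4, "maxiter": 300})
    x = list(res.x)
    shear = 0.0
    if allow_shear:
        res2 = optimize.minimize(cost, x + [0.0], method="Powell",
                                 bounds=bounds + [(-0.2, 0.2)],
                                 options={"xtol": 1e-4, "maxiter": 300})
        if res2.fun <= res.fun:
            x, shear = list(res2.x[:3]), float(res2.x[3])

    t_common = _affine_about_center(x[0], shear, x[1], x[2], center)
    aligned = _warp_forward(movp, t_common) >= 0.5
    dice = _dice(aligned, ref >= 0.5)

    # compose: dose-map px -> (reflect) -> scale s -> pad -> rigid/shear on
    # common grid -> un-pad to H&E-small -> ×downsample to full resolution
    m_reflect = np.eye(3)
    if reflect:
        m_reflect[0, 0] = -1.0
        m_reflect[0, 2] = iqid_map.values.shape[-1] - 1.0
    m_scale = np.diag([s, s, 1.0])
    m_pad = np.eye(3)
    m_pad[:2, 2] = (mx, my)
    m_unpad = np.eye(3)
    m_unpad[:2, 2] = (-rx, -ry)
    m_up = np.diag([float(downsample), float(downsample), 1.0])
    matrix = m_up @ m_unpad @ t_common.params @ m_pad @ m_scale @ m_reflect
    rigid = RigidTransform2D(float(x[0]),
                             (float(x[1]) * downsample, float(x[2]) * downsample))
    return FusionTransform(scale=s * downsample, rigid=rigid, shear=shear,
                           reflect=reflect, matrix=matrix, dice=dice,
                           low_confidence=dice < 0.5)


def overlay_contours(hist: HistologyImage, partition: RegionPartition,
                     T: FusionTransform, region: str = "hot",
                     color=(255, 0, 0), scale_bar_mm: float = 1.0
                     ) -> np.ndarray:
    """Render region iso-contours from the dose map onto the H&E image.

    The region mask is warped into full-resolution H&E coordinates with the
    fusion transform, its 0.5-level contours are rasterised in ``color``, and
    a scale bar of ``scale_bar_mm`` is drawn in the lower-left corner.
    """
    he = hist.rgb.copy()
    if he.ndim == 2:
        he = np.stack([he] * 3, axis=-1)
    if he.dtype != np.uint8:
        he = (255 * np.clip(he, 0, 1)).astype(np.uint8) if he.max() <= 1 \
            else np.clip(he, 0, 255).astype(np.uint8)
    mask = partition.region_masks[region].astype(float)
    tform = AffineTransform(matrix=T.matrix)
    warped = _warp_forward(mask, tform, output_shape=he.shape[:2])
    if warped.max() < 0.5:
        raise ValueError("transform maps the region mask outside the H&E image")
    for contour in find_contours(warped, 0.5):
        rr = np.clip(np.round(contour[:, 0]).astype(int), 0, he.shape[0] - 1)
        cc = np.clip(np.round(contour[:, 1]).astype(int), 0, he.shape[1] - 1)
        he[rr, cc] = color
    bar_px = int(round(scale_bar_mm * 1000.0 / hist.um_per_px))
    if 0 < bar_px < he.shape[1] - 20:
        y = he.shape[0] - max(5, he.shape[0] // 40)
        he[y:y + max(2, he.shape[0] // 200), 10:10 + bar_px] = (0, 0, 0)
    return he
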