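"""Per-slice ROI segmentation and decay correction to activity at biopsy time.

A multi-slice autoradiograph contains several spatially separated tissue
slices imaged simultaneously.  Each slice is segmented into a region of
interest, its temporal count histogram is fit with a decaying exponential
(least squares), and the binned counts are converted to a per-pixel activity
snapshot (Bq) at the biopsy reference time using the fitted decay constant
and the detection efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk

from .listmode import AcquisitionConfig

__all__ = [
    "DecayFit",
    "ActivityImage",
    "segment_rois",
    "fit_decay",
    "decay_correct",
]


@dataclass
class DecayFit:
    """Fitted exponential decay of the temporal count histogram."""

    rate_per_s: float
    amplitude: float
    residual_norm: float
    physical: bool = True  # False when best-fit rate <= 0

    @property
    def half_life_h(self) -> float:
        return float(np.log(2.0) / self.rate_per_s / 3600.0)


@dataclass
class ActivityImage:
    """2-D activity map (Bq per pixel) of one tissue slice at biopsy time."""

    values: np.ndarray
    pixel_size_um: float
    slice_thickness_um: float = 12.0
    t_ref: float = 0.0
    roi_id: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def total_Bq(self) -> float:
        return float(self.values.sum())


def segment_rois(image: np.ndarray, expected_n=None, min_area_fraction=0.001,
                 smooth_sigma_px: float = 2.0):
    """Segment a counts image into per-slice ROI masks in reading order.

    Gaussian smooth -> Otsu threshold on non-zero pixels -> morphological
    closing and hole fill -> connected components -> drop small components ->
    sort row-major by centroid (ties by x).  Returns a list of boolean masks;
    raises when fewer than ``expected_n`` components survive.
    """
    image = np.asarray(image, dtype=float)
    smooth = gaussian(image, sigma=smooth_sigma_px, preserve_range=True)
    nonzero = smooth[smooth > 0]
    if nonzero.size == 0:
        masks = []
    else:
        thr = threshold_otsu(nonzero) if np.unique(nonzero).size > 1 else nonzero[0]
        mask = smooth >= thr
        mask = ndimage.binary_closing(mask, structure=disk(2))
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask)
        masks = []
        min_area = min_area_fraction * image.size
        for i in range(1, n + 1):
            m = labels == i
            if m.sum() >= min_area:
                masks.append(m)
    if expected_n is not None and len(masks) < expected_n:
        raise ValueError(
            f"segmentation shortfall: found {len(masks)} ROIs, "
            f"expected {expected_n}"
        )

    def _key(m):
        cy, cx = ndimage.center_of_mass(m)
        return (round(cy / max(1, m.shape[0] // 8)), cx, cy)

    masks.sort(key=_key)
    if expected_n is not None:
        masks = sorted(masks, key=lambda m: m.sum(), reverse=True)[:expected_n]
        masks.sort(key=_key)
    return masks


def fit_decay(bin_centers_s: np.ndarray, counts: np.ndarray,
              fixed_half_life_h: float | None = None) -> DecayFit:
    """Least-squares fit of counts = amplitude * exp(-rate * t).

    With ``fixed_half_life_h`` only the amplitude is fitted (analytic
    weighted projection).  A non-decaying best fit (rate <= 0) is returned
    with ``physical=False`` and a warning.
    """
    t = np.asarray(bin_centers_s, dtype=float)
    c = np.asarray(counts, dtype=float)
    nonempty = np.count_nonzero(c > 0)
    if fixed_half_life_h is not None:
        if nonempty < 1:
            raise ValueError("need at least 1 non-empty bin with fixed half-life")
        rate = np.log(2.0) / (fixed_half_life_h * 3600.0)
        basis = np.exp(-rate * t)
        amp = float(np.dot(c, basis) / np.dot(basis, basis))
        resid = float(np.sum((c - amp * basis) ** 2))
        return DecayFit(rate, amp, resid)
    if nonempty < 3:
        raise ValueError("need at least 3 non-empty bins to fit rate and amplitude")
    # log-linear initial guess on positive bins
    pos = c > 0
    slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 1e-12)))
    try:
        popt, _ = curve_fit(lambda tt, a, lam: a * np.exp(-lam * tt), t, c,
                            p0=p0, maxfev=20000)
        amp, rate = float(popt[0]), float(popt[1])
    except RuntimeError:
        amp, rate = p0
    resid = float(np.sum((c - amp * np.exp(-rate * t)) ** 2))
    t_span = float(t.max() - t.min()) or 1.0
    if rate * t_span < 1e-6:  # no measurable decay over the window
        warnings.warn("non-decaying temporal histogram: fitted rate <= 0",
                      stacklevel=2)
        return DecayFit(rate if rate > 0 else 1e-300, amp, resid,
                        physical=False)
    return DecayFit(rate, amp, resid)


def decay_correct(counts: np.ndarray, fit: DecayFit,
                  config: AcquisitionConfig, roi_id: int = 0,
                  slice_thickness_um: float = 12.0) -> ActivityImage:
    """Convert a per-pixel counts image to activity (Bq) at the reference time.

    For counts N accumulated over [t_start, t_start + T] (relative to the
    reference time) with decay constant λ and detection efficiency ε,

        A = N · λ · exp(λ t_start) / (ε · (1 − exp(−λ T)))

    which inverts both the decay during acquisition and the detected
    fraction.  Linear in counts and in 1/ε.
    """
    T = config.duration_s
    eps = config.efficiency
    if T <= 0:
        raise ValueError("acquisition duration must be positive")
    if not (0.0 < eps <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    lam = fit.rate_per_s
    scale = lam * np.exp(lam * config.t_start) / (eps * (1.0 - np.exp(-lam * T)))
    values = np.asarray(counts, dtype=float) * scale
    return ActivityImage(values, config.pixel_size_um,
                         slice_thickness_um=slice_thickness_um,
                         t_ref=config.t_ref, roi_id=roi_id)
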