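"""Rigid registration of consecutive slice activity images into a 3-D stack.

Each thin (12 µm) cryosection is treated as a minimally distorted 2-D rigid
transformation of its neighbour.  Orientation is found coarsely by scanning
rotation angles for minimum mean-squared error between intensities, then a
rigid-body (rotation + translation) refinement polishes the alignment.
Bilinear interpolation slightly redistributes activity, so each transformed
slice is rescaled by a recorded scalar compensation factor that restores its
cumulative activity exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .activity import ActivityImage

__all__ = [
    "RigidTransform2D",
    "ActivityStack",
    "coarse_align",
    "refine_rigid",
    "apply_with_compensation",
    "register_stack",
    "repair_stack",
]


@dataclass
class RigidTransform2D:
    """Rotation (degrees, about ``center_px``) followed by translation (px)."""

    rotation_deg: float = 0.0
    translation_px: tuple = (0.0, 0.0)  # (dx, dy)
    center_px: tuple | None = None      # (cx, cy); default image centre

    def inverse(self) -> "RigidTransform2D":
        th = np.deg2rad(self.rotation_deg)
        dx, dy = self.translation_px
        # inverse of x' = R(x - c) + c + t is rotation by -θ with t' = -Rᵀt
        idx = -(np.cos(th) * dx - np.sin(th) * dy)
        idy = -(np.sin(th) * dx + np.cos(th) * dy)
        return RigidTransform2D(-self.rotation_deg, (idx, idy), self.center_px)


def _apply_rigid(image: np.ndarray, T: RigidTransform2D) -> np.ndarray:
    """Warp with bilinear interpolation; out-of-canvas fill is 0."""
    ny, nx = image.shape
    cy = (ny - 1) / 2.0 if T.center_px is None else T.center_px[1]
    cx = (nx - 1) / 2.0 if T.center_px is None else T.center_px[0]
    th = np.deg2rad(T.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # output (y, x) samples input at R^{-1}((p - c - t)) + c
    dx, dy = T.translation_px
    offset_vec = np.array([cy + dy, cx + dx])
    matrix = rot.T  # inverse rotation, (row, col) ordering
    offset = np.array([cy, cx]) - matrix @ offset_vec
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def coarse_align(moving: np.ndarray, reference: np.ndarray,
                 angle_step_deg: float = 1.0) -> float:
    """Rotation angle in [-180, 180) minimising MSE against the reference.

    Exhaustive scan at ``angle_step_deg`` granularity; ties broken by the
    smallest absolute angle.
    """
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)
    if moving.shape != reference.shape:
        raise ValueError("images must share a shape")
    if moving.max() == 0 or reference.max() == 0:
        raise ValueError("degenerate alignment: all-zero image")
    angles = np.arange(-180.0, 180.0, angle_step_deg)
    # evaluate smallest |angle| first so argmin tie-break keeps it
    angles = angles[np.argsort(np.abs(angles), kind="stable")]
    costs = [
        _mse(_apply_rigid(moving, RigidTransform2D(a)), reference)
        for a in angles
    ]
    return float(angles[int(np.argmin(costs))])


def refine_rigid(moving: np.ndarray, reference: np.ndarray,
                 init_rotation_deg: float = 0.0,
                 max_rotation_window_deg: float = 5.0) -> RigidTransform2D:
    """Iterative rigid-body refinement of (θ, dx, dy) from a coarse angle.

    Multi-resolution (2× pyramid then full resolution) Powell minimisation of
    the intensity MSE with bilinear warps.  Guaranteed not to be worse than
    the initial angle; sets ``converged=False`` on optimiser failure.
    """
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)

    def cost_at(params, mov, ref, scale):
        th, dx, dy = params
        T = RigidTransform2D(th, (dx * scale, dy * scale))
        return _mse(_apply_rigid(mov, T), ref)

    x0 = np.array([init_rotation_deg, 0.0, 0.0])
    converged = True
    levels = []
    if min(moving.shape) >= 32:
        levels.append((ndimage.zoom(moving, 0.5, order=1),
                       ndimage.zoom(reference, 0.5, order=1), 0.5))
    levels.append((moving, reference, 1.0))
    x = x0.copy()
    for mov, ref, scale in levels:
        res = optimize.minimize(
            cost_at, np.array([x[0], x[1] / (1.0 / scale), x[2] / (1.0 / scale)]),
            args=(mov, ref, 1.0), method="Powell",
            bounds=[(init_rotation_deg - max_rotation_window_deg,
                     init_rotation_deg + max_rotation_window_deg),
                    (-mov.shape[1] / 4, mov.shape[1] / 4),
                    (-mov.shape[0] / 4, mov.shape[0] / 4)],
            options={"xtol": 1e-4, "ftol": 1e-10, "maxiter": 200})
        converged &= bool(res.success)
        x = np.array([res.x[0], res.x[1] / scale, res.x[2] / scale])
    final = RigidTransform2D(float(x[0]), (float(x[1]), float(x[2])))
    if cost_at([x[0], x[1], x[2]], moving, reference, 1.0) > cost_at(
            [init_rotation_deg, 0, 0], moving, reference, 1.0):
        final = RigidTransform2D(init_rotation_deg, (0.0, 0.0))
    final.converged = converged
    return final


def apply_with_compensation(image: ActivityImage | np.ndarray,
                            T: RigidTransform2D):
    """Apply a rigid transform and rescale so cumulative activity is exact.

    Returns (transformed array or ActivityImage, compensation scalar), where
    compensation = Σ(before)/Σ(after interpolation); the returned image is
    multiplied by it, so interpolation-induced activity error is removed.
    """
    arr = image.values if isinstance(image, ActivityImage) else np.asarray(image, float)
    before = float(arr.sum())
    if before <= 0:
        raise ValueError("cannot compensate an image with non-positive total")
    out = _apply_rigid(arr, T)
    np.clip(out, 0.0, None, out=out)
    after = float(out.sum())
    if after == 0:
        raise ValueError("transform moved all activity off the canvas")
    comp = before / after
    out *= comp
    if isinstance(image, ActivityImage):
        out = ActivityImage(out, image.pixel_size_um,
                            slice_thickness_um=image.slice_thickness_um,
                            t_ref=image.t_ref, roi_id=image.roi_id)
    return out, comp


@dataclass
class ActivityStack:
    """Registered 3-D activity volume (z = slice index), Bq per voxel."""

    values: np.ndarray
    voxel_xyz_um: tuple
    t_ref: float = 0.0
    transforms: list = field(default_factory=list)
    compensation_factors: list = field(default_factory=list)
    replaced_slices: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stack values must be 3-D (z, y, x)")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def total_Bq(self) -> float:
        return float(self.values.sum())


def _pad_to(arr: np.ndarray, shape) -> np.ndarray:
    """Centre-pad with zeros to a common canvas."""
    out = np.zeros(shape, dtype=arr.dtype)
    oy = (shape[0] - arr.shape[0]) // 2
    ox = (shape[1] - arr.shape[1]) // 2
    out[oy:oy + arr.shape[0], ox:ox + arr.shape[1]] = arr
    return out


def register_stack(images: list, angle_step_deg: float = 1.0,
                   pad_px: int = 0, enforce_odd: bool = False) -> ActivityStack:
    """Chain-register ordered slice images into an ActivityStack.

    Slice 0 is fixed; each subsequent slice is aligned to the *transformed*
    previous slice by coarse MSE rotation search plus rigid refinement, then
    rescaled by its compensation factor.  All slices are zero-padded to a
    common canvas (plus ``pad_px`` on each side) first.  With
    ``enforce_odd=True`` an even slice count is reduced by dropping the last
    slice (a symmetric central slice is required for central-slice dosimetry).
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    arrays = [im.values if isinstance(im, ActivityImage) else np.asarray(im, float)
              for im in images]
    pixel = images[0].pixel_size_um if isinstance(images[0], ActivityImage) else 1.0
    thickness = (images[0].slice_thickness_um
                 if isinstance(images[0], ActivityImage) else 12.0)
    t_ref = images[0].t_ref if isinstance(images[0], ActivityImage) else 0.0
    if enforce_odd and len(arrays) % 2 == 0:
        warnings.warn("dropping last slice to obtain an odd slice count",
                      stacklevel=2)
        arrays = arrays[:-1]
    canvas = (max(a.shape[0] for a in arrays) + 2 * pad_px,
              max(a.shape[1] for a in arrays) + 2 * pad_px)
    arrays = [_pad_to(a, canvas) for a in arrays]

    out = np.empty((len(arrays),) + canvas)
    transforms = [RigidTransform2D()]
    comps = [1.0]
    out[0] = arrays[0]
    for k in range(1, len(arrays)):
        ref = out[k - 1]
        if arrays[k].max() == 0 or ref.max() == 0:
            # nothing to align (empty slice or empty reference): keep as-is
            out[k] = arrays[k]
            transforms.append(RigidTransform2D())
            comps.append(1.0)
            continue
        theta0 = coarse_align(arrays[k], ref, angle_step_deg)
        T = refine_rigid(arrays[k], ref, theta0)
        moved, comp = apply_with_compensation(arrays[k], T)
        out[k] = moved
        transforms.append(T)
        comps.append(comp)
    return ActivityStack(out, (pixel, pixel, thickness), t_ref=t_ref,
                         transforms=transforms, compensation_factors=comps)


def repair_stack(stack: ActivityStack, bad_indices) -> ActivityStack:
    """Replace torn/discarded slices by copies of their nearest good neighbour.

    Ties between equidistant good neighbours go to the lower index.  The
    replaced indices are recorded in ``replaced_slices``.
    """
    bad = sorted(set(int(i) for i in bad_indices))
    n = stack.n_slices
    if any(i < 0 or i >= n for i in bad):
        raise IndexError("bad slice index outside stack")
    good = [i for i in range(n) if i not in bad]
    if not good:
        raise ValueError("all slices are bad; stack is unrecoverable")
    values = stack.values.copy()
    replacements = []
    for i in bad:
        j = min(good, key=lambda g: (abs(g - i), g))
        values[i] = stack.values[j]
        replacements.append((i, j))
    return ActivityStack(values, stack.voxel_xyz_um, t_ref=stack.t_ref,
                         transforms=list(stack.transforms),
                         compensation_factors=list(stack.compensation_factors),
                         replaced_slices=stack.replaced_slices + replacements)
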