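"""File formats: float32 multi-page TIFF + JSON sidecars, listmode CSV.

Every on-disk artifact carries its units and geometry in a JSON sidecar next
to the image file; readers refuse files whose sidecar is missing and validate
integrity fields (the kernel's total energy) on load.  Arrays round-trip
bitwise at float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dosimetry import DoseRateMap
from .kernel import DoseKernel
from .listmode import LISTMODE_COLUMNS, AcquisitionConfig, ListmodeData
from .registration import ActivityStack, RigidTransform2D

__all__ = [
    "write_image", "read_image",
    "write_kernel", "read_kernel",
    "write_stack", "read_stack",
    "write_dose_map", "read_dose_map",
    "write_listmode", "read_listmode",
]


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_image(path, array: np.ndarray, sidecar: dict) -> None:
    arr = np.asarray(array, dtype=np.float32)
    pages = arr if arr.ndim == 3 else arr[None]
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, RigidTransform2D):
        return {"rotation_deg": obj.rotation_deg,
                "translation_px": list(obj.translation_px)}
    raise TypeError(f"cannot serialise {type(obj)}")


def read_image(path):
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sc}; images must carry their metadata"
        )
    arr = tifffile.imread(str(path))
    with open(sc) as fh:
        sidecar = json.load(fh)
    return np.asarray(arr), sidecar


def write_kernel(path, kernel: DoseKernel) -> None:
    sidecar = {
        "kind": "dose_kernel",
        "units": "MeV_per_emission",
        "voxel_xyz_um": list(kernel.voxel_xyz_um),
        "n_events": kernel.n_events,
        "total_MeV": kernel.total_MeV,
        "provenance": kernel.provenance,
    }
    write_image(path, kernel.values, sidecar)
    unc = Path(path).with_name(Path(path).stem + "_relunc" + Path(path).suffix)
    tifffile.imwrite(str(unc), kernel.rel_uncertainty.astype(np.float32),
                     photometric="minisblack")


def read_kernel(path) -> DoseKernel:
    values, sidecar = read_image(path)
    values = values.astype(float)
    total = float(values.sum())
    stated = sidecar.get("total_MeV")
    if stated is not None and abs(total - stated) > 1e-4 * max(abs(stated), 1.0):
        raise ValueError(
            f"kernel total {total} MeV does not match sidecar {stated} MeV"
        )
    unc_path = Path(path).with_name(
        Path(path).stem + "_relunc" + Path(path).suffix)
    rel = (tifffile.imread(str(unc_path)).astype(float)
           if unc_path.exists() else np.zeros_like(values))
    return DoseKernel(values, tuple(sidecar["voxel_xyz_um"]),
                      int(sidecar["n_events"]), rel,
                      sidecar.get("provenance", {}))


def write_stack(path, stack: ActivityStack) -> None:
    sidecar = {
        "kind": "activity_stack",
        "units": "Bq_per_voxel",
        "voxel_xyz_um": list(stack.voxel_xyz_um),
        "t_ref": stack.t_ref,
        "transforms": [_jsonify(t) if isinstance(t, RigidTransform2D) else t
                       for t in stack.transforms],
        "compensation_factors": list(stack.compensation_factors),
        "replaced_slices": [list(p) for p in stack.replaced_slices],
    }
    write_image(path, stack.values, sidecar)


def read_stack(path) -> ActivityStack:
    values, sidecar = read_image(path)
    transforms = [
        RigidTransform2D(t["rotation_deg"], tuple(t["translation_px"]))
        for t in sidecar.get("transforms", [])
    ]
    return ActivityStack(values.astype(float),
                         tuple(sidecar["voxel_xyz_um"]),
                         t_ref=sidecar.get("t_ref", 0.0),
                         transforms=transforms,
                         compensation_factors=sidecar.get(
                             "compensation_factors", []),
                         replaced_slices=[tuple(p) for p in
                                          sidecar.get("replaced_slices", [])])


def write_dose_map(path, dmap: DoseRateMap) -> None:
    sidecar = {
        "kind": "dose_rate_map",
        "units": "mGy/h",
        "voxel_xyz_um": list(dmap.voxel_xyz_um),
        "t_ref": dmap.t_ref,
        "provenance": dmap.provenance,
    }
    write_image(path, dmap.values, sidecar)


def read_dose_map(path) -> DoseRateMap:
    values, sidecar = read_image(path)
    if sidecar.get("units") != "mGy/h":
        raise ValueError(f"unit mismatch: expected mGy/h, got {sidecar.get('units')}")
    shape = values.shape
    if shape[0] == 1:
        values = values[0]
    return DoseRateMap(values.astype(float), tuple(sidecar["voxel_xyz_um"]),
                       t_ref=sidecar.get("t_ref", 0.0),
                       provenance=sidecar.get("provenance", {}))


def write_listmode(path, lm: ListmodeData) -> None:
    lm.events.to_csv(path, index=False, columns=LISTMODE_COLUMNS)
    cfg = {
        "pixel_size_um": lm.config.pixel_size_um,
        "frame_rate_hz": lm.config.frame_rate_hz,
        "efficiency": lm.config.efficiency,
        "t_ref": lm.config.t_ref,
        "t_start": lm.config.t_start,
        "duration_s": lm.config.duration_s,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(cfg, fh, indent=1)


def read_listmode(path) -> ListmodeData:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing acquisition sidecar {sc}")
    events = pd.read_csv(path)
    with open(sc) as fh:
        cfg = AcquisitionConfig(**json.load(fh))
    return ListmodeData(events, cfg)
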