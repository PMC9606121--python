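"""Batch pipeline: listmode → activity → registration → dose → uniformity.

``run_pipeline`` executes the full processing chain the way the batch
dosimetry runs are performed — from per-slice event data (measured CSVs or a
simulated phantom acquisition) through decay correction, stack registration,
kernel convolution and σ-partition analysis — writing every intermediate
with its JSON sidecar plus a manifest with seeds and checksums, so a run is
reproducible and idempotent given the same inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as adio
from .activity import decay_correct, fit_decay
from .dosimetry import MediumModel, central_slice, convolve_dose_rate
from .kernel import generate_kernel, radial_average, rebin_kernel
from .listmode import AcquisitionConfig, bin_spatial, bin_temporal
from .phantom import PhantomSpec, build_truth_stack, simulate_acquisition
from .physics import AT211, load_water_stopping_power
from .registration import register_stack, repair_stack
from .uniformity import dose_rate_area_histogram, partition_by_sigma, tissue_mask

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one batch run; all units explicit."""

    out_dir: str = "alphadose_run"
    seed: int = 0
    # input: either a list of per-slice listmode CSVs, or simulate a phantom
    listmode_files: list = field(default_factory=list)
    simulate: bool = True
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    # decay correction
    fixed_half_life_h: float | None = None
    temporal_bin_s: float = 600.0
    # registration
    angle_step_deg: float = 1.0
    bad_slices: list = field(default_factory=list)
    # kernel
    kernel_file: str | None = None
    kernel_n_events: int = 200_000
    kernel_voxel_um: float = 1.0
    kernel_half_extent_um: float = 75.0
    density_g_per_cm3: float = 1.0


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and return the manifest dict.

    Stage failures raise with the stage name; artifacts of completed stages
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "artifacts": {}}
    rng_seed = int(config.seed)

    # --- stage: input events -------------------------------------------------
    bad = list(config.bad_slices)
    if config.simulate:
        truth, _ = build_truth_stack(config.phantom)
        slices_lm, sim_manifest = simulate_acquisition(
            truth, config.acquisition, AT211, seed=rng_seed,
            spec=config.phantom)
        bad += [s["index"] for s in sim_manifest["slices"] if s["torn"]]
        grid = truth.values.shape[1:]
        manifest["simulated"] = sim_manifest
    else:
        if not config.listmode_files:
            raise ValueError("stage input: no listmode files and simulate=False")
        slices_lm = [adio.read_listmode(p) for p in config.listmode_files]
        extent = max(
            max(lm.events["x_px"].max(), lm.events["y_px"].max())
            for lm in slices_lm if lm.n_events
        )
        grid = (int(np.ceil(extent)) + 1,) * 2
    manifest["stages"].append("input")

    # --- stage: activity -----------------------------------------------------
    images = []
    for k, lm in enumerate(slices_lm):
        counts = bin_spatial(lm, grid)
        if lm.n_events == 0:
            from .activity import ActivityImage
            img = ActivityImage(np.zeros(grid), lm.config.pixel_size_um,
                                t_ref=lm.config.t_ref, roi_id=k)
            fit = None
        else:
            centers, hist = bin_temporal(lm, config.temporal_bin_s)
            try:
                fit = fit_decay(centers, hist,
                                fixed_half_life_h=config.fixed_half_life_h)
            except ValueError:
                # too few counts to fit a rate: fall back to the nuclide λ
                fit = fit_decay(centers, hist,
                                fixed_half_life_h=AT211.half_life_h)
            img = decay_correct(counts, fit, lm.config, roi_id=k)
        images.append(img)
        adio.write_image(out / f"activity_{k:03d}.tif", img.values, {
            "kind": "activity_image", "units": "Bq_per_pixel",
            "pixel_size_um": img.pixel_size_um,
            "slice_thickness_um": img.slice_thickness_um,
            "t_ref": img.t_ref, "roi_id": k,
            "fit_half_life_h": fit.half_life_h if fit else None,
        })
    manifest["stages"].append("activity")

    # --- stage: registration -------------------------------------------------
    stack = register_stack(images, angle_step_deg=config.angle_step_deg,
                           enforce_odd=True)
    if bad:
        stack = repair_stack(stack, [b for b in bad if b < stack.n_slices])
    adio.write_stack(out / "stack.tif", stack)
    manifest["stages"].append("registration")

    # --- stage: kernel -------------------------------------------------------
    if config.kernel_file:
        kern = adio.read_kernel(config.kernel_file)
    else:
        kern = generate_kernel(AT211, load_water_stopping_power(),
                               config.kernel_n_events,
                               voxel_um=config.kernel_voxel_um,
                               half_extent_um=config.kernel_half_extent_um,
                               seed=rng_seed)
        kern = radial_average(kern)
    kern_binned = rebin_kernel(kern, stack.voxel_xyz_um[0],
                               stack.voxel_xyz_um[2])
    adio.write_kernel(out / "kernel.tif", kern_binned)
    manifest["stages"].append("kernel")

    # --- stage: dose ---------------------------------------------------------
    medium = MediumModel(config.density_g_per_cm3)
    dmap = convolve_dose_rate(stack, kern_binned, medium)
    adio.write_dose_map(out / "dose_rate.tif", dmap)
    central = central_slice(dmap)
    adio.write_dose_map(out / "dose_rate_central.tif", central)
    manifest["stages"].append("dose")

    # --- stage: uniformity ---------------------------------------------------
    mask = tissue_mask(central)
    part = partition_by_sigma(central, mask)
    hist = dose_rate_area_histogram(central, mask)
    report = {
        "mean_mGy_per_h": part.mean,
        "sigma_mGy_per_h": part.sigma,
        "area_fractions": part.area_fractions,
        "region_means_mGy_per_h": part.region_means,
        "central_slice_total_mGy_per_h": float(central.values.sum()),
        "total_area_mm2": hist["total_area_mm2"],
    }
    with open(out / "uniformity.json", "w") as fh:
        json.dump(report, fh, indent=1)
    manifest["stages"].append("uniformity")

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _checksum(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
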