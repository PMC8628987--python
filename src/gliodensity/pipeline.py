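"""One-command end-to-end phantom pipeline.

Stage order: phantom labels -> geodesic distance map -> imposed cell
density -> nuclei slides -> tile density maps -> distance/density pairs ->
decay-model fits -> edema-outline analyses.  Every stochastic stage draws
its own child seed from the master seed through a fixed counter scheme
(``SeedSequence([master_seed, stage_counter])``), so a run is reproducible
end to end and no stage reuses another stage's stream.

Distance/density pairs can come from two sources: ``histology`` walks the
full slide route (Poisson nuclei -> tiles -> registered voxels; both
surface- and volume-flavor fits), while ``imposed`` samples the imposed
density field directly at white voxels (volume flavor only) — the route
with no sampling noise, under which a noiseless run recovers its generating
parameters essentially exactly.  ``auto`` uses histology when the slide
plan is non-empty.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .edema import boundary_distance_icdf, boundary_voxels, threshold_scan
from .errors import ConfigurationError
from .geodesics import geodesic_distance
from .grids import ScalarVolume, TissueLabelVolume
from .histology import compute_surface_density_map, register_map_to_grid, surface_to_volume
from .infiltration import DecayModelParams, collect_pairs, fit_decay_model
from .phantom import impose_infiltration_profile, make_brain_phantom, make_edema_mask, sample_nuclei_slide

__all__ = ["PipelineConfig", "run_pipeline", "default_slide_plan"]

# stage counters of the seed scheme (documented, never reused)
STAGE_SEEDS = {"phantom": 0, "density_noise": 1, "slides": 2, "edema": 3}


@dataclass
class PipelineConfig:
    """Parameters of one end-to-end phantom run (all units mm / day / cell/mm^3)."""

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 0.5
    core_radius_mm: float = 5.0
    # generating decay model (volume flavor); defaults are the fitted
    # whole-brain values the study conditions prescribe
    c_core: float = 1.05e5
    lambda_white: float = 8.46
    c_white: float = 0.59e5
    noise_cv: float = 0.2
    gray_factor: float = 1.5
    # slide plan: (slice_index, (j0, j1, k0, k1)) windows; empty => imposed pairs
    slide_plan: list = field(default_factory=list)
    pair_source: str = "auto"  # auto | histology | imposed
    edema_mode: str = "perturbed"  # iso | perturbed
    edema_threshold_mm: float = 20.0
    perturb_amp_mm: float = 10.0
    perturb_scale_mm: float = 15.0
    scan_t_min: float = 1.0
    scan_t_max: float | None = None
    scan_step: float = 0.5
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.pair_source not in ("auto", "histology", "imposed"):
            raise ConfigurationError(f"unknown pair_source {self.pair_source!r}")
        if self.edema_mode not in ("iso", "perturbed"):
            raise ConfigurationError(f"unknown edema_mode {self.edema_mode!r}")
        if self.noise_cv < 0 or self.scan_step <= 0 or self.edema_threshold_mm <= 0:
            raise ConfigurationError("invalid pipeline parameter")
        DecayModelParams(self.c_core, self.lambda_white, self.c_white, "volume").validate()
        if self.pair_source == "histology" and not self.slide_plan:
            raise ConfigurationError("histology pair source needs a non-empty slide plan")
        return self

    def stage_seed(self, stage: str, offset: int = 0) -> int:
        ss = np.random.SeedSequence([int(self.seed), STAGE_SEEDS[stage], offset])
        return int(ss.generate_state(1)[0] % (2**31))


def default_slide_plan(
    shape: tuple[int, int, int] = (96, 96, 96),
    half_width_vox: int = 8,
) -> list:
    """Six slides through the tumor hemisphere, the bridge and beyond,
    each a (2*half_width)^2-voxel window centered in-plane."""
    nx, ny, nz = shape
    jc, kc = ny // 2, nz // 2
    window = (jc - half_width_vox, jc + half_width_vox, kc - half_width_vox, kc + half_width_vox)
    # from the core hemisphere across the bridge into the contralateral side
    xs = [int(nx * f) for f in (0.26, 0.34, 0.42, 0.52, 0.70, 0.82)]
    return [(x, window) for x in xs]


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return (and optionally write) the results.

    Returns a dict with the phantom, distance map, density field, pairs,
    fit results, edema analyses and a manifest carrying version, per-stage
    seeds and per-stage array checksums.
    """
    config.validate()
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    labels = make_brain_phantom(
        config.shape, config.voxel_size, config.core_radius_mm, seed=config.stage_seed("phantom")
    )
    manifest["stages"]["phantom"] = {"checksum": _sha(labels.labels)}

    white = labels.white_mask
    core = labels.core_mask
    distance = geodesic_distance(core, white, grid=labels.grid)
    d_hash = distance.values.copy()
    d_hash[np.isinf(d_hash)] = -1.0
    manifest["stages"]["distance"] = {
        "checksum": _sha(d_hash),
        "max_finite_mm": float(np.nanmax(np.where(np.isfinite(distance.values), distance.values, np.nan))),
    }

    truth = DecayModelParams(config.c_core, config.lambda_white, config.c_white, "volume")
    density = impose_infiltration_profile(
        labels, distance, truth, noise_cv=config.noise_cv,
        seed=config.stage_seed("density_noise"), gray_factor=config.gray_factor,
    )
    manifest["stages"]["density"] = {"checksum": _sha(np.nan_to_num(density.values, nan=-1.0))}

    source = config.pair_source
    if source == "auto":
        source = "histology" if config.slide_plan else "imposed"

    fits = {}
    slides_out = []
    if source == "histology":
        surface_samples = np.full(labels.grid.shape, np.nan)
        volume_samples = np.full(labels.grid.shape, np.nan)
        for i, (slice_index, window) in enumerate(config.slide_plan):
            slide = sample_nuclei_slide(
                density, labels, slice_index, window,
                seed=config.stage_seed("slides", i), slide_id=i,
            )
            smap = compute_surface_density_map(slide)
            surf_slice = register_map_to_grid(smap, labels)
            vmap = smap
            vmap_vals = surface_to_volume(np.where(np.isfinite(smap.values), smap.values, np.nan))
            vmap = type(smap)(
                slide_id=smap.slide_id, slice_index=smap.slice_index,
                extent_vox=smap.extent_vox, values=vmap_vals,
                tissue_area=smap.tissue_area, voxel_size_mm=smap.voxel_size_mm,
            )
            vol_slice = register_map_to_grid(vmap, labels)
            surface_samples[slice_index] = np.where(np.isfinite(surf_slice), surf_slice, surface_samples[slice_index])
            volume_samples[slice_index] = np.where(np.isfinite(vol_slice), vol_slice, volume_samples[slice_index])
            slides_out.append(slide)
        surf_pairs = collect_pairs(surface_samples, distance, white)
        vol_pairs = collect_pairs(volume_samples, distance, white)
        fits["surface"] = fit_decay_model(surf_pairs, flavor="surface")
        fits["volume"] = fit_decay_model(vol_pairs, flavor="volume")
        pairs = vol_pairs
    else:
        pairs = collect_pairs(density, distance, white)
        fits["volume"] = fit_decay_model(pairs, flavor="volume")
    manifest["stages"]["fit"] = {
        flavor: {"checksum": _sha(np.array(list(fr.params.as_dict().values())[:3], float)), **fr.as_dict()}
        for flavor, fr in fits.items()
    }

    edema = make_edema_mask(
        distance, config.edema_mode, config.edema_threshold_mm,
        config.perturb_amp_mm, config.perturb_scale_mm, seed=config.stage_seed("edema"),
    )
    domain = white | core
    edema_boundary = boundary_voxels(edema.mask, labels.grid, domain=domain)
    icdf = boundary_distance_icdf(edema_boundary, distance)
    scan = threshold_scan(
        distance, edema.mask, config.scan_t_min, config.scan_t_max, config.scan_step, domain=domain
    )
    manifest["stages"]["edema"] = {
        "checksum": _sha(edema.mask),
        "mode": edema.mode,
        "icdf_quantiles": icdf["quantiles"],
        "icdf_range_mm": icdf["range_mm"],
        "best_t_hausdorff": scan.best_t_hausdorff,
        "best_t_assd": scan.best_t_assd,
        "min_hausdorff": scan.min_hausdorff,
        "min_assd": scan.min_assd,
    }

    results = {
        "labels": labels,
        "distance": distance,
        "density": density,
        "slides": slides_out,
        "pairs": pairs,
        "fits": fits,
        "edema": edema,
        "icdf": icdf,
        "scan": scan,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_run(results, Path(out_dir))
    return results


def _write_run(results: dict, out_dir: Path) -> None:
    import pandas as pd

    from .io import write_slide, write_volume

    out_dir.mkdir(parents=True, exist_ok=True)
    from .grids import ScalarVolume

    write_volume(results["labels"], out_dir / "labels.nii.gz")
    write_volume(results["distance"], out_dir / "distance.nii.gz")
    write_volume(results["density"], out_dir / "density.nii.gz")
    edema = results["edema"]
    write_volume(
        ScalarVolume(edema.grid, edema.mask.astype(float), units="mask"),
        out_dir / "edema.nii.gz",
    )
    for slide in results["slides"]:
        write_slide(slide, out_dir / "slides")
    pairs = results["pairs"]
    pd.DataFrame({"d_mm": pairs.d_mm, "density": pairs.density}).to_csv(
        out_dir / "pairs.csv", index=False
    )
    (out_dir / "fits.json").write_text(
        json.dumps({k: v.as_dict() for k, v in results["fits"].items()}, indent=1)
    )
    results["icdf"]["table"].to_csv(out_dir / "icdf.csv", index=False)
    results["scan"].curves.to_csv(out_dir / "scan_curves.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(results["manifest"], indent=1, default=float))
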