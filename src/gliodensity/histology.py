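"""Tile-based cell density maps from nuclei slides.

Slides are rasterized at 1 um/px and divided into adjacent 100 px x 100 px
tiles, so each tile corresponds to one 0.1 mm x 0.1 mm pixel of the surface
density map.  A tile's density is its nucleus count divided by the actual
tissue area inside the tile (tissue pixels x 1e-6 mm^2); tiles with less
than 10% tissue are marked missing (NaN).  Nuclei belong to the tile whose
half-open [x, x+100) x [y, y+100) window contains their center, so no
nucleus is counted twice.

Volume densities (cell/mm^3) are extrapolated from surface densities
(cell/mm^2) by the 3/2-power rule c_volume = c_surface^(3/2), valid for
approximately spherical, locally isotropic, homogeneously distributed
nuclei.  Maps are resampled onto the 0.5 mm analysis grid by block-averaging
the 5 x 5 map pixels covering each voxel footprint; voxels with more than
half their tiles missing stay unsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import TissueLabelVolume
from .phantom import NucleiSlide

__all__ = [
    "SurfaceDensityMap",
    "compute_surface_density_map",
    "surface_to_volume",
    "register_map_to_grid",
]

TILE_PX = 100  # 100 px x 100 px tiles at 1 um/px
MAP_PIXEL_MM = 0.1
MIN_TISSUE_FRACTION = 0.10
PX_AREA_MM2 = 1e-6  # one 1 um x 1 um pixel


@dataclass
class SurfaceDensityMap:
    """Per-tile surface cell density for one slide (cell/mm^2, NaN = missing)."""

    slide_id: int
    slice_index: int
    extent_vox: tuple[int, int, int, int]
    values: np.ndarray = field(repr=False)  # 2D, cell/mm^2, NaN where missing
    tissue_area: np.ndarray = field(repr=False)  # 2D, mm^2 per tile
    pixel_size_mm: float = MAP_PIXEL_MM
    voxel_size_mm: float = 0.5

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.values).sum())


def compute_surface_density_map(slide: NucleiSlide) -> SurfaceDensityMap:
    """Tile nucleus counts normalized by per-tile tissue area."""
    mask = np.asarray(slide.tissue_mask, bool)
    ny, nx = mask.shape
    if ny % TILE_PX or nx % TILE_PX:
        raise ValueError("slide dimensions must be a multiple of the 100 px tile size")
    ty, tx = ny // TILE_PX, nx // TILE_PX

    tissue_px = mask.reshape(ty, TILE_PX, tx, TILE_PX).sum(axis=(1, 3))
    tissue_area = tissue_px * PX_AREA_MM2

    counts = np.zeros((ty, tx), dtype=np.int64)
    if len(slide.nuclei):
        # half-open tile membership by nucleus center
        ti = np.floor(slide.nuclei[:, 0] / TILE_PX).astype(int)
        tj = np.floor(slide.nuclei[:, 1] / TILE_PX).astype(int)
        ok = (ti >= 0) & (ti < ty) & (tj >= 0) & (tj < tx)
        np.add.at(counts, (ti[ok], tj[ok]), 1)

    tile_area = (TILE_PX * TILE_PX) * PX_AREA_MM2
    defined = tissue_area >= MIN_TISSUE_FRACTION * tile_area
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(defined, counts / tissue_area, np.nan)
    return SurfaceDensityMap(
        slide_id=slide.slide_id,
        slice_index=slide.slice_index,
        extent_vox=slide.extent_vox,
        values=values,
        tissue_area=tissue_area,
        voxel_size_mm=slide.voxel_size_mm,
    )


def surface_to_volume(csurface):
    """Extrapolate volume density: c_volume = c_surface^(3/2).

    Strictly monotone; cell/mm^2 in, cell/mm^3 out.  NaN passes through
    (missing tiles stay missing).
    """
    arr = np.asarray(csurface, dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("surface density must be >= 0")
    out = arr**1.5
    return float(out) if out.ndim == 0 else out


def register_map_to_grid(
    density_map: SurfaceDensityMap,
    labels: TissueLabelVolume,
    slice_index: int | None = None,
) -> np.ndarray:
    """Block-average a density map onto its grid slice.

    Returns a full (ny, nz) slice array in map units with NaN where no
    sample exists.  Each 0.5 mm voxel footprint covers 5 x 5 map pixels
    (identity in-plane transform on phantoms); a voxel is sampled only if
    more than half of its tiles are defined.
    """
    grid = labels.grid
    if slice_index is None:
        slice_index = density_map.slice_index
    if not (0 <= slice_index < grid.shape[0]):
        raise IndexError(f"slice_index {slice_index} outside grid")
    if slice_index != density_map.slice_index:
        raise IndexError(
            f"map belongs to slice {density_map.slice_index}, not {slice_index}"
        )
    tiles_per_vox = int(round(grid.voxel_size[1] / density_map.pixel_size_mm))
    j0, j1, k0, k1 = density_map.extent_vox
    vals = density_map.values
    ty, tx = vals.shape
    if ty != (j1 - j0) * tiles_per_vox or tx != (k1 - k0) * tiles_per_vox:
        raise IndexError("density map extent does not match its voxel window")

    blocks = vals.reshape(j1 - j0, tiles_per_vox, k1 - k0, tiles_per_vox)
    finite = np.isfinite(blocks)
    n_def = finite.sum(axis=(1, 3))
    total = np.where(finite, blocks, 0.0).sum(axis=(1, 3))
    need = tiles_per_vox * tiles_per_vox // 2  # > 50% of tiles defined
    with np.errstate(invalid="ignore", divide="ignore"):
        voxel_vals = np.where(n_def > need, total / np.maximum(n_def, 1), np.nan)

    out = np.full((grid.shape[1], grid.shape[2]), np.nan)
    out[j0:j1, k0:k1] = voxel_vals
    return out
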