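"""NIfTI / CSV / PNG round-trip conventions.

Volumes are written as NIfTI-1 with an identity-direction affine scaled by
the voxel size (translation = grid origin); anything rotated or sheared is
rejected, since the pipeline defines world coordinates as voxel centers at
``origin + index * voxel_size``.  Label volumes are unsigned integers
(0=background, 1=csf, 2=gray, 3=white, 4=core, 5=necrosis); scalar volumes
are float64, with +inf stored as the sentinel 1e9 and restored on read.  A
JSON sidecar records kind, units and the sentinel so files are
self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib

from .errors import FormatError
from .grids import ScalarVolume, TissueLabelVolume, VoxelGrid
from .phantom import NucleiSlide

__all__ = ["write_volume", "read_volume", "write_slide", "read_slide"]

INF_SENTINEL = 1e9


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise FormatError(
            "foreign NIfTI orientation: affine must be diagonal (identity direction "
            "cosines scaled by voxel size); reorient/resample the volume first"
        )
    vs = np.diag(rot)
    if (vs <= 0).any():
        raise FormatError("voxel sizes in affine must be positive")
    return VoxelGrid(tuple(shape), tuple(float(v) for v in vs), tuple(float(o) for o in aff[:3, 3]))


def write_volume(volume: TissueLabelVolume | ScalarVolume, path: str | Path) -> Path:
    """Write a label or scalar volume as NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    if isinstance(volume, TissueLabelVolume):
        data = volume.labels.astype(np.uint8)
        meta = {"kind": "labels", "units": "label code"}
    elif isinstance(volume, ScalarVolume):
        data = volume.values.astype(np.float64).copy()
        n_inf = int(np.isinf(data).sum())
        data[np.isinf(data)] = INF_SENTINEL
        meta = {"kind": "scalar", "units": volume.units, "inf_sentinel": INF_SENTINEL, "n_inf": n_inf}
    else:
        raise TypeError(f"cannot write {type(volume).__name__}")
    img = nib.Nifti1Image(data, _affine(volume.grid))
    nib.save(img, str(path))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: str | Path) -> TissueLabelVolume | ScalarVolume:
    """Read a volume written by :func:`write_volume` (or any diagonal-affine
    NIfTI; integer data is interpreted as labels, float as scalar)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    grid = _grid_from_affine(np.asarray(img.affine, float), img.shape)
    data = np.asanyarray(img.dataobj)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    kind = meta.get("kind", "labels" if np.issubdtype(data.dtype, np.integer) else "scalar")
    if kind == "labels":
        return TissueLabelVolume(grid, data.astype(np.uint8))
    vals = data.astype(np.float64)
    sentinel = meta.get("inf_sentinel", INF_SENTINEL)
    vals[vals >= sentinel] = np.inf
    return ScalarVolume(grid, vals, units=meta.get("units", ""))


def write_slide(slide: NucleiSlide, out_dir: str | Path) -> Path:
    """One CSV of nucleus centers (x_um, y_um), a 1 um/px PNG tissue mask,
    and a JSON sidecar per slide."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"slide_{slide.slide_id:03d}"
    pd.DataFrame({"x_um": slide.nuclei[:, 0], "y_um": slide.nuclei[:, 1]}).to_csv(
        out_dir / f"{stem}_nuclei.csv", index=False
    )
    iio.imwrite(out_dir / f"{stem}_tissue.png", (slide.tissue_mask * np.uint8(255)))
    meta = {
        "slide_id": slide.slide_id,
        "slice_index": slide.slice_index,
        "extent_vox": list(slide.extent_vox),
        "voxel_size_mm": slide.voxel_size_mm,
        "um_per_px": 1.0,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return out_dir / f"{stem}.json"


def read_slide(meta_path: str | Path) -> NucleiSlide:
    import imageio.v3 as iio
    import pandas as pd

    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    stem = meta_path.stem
    d = meta_path.parent
    nuclei = pd.read_csv(d / f"{stem}_nuclei.csv")[["x_um", "y_um"]].to_numpy()
    tissue = iio.imread(d / f"{stem}_tissue.png") > 0
    return NucleiSlide(
        slide_id=int(meta["slide_id"]),
        slice_index=int(meta["slice_index"]),
        extent_vox=tuple(meta["extent_vox"]),
        tissue_mask=tissue,
        nuclei=nuclei,
        voxel_size_mm=float(meta["voxel_size_mm"]),
    )
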