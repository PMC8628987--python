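"""Synthetic brain phantoms and the synthetic inputs derived from them.

The phantom emulates the geometry the analysis needs and nothing more: two
ellipsoidal "hemispheres" of gray matter with white-matter interiors, a
white bridge between them standing in for the corpus callosum, a spherical
tumor core with a necrotic center embedded in one hemisphere's white matter,
and small CSF ventricles.  On top of the label volume the module can impose
an exponentially decaying total cell density

    c_total(d) = c_core * exp(-d / lambda_white) + c_white

with multiplicative lognormal noise, realize nuclei as an inhomogeneous
Poisson point pattern on 1 um tissue masks (the surface intensity is
c_volume^(2/3), the inverse of the volume-extrapolation rule), and build
edema masks that are either exact iso-distance regions (null scenario) or
smoothly perturbed regions (the observed scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .grids import LABELS, ScalarVolume, TissueLabelVolume, VoxelGrid
from .infiltration import DecayModelParams

__all__ = [
    "MetricTensorField",
    "NucleiSlide",
    "EdemaMask",
    "make_brain_phantom",
    "impose_infiltration_profile",
    "sample_nuclei_slide",
    "make_edema_mask",
    "make_metric_field",
    "bridge_mask",
]

#: Nuclei slides are always rasterized at 1 um per pixel.
SLIDE_UM_PER_PX = 1.0


@dataclass
class MetricTensorField:
    """Per-voxel symmetric positive-definite 3x3 metric (mm units)."""

    grid: VoxelGrid
    tensor: np.ndarray = field(repr=False)  # (*shape, 3, 3)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != self.grid.shape + (3, 3):
            raise ValueError("tensor field shape must be shape + (3, 3)")


@dataclass
class NucleiSlide:
    """Synthetic 2D histology slide: 1 um tissue mask plus nuclei centers.

    The slide lies in the (j, k) plane of the 3D grid at voxel slice
    ``slice_index`` along axis 0.  ``extent_vox`` is the half-open voxel
    index window ``(j0, j1, k0, k1)`` the slide covers; slide-local
    coordinates are micrometres from the footprint corner of voxel
    ``(j0, k0)``.
    """

    slide_id: int
    slice_index: int
    extent_vox: tuple[int, int, int, int]
    tissue_mask: np.ndarray = field(repr=False)  # 2D bool, 1 um/px
    nuclei: np.ndarray = field(repr=False)  # (N, 2) float um
    voxel_size_mm: float = 0.5

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei, dtype=float).reshape(-1, 2)

    @property
    def origin_mm(self) -> tuple[float, float]:
        """World (j, k) coordinate of the slide corner (voxel footprint corner)."""
        j0, _, k0, _ = self.extent_vox
        vs = self.voxel_size_mm
        return ((j0 - 0.5) * vs, (k0 - 0.5) * vs)


@dataclass
class EdemaMask:
    """Binary edema region on the analysis grid."""

    grid: VoxelGrid
    mask: np.ndarray = field(repr=False)
    mode: str = "iso"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if self.mode not in ("iso", "perturbed"):
            raise ValueError(f"unknown edema mode {self.mode!r}")


def _ellipsoid(grid: VoxelGrid, center_mm: np.ndarray, semi_mm: np.ndarray) -> np.ndarray:
    coords = [grid.axis_coords(a) for a in range(3)]
    x = (coords[0] - center_mm[0]) / semi_mm[0]
    y = (coords[1] - center_mm[1]) / semi_mm[1]
    z = (coords[2] - center_mm[2]) / semi_mm[2]
    return (
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    ) <= 1.0


def make_brain_phantom(
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 0.5,
    core_radius_mm: float = 5.0,
    seed: int = 0,
    with_ventricles: bool = True,
) -> TissueLabelVolume:
    """Build the two-hemisphere label phantom with an embedded tumor core.

    The core center is jittered by up to half a voxel from the first
    hemisphere's white-matter center (seeded), and the necrotic center is a
    concentric sphere of half the core radius.  ``core_radius_mm = 0``
    produces a tumor-free brain.

    Raises
    ------
    ConfigurationError
        If the core sphere does not fit inside white matter.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ConfigurationError("phantom shape must be at least 32 voxels per axis")
    if core_radius_mm < 0:
        raise ConfigurationError("core_radius_mm must be >= 0")
    grid = VoxelGrid(shape, (voxel_size,) * 3)
    rng = np.random.default_rng(seed)
    L = grid.extent_mm  # physical box, mm

    labels = np.zeros(shape, dtype=np.uint8)

    hemi_centers = []
    white_semi = None
    for cx in (0.26, 0.74):
        center = np.array([cx * L[0], 0.5 * L[1], 0.5 * L[2]])
        semi = np.array([0.23 * L[0], 0.42 * L[1], 0.42 * L[2]])
        hemi = _ellipsoid(grid, center, semi)
        white_semi = 0.80 * semi
        white = _ellipsoid(grid, center, white_semi)
        labels[hemi] = LABELS["gray"]
        labels[white] = LABELS["white"]
        hemi_centers.append(center)

    # white bridge ("corpus callosum") connecting the two hemispheres
    cj = [grid.axis_coords(a) for a in range(3)]
    in_x = (cj[0] >= 0.30 * L[0]) & (cj[0] <= 0.70 * L[0])
    in_y = np.abs(cj[1] - 0.5 * L[1]) <= 0.07 * L[1]
    in_z = np.abs(cj[2] - 0.5 * L[2]) <= 0.07 * L[2]
    bridge = in_x[:, None, None] & in_y[None, :, None] & in_z[None, None, :]
    labels[bridge] = LABELS["white"]

    if with_ventricles:
        for center in hemi_centers:
            vent = _ellipsoid(
                grid,
                center + np.array([0.0, 0.0, 0.17 * L[2]]),
                np.array([2.0, 2.0, 2.0]),
            )
            labels[vent & (labels == LABELS["white"])] = LABELS["csf"]

    if core_radius_mm > 0:
        # off-center within its hemisphere so the iso-distance surfaces of
        # interest span a wide shell rather than a small cap past the bridge
        core_center = (
            hemi_centers[0]
            + np.array([0.0, -0.45 * white_semi[1], 0.0])
            + rng.uniform(-0.5, 0.5, size=3) * voxel_size
        )
        core = _ellipsoid(grid, core_center, np.full(3, core_radius_mm))
        if not core.any():
            raise ConfigurationError("core radius smaller than one voxel")
        if (labels[core] != LABELS["white"]).any():
            raise ConfigurationError(
                f"core of radius {core_radius_mm} mm does not fit inside white matter"
            )
        labels[core] = LABELS["core"]
        necrosis = _ellipsoid(grid, core_center, np.full(3, 0.5 * core_radius_mm))
        labels[necrosis] = LABELS["necrosis"]

    return TissueLabelVolume(grid, labels)


def bridge_mask(labels: TissueLabelVolume, band_fraction: float = 0.05) -> np.ndarray:
    """White voxels in the central x-band of the grid (the phantom's bridge).

    A structural convention for the default phantom geometry: the hemisphere
    white matter never reaches the central ``band_fraction`` of the x-axis,
    so white voxels there belong to the bridge.
    """
    grid = labels.grid
    x = grid.axis_coords(0)
    band = np.abs(x - 0.5 * grid.extent_mm[0]) <= band_fraction * grid.extent_mm[0]
    return labels.white_mask & band[:, None, None]


def impose_infiltration_profile(
    labels: TissueLabelVolume,
    distance_map: ScalarVolume,
    decay_params: DecayModelParams,
    noise_cv: float = 0.0,
    seed: int | None = None,
    gray_factor: float = 1.5,
) -> ScalarVolume:
    """Impose the exponential-plus-baseline cell density on the phantom.

    White-matter voxels with finite distance d receive
    ``(c_core * exp(-d/lambda) + c_white) * eps`` where ``eps`` is lognormal
    with mean 1 and coefficient of variation ``noise_cv``.  The tumor core
    (and necrosis) receives the deterministic d=0 value; gray matter a
    distinct constant baseline ``gray_factor * c_white``; everything outside
    the brain — and white matter unreachable from the core — is NaN.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    decay_params.validate()
    d = distance_map.values
    values = np.full(labels.grid.shape, np.nan)

    white = labels.white_mask & np.isfinite(d)
    model = decay_params.c_core * np.exp(-d[white] / decay_params.lambda_white) + decay_params.c_white
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = np.log1p(noise_cv**2)
        eps = rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=model.shape)
        model = model * eps
    values[white] = model
    values[labels.core_mask] = decay_params.c_core + decay_params.c_white
    values[labels.mask("gray")] = gray_factor * decay_params.c_white
    return ScalarVolume(labels.grid, values, units="cell/mm^3")


def sample_nuclei_slide(
    volume_density: ScalarVolume,
    labels: TissueLabelVolume,
    slice_index: int,
    slide_extent: tuple[int, int, int, int],
    seed: int | None = None,
    slide_id: int = 0,
) -> NucleiSlide:
    """Draw nuclei on one grid slice as an inhomogeneous Poisson process.

    The surface intensity on tissue is ``c_volume^(2/3)`` per mm^2 — the
    inverse of the surface-to-volume extrapolation — held constant over each
    voxel footprint.  The tissue mask is the brain mask of the slice
    upsampled to 1 um pixels.
    """
    grid = labels.grid
    if not (0 <= slice_index < grid.shape[0]):
        raise IndexError(f"slice_index {slice_index} outside grid of shape {grid.shape}")
    j0, j1, k0, k1 = (int(v) for v in slide_extent)
    if not (0 <= j0 < j1 <= grid.shape[1] and 0 <= k0 < k1 <= grid.shape[2]):
        raise IndexError(f"slide extent {slide_extent} outside grid")
    if grid.voxel_size[1] != grid.voxel_size[2]:
        raise ConfigurationError("slide sampling requires isotropic in-plane voxels")

    vs = grid.voxel_size[1]
    px_per_vox = int(round(vs * 1000.0 / SLIDE_UM_PER_PX))
    rng = np.random.default_rng(seed)

    dens = volume_density.values[slice_index, j0:j1, k0:k1]
    tissue_vox = labels.brain_mask[slice_index, j0:j1, k0:k1]

    csurf = np.where(np.isfinite(dens), np.maximum(dens, 0.0), 0.0) ** (2.0 / 3.0)
    area_mm2 = vs * vs
    mean_counts = np.where(tissue_vox, csurf * area_mm2, 0.0)
    counts = rng.poisson(mean_counts)

    pts = []
    jj, kk = np.nonzero(counts)
    for j, k in zip(jj, kk):
        n = counts[j, k]
        # uniform positions inside the voxel footprint, in um from slide corner
        u = rng.uniform(0.0, px_per_vox, size=(n, 2))
        u[:, 0] += j * px_per_vox
        u[:, 1] += k * px_per_vox
        pts.append(u)
    nuclei = np.concatenate(pts, axis=0) if pts else np.empty((0, 2))

    tissue_mask = np.repeat(np.repeat(tissue_vox, px_per_vox, axis=0), px_per_vox, axis=1)
    return NucleiSlide(
        slide_id=slide_id,
        slice_index=slice_index,
        extent_vox=(j0, j1, k0, k1),
        tissue_mask=tissue_mask,
        nuclei=nuclei,
        voxel_size_mm=vs,
    )


def smooth_random_field(
    shape: tuple[int, int, int],
    scale_vox: float,
    seed: int | None,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation
    length ``scale_vox`` voxels (white noise filtered with a Gaussian)."""
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale_vox, mode="nearest")
    f -= f.mean()
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return f / sd


def make_edema_mask(
    distance_map: ScalarVolume,
    mode: str = "iso",
    threshold_mm: float = 20.0,
    perturb_amp_mm: float = 10.0,
    perturb_scale_mm: float = 15.0,
    seed: int | None = None,
) -> EdemaMask:
    """Build an edema mask from the geodesic distance map.

    ``iso`` mode realizes the null hypothesis exactly: the mask is the set of
    voxels with finite distance <= ``threshold_mm``, so its outline is an
    iso-distance contour by construction.  ``perturbed`` mode thresholds at
    ``threshold_mm + f(r)`` with ``f`` a smooth random field (Gaussian-filtered
    white noise, correlation length ``perturb_scale_mm``) standardized over
    the shell of voxels within ``perturb_amp_mm`` of the threshold surface and
    scaled to standard deviation ``perturb_amp_mm / 3`` there — so the
    amplitude parameter controls the realized outline displacement (excursions
    within roughly +/- the amplitude) independent of how the field happens to
    sit on the surface.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be > 0")
    if perturb_amp_mm < 0:
        raise ValueError("perturb_amp_mm must be >= 0")
    d = distance_map.values
    grid = distance_map.grid
    if mode == "iso" or perturb_amp_mm == 0:
        mask = np.isfinite(d) & (d <= threshold_mm)
        return EdemaMask(grid, mask, mode=mode)
    if mode != "perturbed":
        raise ValueError(f"unknown edema mode {mode!r}")
    scale_vox = perturb_scale_mm / float(np.mean(grid.spacing))
    f = smooth_random_field(grid.shape, scale_vox, seed)
    finite = np.isfinite(d)
    shell = finite & (np.abs(d - threshold_mm) <= perturb_amp_mm + grid.voxel_diagonal_mm)
    if shell.sum() >= 10 and f[shell].std() > 0:
        f = (f - f[shell].mean()) / f[shell].std()
    f = f * (perturb_amp_mm / 3.0)
    mask = finite & (d <= threshold_mm + f)
    return EdemaMask(grid, mask, mode="perturbed")


def make_metric_field(
    labels: TissueLabelVolume,
    mode: str = "unit",
    anisotropy_ratio: float = 1.0,
) -> MetricTensorField:
    """Unit isotropic metric, or a fiber metric fast along the bridge axis.

    In ``fiber`` mode the metric eigenvalue along the bridge (x) axis is
    ``1 / anisotropy_ratio`` inside the bridge region and 1 elsewhere, so
    traveling time through the bridge shrinks as the ratio grows while the
    transverse cost is unchanged.
    """
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    shape = labels.grid.shape
    tensor = np.zeros(shape + (3, 3))
    tensor[..., 0, 0] = tensor[..., 1, 1] = tensor[..., 2, 2] = 1.0
    if mode == "unit" or anisotropy_ratio == 1.0:
        return MetricTensorField(labels.grid, tensor)
    if mode != "fiber":
        raise ValueError(f"unknown metric mode {mode!r}")
    br = bridge_mask(labels)
    tensor[br, 0, 0] = 1.0 / anisotropy_ratio
    return MetricTensorField(labels.grid, tensor)
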