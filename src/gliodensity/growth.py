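"""Reaction-diffusion (Fisher-KPP) tumor growth on labeled voxel grids.

The model evolves a normalized tumor cell density c(r, t) in [0, 1]:

    dc/dt = div(D(r) grad c) + R(c),    D grad c . n = 0 on the brain boundary

with per-tissue isotropic diffusivity (d_white in white matter and the tumor
core, d_gray in gray matter, zero outside the brain) and a choice of
reaction term: logistic rho*c*(1-c), exponential rho*c, or Gompertz
rho*c*ln(1/c) (continuously extended to 0 at c=0).

Discretization is explicit Euler in flux form: the face diffusivity between
two adjacent voxels is the arithmetic mean of their diffusivities, and a
face is closed (zero flux) whenever either endpoint lies outside the brain
domain — which realizes the no-flux Neumann condition exactly and conserves
mass when rho = 0.

In white matter the classical Fisher asymptotics hold: the front travels at
speed 2*sqrt(rho*d_white) and the density tail ahead of it decays as
exp(-d / lambda_white) with infiltration length lambda_white =
sqrt(d_white / rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, StabilityError
from .grids import LABELS, ScalarVolume, TissueLabelVolume, VoxelGrid

__all__ = [
    "GrowthModelParams",
    "CellDensityState",
    "reaction_term",
    "cfl_limit",
    "simulate_growth",
    "infiltration_length",
    "tail_decay_length",
    "front_position_1d",
]

REACTION_KINDS = ("logistic", "exponential", "gompertz")


@dataclass
class GrowthModelParams:
    """Diffusion/proliferation parameters of the growth model."""

    d_white: float  # mm^2 / day
    d_gray: float  # mm^2 / day
    rho: float  # 1 / day
    reaction: str = "logistic"
    c_max: float = 1e5  # cell / mm^3, normalization constant

    def __post_init__(self) -> None:
        # coerce, so YAML scalars like "1.0e5" parse cleanly
        self.d_white = float(self.d_white)
        self.d_gray = float(self.d_gray)
        self.rho = float(self.rho)
        self.c_max = float(self.c_max)
        if not (self.d_white >= self.d_gray > 0):
            raise ValueError("require d_white >= d_gray > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.c_max <= 0:
            raise ValueError("c_max must be > 0")
        if self.reaction not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.reaction!r}")


@dataclass
class CellDensityState:
    """Normalized tumor cell density on the voxel grid at a given time."""

    grid: VoxelGrid
    c: np.ndarray = field(repr=False)
    time: float = 0.0  # days

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != self.grid.shape:
            raise ValueError("c shape does not match grid shape")

    def total_mass(self) -> float:
        """Integral of c over the grid (normalized cells x mm^3)."""
        return float(self.c.sum() * self.grid.voxel_volume_mm3)


def reaction_term(c, rho: float, kind: str):
    """Proliferation rate per day for density c in [0, 1]."""
    c = np.asarray(c, dtype=float)
    if kind == "logistic":
        out = rho * c * (1.0 - c)
    elif kind == "exponential":
        out = rho * c
    elif kind == "gompertz":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(c > 0, rho * c * np.log(1.0 / np.maximum(c, 1e-300)), 0.0)
    else:
        raise ValueError(f"unknown reaction kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def diffusivity_map(labels: TissueLabelVolume, params: GrowthModelParams) -> np.ndarray:
    """Per-voxel isotropic diffusivity: white/core/necrosis -> d_white,
    gray -> d_gray, outside the brain -> 0."""
    D = np.zeros(labels.grid.shape)
    D[labels.white_mask | labels.core_mask] = params.d_white
    D[labels.labels == LABELS["gray"]] = params.d_gray
    return D


def cfl_limit(params: GrowthModelParams, grid: VoxelGrid) -> float:
    """Largest stable explicit time step: 0.9 * dx_min^2 / (6 * max D)."""
    dx_min = float(np.min(grid.spacing))
    return 0.9 * dx_min**2 / (6.0 * params.d_white)


def simulate_growth(
    labels: TissueLabelVolume,
    params: GrowthModelParams,
    c0: np.ndarray | None = None,
    t_end: float = 100.0,
    dt: float | None = None,
    overshoot_tol: float = 1e-12,
) -> CellDensityState:
    """Integrate the model to ``t_end`` days with explicit Euler.

    ``c0`` defaults to 1 on core voxels and 0 elsewhere.  ``dt`` defaults to
    the CFL limit; an explicitly larger ``dt`` raises :class:`StabilityError`.
    For the saturating reaction kinds the solution is clipped to [0, 1] only
    when the overshoot is below ``overshoot_tol`` (otherwise
    :class:`NumericalError`); the exponential kind is unbounded by design.
    """
    grid = labels.grid
    limit = cfl_limit(params, grid)
    if dt is None:
        dt = limit
    if dt > limit * (1 + 1e-12):
        raise StabilityError(f"dt={dt} exceeds CFL bound {limit:.6g} day")
    if params.rho * dt > 1.0:
        raise StabilityError("rho * dt must not exceed 1 for the explicit reaction step")

    brain = labels.brain_mask
    if c0 is None:
        c = np.where(labels.core_mask, 1.0, 0.0)
    else:
        c = np.array(c0, dtype=float)
        if c.shape != grid.shape:
            raise ValueError("c0 shape does not match grid shape")
        if (c[~brain] != 0).any():
            raise ValueError("c0 must vanish outside the brain domain")
        if c.min() < 0 or (params.reaction != "exponential" and c.max() > 1):
            raise ValueError("c0 must lie in [0, 1]")

    D = diffusivity_map(labels, params)
    inv_dx2 = 1.0 / grid.spacing**2

    # Per-axis face transmissibilities: arithmetic-mean diffusivity, closed
    # (zero) at any face touching a non-brain voxel.
    faces = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        Dface = 0.5 * (D[sl_lo] + D[sl_hi])
        open_face = brain[sl_lo] & brain[sl_hi]
        faces.append((sl_lo, sl_hi, np.where(open_face, Dface, 0.0) * inv_dx2[ax]))

    n_steps = int(np.ceil(t_end / dt - 1e-12))
    t = 0.0
    for step in range(n_steps):
        h = min(dt, t_end - t)
        lap = np.zeros_like(c)
        for sl_lo, sl_hi, T in faces:
            flux = T * (c[sl_hi] - c[sl_lo])
            lap[sl_lo] += flux
            lap[sl_hi] -= flux
        c = c + h * (lap + reaction_term(c, params.rho, params.reaction))
        if params.reaction != "exponential":
            over = max(c.max() - 1.0, -c.min(), 0.0)
            if over > overshoot_tol:
                raise NumericalError(f"solution overshot [0, 1] by {over:.3e} at t={t + h:.4g}")
            np.clip(c, 0.0, 1.0, out=c)
        else:
            if c.min() < -overshoot_tol:
                raise NumericalError("negative density in exponential-growth run")
            np.clip(c, 0.0, None, out=c)
        t += h
    return CellDensityState(grid, c, time=t)


def infiltration_length(params: GrowthModelParams) -> float:
    """Infiltration length lambda_white = sqrt(d_white / rho), in mm."""
    if params.rho <= 0:
        raise ValueError("infiltration length undefined for rho = 0")
    return float(np.sqrt(params.d_white / params.rho))


def tail_decay_length(
    state: CellDensityState,
    distance_map: ScalarVolume | np.ndarray,
    white_mask: np.ndarray,
    fit_window_mm: tuple[float, float],
) -> float:
    """e-folding length of the simulated density tail.

    Fits ln c against distance over white voxels whose distance lies in
    ``fit_window_mm`` and returns the negated inverse slope.  A flat profile
    yields +inf; a window containing non-positive densities is an error.
    """
    d = distance_map.values if isinstance(distance_map, ScalarVolume) else np.asarray(distance_map, float)
    lo, hi = fit_window_mm
    sel = np.asarray(white_mask, bool) & np.isfinite(d) & (d >= lo) & (d <= hi)
    if not sel.any():
        raise ValueError("fit window contains no white voxels")
    c = state.c[sel]
    if (c <= 0).any():
        raise ValueError("fit window contains non-positive densities")
    slope = np.polyfit(d[sel], np.log(c), 1)[0]
    if slope >= -1e-12:
        return float("inf")
    return float(-1.0 / slope)


def front_position_1d(c_line: np.ndarray, coords_mm: np.ndarray, level: float = 0.5) -> float:
    """Position (mm) where a monotone 1D profile crosses ``level``,
    linearly interpolated between voxel centers."""
    c_line = np.asarray(c_line, float)
    above = c_line >= level
    if not above.any() or above.all():
        raise ValueError("profile does not cross the level")
    i = int(np.max(np.nonzero(above)))
    if i + 1 >= c_line.size:
        raise ValueError("front touches the domain end")
    c0, c1 = c_line[i], c_line[i + 1]
    frac = (c0 - level) / (c0 - c1)
    return float(coords_mm[i] + frac * (coords_mm[i + 1] - coords_mm[i]))
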