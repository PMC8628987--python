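"""Exponential-plus-baseline infiltration model and its least-squares fit.

The working model for total cell density in white matter as a function of
geodesic distance d (mm) to the tumor core is

    c_total(d) = c_core * exp(-d / lambda_white) + c_white

where c_core is the tumor cell density iso-value at the core boundary,
lambda_white the infiltration length, and c_white the healthy white-matter
baseline cellularity.  The model exists in two flavors: ``surface``
(cell/mm^2, fitted to tile densities) and ``volume`` (cell/mm^3, fitted to
extrapolated volume densities); they are fitted independently because the
surface-to-volume power law does not commute with the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

from .errors import EmptyPairsError
from .grids import ScalarVolume

__all__ = [
    "DecayModelParams",
    "DistanceDensityPairs",
    "FitResult",
    "collect_pairs",
    "synthesize_pairs",
    "fit_decay_model",
    "predict_total_density",
    "predict_overcellularity",
]


@dataclass
class DecayModelParams:
    """Parameters (c_core, lambda_white, c_white) of the decay model."""

    c_core: float
    lambda_white: float  # mm
    c_white: float
    flavor: str = "volume"  # "surface" (cell/mm^2) or "volume" (cell/mm^3)

    def validate(self) -> "DecayModelParams":
        if self.flavor not in ("surface", "volume"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if not (self.c_core > 0 and self.lambda_white > 0 and self.c_white > 0):
            raise ValueError("all decay parameters must be strictly positive")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DistanceDensityPairs:
    """Paired (distance, density) samples over white-matter voxels."""

    d_mm: np.ndarray
    density: np.ndarray
    slide_id: np.ndarray | None = None  # provenance, optional
    voxel_index: np.ndarray | None = None  # (N, 3) int, optional

    def __post_init__(self) -> None:
        self.d_mm = np.asarray(self.d_mm, dtype=float).ravel()
        self.density = np.asarray(self.density, dtype=float).ravel()
        if self.d_mm.shape != self.density.shape:
            raise ValueError("d_mm and density must have equal length")
        if (self.d_mm < 0).any():
            raise ValueError("distances must be >= 0")
        if (self.density < 0).any():
            raise ValueError("densities must be >= 0")

    def __len__(self) -> int:
        return self.d_mm.size


@dataclass
class FitResult:
    params: DecayModelParams
    residual_norm: float
    converged: bool
    degenerate: bool
    n_pairs: int
    init: tuple[float, float, float]
    bounds: tuple[float, float]
    message: str = ""

    def as_dict(self) -> dict:
        out = asdict(self)
        out["params"] = self.params.as_dict()
        return out


def predict_total_density(params: DecayModelParams, d) -> np.ndarray | float:
    """c_core * exp(-d/lambda) + c_white at distance(s) d (mm)."""
    d = np.asarray(d, dtype=float)
    out = params.c_core * np.exp(-d / params.lambda_white) + params.c_white
    return float(out) if out.ndim == 0 else out


def predict_overcellularity(params: DecayModelParams, d):
    """Density above the white-matter baseline at distance d.

    Returns ``(overcellularity, percent_of_c_core)`` — the tumor-attributed
    part of the total density and the same value expressed as a percentage
    of the core iso-value.
    """
    d = np.asarray(d, dtype=float)
    over = params.c_core * np.exp(-d / params.lambda_white)
    pct = 100.0 * over / params.c_core
    if over.ndim == 0:
        return float(over), float(pct)
    return over, pct


def collect_pairs(
    density_samples: ScalarVolume | np.ndarray,
    distance_map: ScalarVolume | np.ndarray,
    white_mask: np.ndarray,
    slide_ids: np.ndarray | None = None,
) -> DistanceDensityPairs:
    """One pair per white voxel holding both a density sample (non-NaN)
    and a finite geodesic distance; all other voxels are skipped."""
    dens = density_samples.values if isinstance(density_samples, ScalarVolume) else np.asarray(density_samples, float)
    dist = distance_map.values if isinstance(distance_map, ScalarVolume) else np.asarray(distance_map, float)
    ok = np.asarray(white_mask, bool) & np.isfinite(dist) & np.isfinite(dens)
    if not ok.any():
        raise EmptyPairsError("no white voxel has both a density sample and a finite distance")
    idx = np.argwhere(ok)
    return DistanceDensityPairs(
        d_mm=dist[ok],
        density=np.maximum(dens[ok], 0.0),
        slide_id=None if slide_ids is None else np.asarray(slide_ids)[ok],
        voxel_index=idx,
    )


def synthesize_pairs(
    params: DecayModelParams,
    n: int,
    d_range_mm: tuple[float, float] = (0.0, 40.0),
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> DistanceDensityPairs:
    """Draw synthetic pairs from the model with multiplicative lognormal
    noise of mean 1 and coefficient of variation ``noise_cv`` (the same noise
    family the phantom imposes on its density field)."""
    params.validate()
    rng = np.random.default_rng(seed)
    d = rng.uniform(d_range_mm[0], d_range_mm[1], size=n)
    dens = np.asarray(predict_total_density(params, d))
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        dens = dens * rng.lognormal(-0.5 * sigma2, np.sqrt(sigma2), size=n)
    return DistanceDensityPairs(d_mm=d, density=dens)


def default_init(pairs: DistanceDensityPairs) -> tuple[float, float, float]:
    """Data-driven starting point: baseline from the farthest distance
    quartile, core amplitude from the near-core high quantile, lambda 10 mm."""
    d, y = pairs.d_mm, pairs.density
    q75 = np.quantile(d, 0.75)
    c_white0 = float(np.median(y[d >= q75])) if (d >= q75).any() else float(np.median(y))
    near = y[d < 2.0]
    if near.size == 0:
        near = y[d <= np.quantile(d, 0.05)]
    c_core0 = max(float(np.quantile(near, 0.95)) - c_white0, 1e-3)
    c_white0 = max(c_white0, 1e-3)
    return (c_core0, 10.0, c_white0)


def fit_decay_model(
    pairs: DistanceDensityPairs,
    init: tuple[float, float, float] | None = None,
    bounds: tuple[float, float] = (1e-6, 1e7),
    flavor: str = "volume",
    weights: np.ndarray | None = None,
) -> FitResult:
    """Nonlinear least squares of c_core*exp(-d/lambda)+c_white to the pairs.

    lambda is additionally bounded above by the largest observed distance,
    which prevents degenerate flat fits.  A fit is flagged degenerate when
    c_core collapses to the lower bound (no decay signal).
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to fit the decay model")
    d, y = pairs.d_mm, pairs.density
    lo, hi = bounds
    lam_hi = min(hi, float(d.max())) if d.max() > 0 else hi
    if init is None:
        init = default_init(pairs)
    x0 = np.clip(np.asarray(init, dtype=float), lo * 1.01, [hi, lam_hi, hi])
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    def resid(x):
        return w * (x[0] * np.exp(-d / x[1]) + x[2] - y)

    sol = least_squares(
        resid,
        x0,
        bounds=([lo, lo, lo], [hi, lam_hi, hi]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    c_core, lam, c_white = (float(v) for v in sol.x)
    degenerate = c_core <= 10 * lo or lam <= 10 * lo
    params = DecayModelParams(c_core=c_core, lambda_white=lam, c_white=c_white, flavor=flavor)
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        degenerate=bool(degenerate),
        n_pairs=len(pairs),
        init=tuple(float(v) for v in x0),
        bounds=(lo, hi),
        message=str(sol.message),
    )
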