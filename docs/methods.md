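# Methods

This note documents the models, conventions and numerical choices behind
`gliodensity`, in the order the pipeline uses them.

## Grids and world coordinates

All volumes live on regular axis-aligned grids; the center of voxel
(i, j, k) is at `origin + (i, j, k) · voxel_size` (mm).  The default
analysis grid is 96³ voxels at 0.5 mm — distance maps, imposed densities and
registered histology samples all share it, so pair extraction is a mask
intersection with no resampling ambiguity.  NIfTI output uses a diagonal
affine built from the voxel size; files with rotated or sheared affines are
rejected rather than silently reinterpreted, and +inf (unreachable voxels)
is stored as the sentinel 1e9 with a JSON sidecar noting it.

## The brain phantom

The phantom is a geometric stand-in for the tissue architecture the analysis
depends on, not an anatomical atlas: two ellipsoidal gray-matter hemispheres
(in-plane semi-axes 0.42 of the box) with white-matter interiors (0.80 of
the hemisphere semi-axes), a white bridge between them standing in for the
corpus callosum, small CSF ventricles, and a spherical tumor core with a
concentric necrotic center embedded in one hemisphere's white matter.  The
core is deliberately placed off-center (0.45 of the white semi-axis), so
that iso-distance surfaces in the 15–25 mm range form wide shells spanning
both hemispheres instead of small caps just past the bridge — perturbations
of an outline can only be detected if the outline has spatial extent.
Generation is deterministic given the seed (the seed only jitters the core
center by up to half a voxel).  White matter forms a single face-connected
component; the embedding of the core inside white matter is checked and a
configuration error raised otherwise.

What the phantom does not emulate: cortical folding, realistic gray/white
contrast, scanner noise, registration error between modalities (identity
in-plane registration stands in for the landmark-based step a real study
needs), and partial-volume effects.  Tests passing on phantoms therefore
validate the machinery — solvers, estimators, diagnostics — not the
biological fidelity of any particular parameter value.

## Imposed infiltration profile

On white matter the total cell density is c(d) = c_core·exp(−d/λ_white) +
c_white, evaluated on the geodesic distance map and multiplied by lognormal
noise with mean 1 and coefficient of variation `noise_cv` (default 0.2).
Lognormal rather than Gaussian noise keeps densities positive at any noise
level.  Defaults are c_core = 1.05×10⁵, λ_white = 8.46 mm, c_white =
0.59×10⁵ cell/mm³ — the volume-flavor parameter regime the analysis targets.
Gray matter gets a constant 1.5 × c_white (the gray/white cellularity
contrast is a free parameter of the phantom; 1.5 is a plausible default and
nothing downstream depends on it), the core gets the deterministic d = 0
value, and everything outside the brain is NaN.

## Nuclei slides and tile density maps

Nuclei are realized as an inhomogeneous Poisson point process on a 1 µm/px
tissue mask, with surface intensity c_surface = c_volume^(2/3) per mm² —
the inverse of the extrapolation law below, so the slide route is
self-consistent by construction.  No hard-core repulsion or nucleus shape is
modeled: the only statistic the pipeline consumes is the count per tile,
for which Poisson is the right null.  Density maps divide each 100 px ×
100 px tile's count by its actual tissue area (tissue pixels × 10⁻⁶ mm²);
tiles under 10% tissue are marked missing, because density estimates from
slivers of tissue are dominated by the area denominator.  Tile membership
is half-open by nucleus center, so edge nuclei are counted exactly once.
Volume densities use c_volume = c_surface^(3/2), valid for approximately
spherical, locally isotropic, homogeneously distributed nuclei; the
conversion is applied per tile, before spatial averaging, and the two model
flavors (surface, volume) are always fitted independently because the power
law does not commute with either averaging or fitting.  Registration to the
analysis grid is a 5×5 block mean of map pixels per 0.5 mm voxel footprint;
a voxel is sampled only if more than half of its tiles are defined, and the
missing marker propagates (unsampled voxels simply yield no pair).

## Growth solver

Explicit Euler in flux form: per-axis face transmissibilities use the
arithmetic mean of the endpoint diffusivities and are zero across any face
touching a non-brain voxel, which realizes the no-flux Neumann condition
discretely and conserves ∑c exactly when ρ = 0 (verified to 1e−10 over 1000
steps).  The time step obeys dt ≤ 0.9·dx²/(6·max D); violating it raises an
error rather than warning.  Diffusivity is an isotropic per-tissue scalar
(d_white in white matter and the core, d_gray in gray matter); anisotropy is
deliberately confined to the geodesics module, since the growth analysis
itself never had tensor data.  Reaction kinds: logistic ρc(1−c),
exponential ρc, Gompertz ρc·ln(1/c) with the continuous limit 0 at c = 0.
Saturating kinds are clipped to [0, 1] only when overshoot is below 1e−12;
larger overshoot is an error, not a silent fix.

The Fisher–KPP checks initialize a quasi-1D white rod with the critical
exponential profile min(1, e^(−x/λ)), under which the front reaches its
asymptotic speed 2√(ρ d) quickly (front position measured by linear
interpolation of the c = 0.5 crossing over two 300-day legs at dx =
0.25 mm; the measured speed is ~4% low, dominated by the slow O(1/t)
transient, within the 5% contract).  The tail decay length is the negated
inverse slope of ln c vs. distance, fitted 20–45 mm ahead of the front —
closer than 20 mm the pulled-front prefactor still biases the local slope
by more than 10%.  Grid-refinement convergence is asserted on successive
speed differences |s(h/2) − s(h/4)| ≤ ½|s(h) − s(h/2)|, which cancels the
shared transient bias and isolates the discretization order (the scheme
measures ≈ 0.26, i.e. second order).

## Geodesic distance maps

Distances are first-arrival costs from the tumor core (sources, d = 0)
through a permitted mask — white matter by default, optionally the whole
brain — on a voxel graph whose edge between neighbors with world offset v
costs √(vᵀ M v), M the mean of the endpoint metric tensors.  The unit
metric gives mm; an anisotropic metric gives a traveling time and outputs
are labeled as such.  Two stencils exist: the 26-connected reference
(`graph26`), and the default extended stencil of all 98 coprime offsets in
the 5³ neighborhood, which cuts the worst-direction chamfer overestimate
from ~8% to under 5% at r ≥ 10 voxels; offsets reaching two voxels are
admitted only when both voxels straddling their midpoint are in the domain,
so paths cannot tunnel through thin obstacles such as the gray gap between
hemispheres.  A pure-Python heap Dijkstra (`dijkstra_oracle`) implements
the 26-connected semantics independently of the scipy-based production
solver and is the reference in the equivalence tests (production within 8%
RMS on random masked instances; `graph26` matches it exactly).  The fiber
metric shrinks the along-bridge eigenvalue to 1/ratio inside the bridge,
and the anisotropy check verifies contralateral mean arrival time decreases
monotonically with the ratio.

## Infiltration fit

Pairs are one per white voxel holding both a finite distance and a density
sample.  The fit is unweighted nonlinear least squares (trust-region
reflective, tight tolerances) of c_core·e^(−d/λ) + c_white with bounds
(10⁻⁶, 10⁷) on all parameters and λ additionally capped by the largest
observed distance — an unbounded λ lets a flat cloud masquerade as slow
decay.  Initialization is data-driven: c_white from the median of the
farthest distance quartile, c_core from the 95th percentile of near-core
(d < 2 mm) densities minus that baseline, λ = 10 mm.  A fit whose c_core
collapses to the lower bound is flagged degenerate (no decay signal), never
silently returned as a success.  Optional per-pair weights (e.g. tile
tissue area) are accepted behind a flag; the default analysis does not use
them.  Noiseless pairs reproduce their generating parameters to well below
0.1%; at noise_cv = 0.2 and n = 5000 the median relative errors are ~2%
(λ), ~0.6% (c_white) and ~1% (c_core) over 20 repetitions.

## Edema geometry

`imaging_mask` realizes the threshold visibility model (defaults 0.80
enhancing, 0.16 edema).  Boundaries are face-connectivity inner boundaries
as voxel-center coordinates in mm; when a `domain` mask is given (white ∪
core for everything derived from the white-matter distance map), voxels
adjacent only to non-domain tissue are not boundary — the analysis never
leaves the propagation domain, which is also what makes the iso-distance
null scenario exactly step-like instead of polluted by the white/gray
interface.  Hausdorff and ASSD are computed exactly with KD-trees (no
distance-transform approximation), so brute-force equality holds on small
sets.  The inverse cumulative distribution reports the fraction of boundary
voxels at distance ≥ x plus upper quantiles; the threshold scan sweeps
t over [1 mm, max finite d] in 0.5 mm steps, compares the boundary of
{d ≤ t} to the edema boundary under both metrics, skips empty regions, and
breaks ties toward the smaller threshold.

Edema masks: `iso` mode is {finite d ≤ T} — the null hypothesis by
construction.  `perturbed` mode thresholds at T + f(r) where f is
Gaussian-filtered white noise with correlation length `perturb_scale_mm`
(default 15 mm), standardized over the shell of voxels within one amplitude
of the threshold surface and scaled to a standard deviation of amp/3
(default amp 10 mm).  Standardizing on the shell rather than globally makes
the amplitude parameter control the realized outline displacement: a field
with a 15 mm correlation length is nearly constant across a surface of
similar extent, and without this choice the "perturbed" scenario would
collapse to a shifted iso-contour.  One consequence of the finite phantom
is that the upper tail of the perturbed boundary-distance distribution
saturates near the maximum reachable distance (~30 mm), so upper-quantile
gaps are compressed relative to an unbounded medium; the diagnostics the
analysis relies on (step vs. continuous ICDF, threshold recovery, Hausdorff
vs. ASSD minima) are unaffected.

## Pipeline and reproducibility

`run_pipeline` chains phantom → distance map → imposed density → slides →
tile maps → pairs → fits → edema analyses, with every stochastic stage
seeded as `SeedSequence([master_seed, stage_counter, repetition])` — stage
counters are fixed constants, so no stage reuses another's stream and runs
are bit-reproducible (manifests carry per-stage SHA-256 checksums and
change iff an input parameter changes).  Pairs can come from the full
histology route (both fit flavors, Poisson sampling noise included) or
directly from the imposed density field (`imposed`, selected automatically
when the slide plan is empty); the direct route carries no sampling noise,
which is what makes the noiseless end-to-end identifiability check exact.
The default slide plan places six 8×8 mm windows from the core hemisphere
across the bridge into the contralateral side, spanning distances 0–25 mm
(about three infiltration lengths).

## Problem sizes

Defaults were chosen so each analysis is statistically meaningful at
desk scale: 96³ phantom (≈1.5×10⁵ white voxels), 20-seed recovery at
n = 5000 pairs, a 704-voxel rod for the Fisher run, 16³ instances for the
oracle suite, and 12×12 voxel slides (6000² pixels at 1 µm) for histology.
The full test suite runs in about half a minute; the acceptance script in
about 20 seconds.

## Known limitations

- The graph-based distance map overestimates true geodesic distances by a
  direction-dependent chamfer factor (< 5% with the extended stencil); it
  is not a converging eikonal solver.
- The anisotropic metric path uses the same graph semantics; no causality-
  ordered anisotropic fast marching is implemented.
- The explicit growth solver is first-order in time and requires small
  steps; stiff parameter regimes (large D on fine grids) get slow rather
  than inaccurate.
- Histology realism is limited to count statistics: no nucleus morphology,
  staining variation, tissue deformation, or detection error model.
- The fit reports point estimates and residual diagnostics only; no
  uncertainty quantification.
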