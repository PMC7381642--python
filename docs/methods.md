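# Methods

## The model

The package simulates skin-pattern formation in *Pseudoplatystoma*
(surubim) catfishes as two stacked reaction–diffusion layers.  Each layer
carries two morphogen fields, `u` and `v`, measured as deviations from an
average level (positive = local excess, negative = deficiency).  The local
kinetics are the BVAM system, the most general two-species kinetics with
quadratic and cubic nonlinearities that conserve mass:

    f(u, v) = u + a v − C u v − u v²
    g(u, v) = b v + h u + C u v + u v²

The nonlinear terms cancel in `f + g`, which is therefore exactly linear —
the "mass conservation" structure asserted by a property test.  The two
layers evolve as

    ∂u₁/∂t = D ∇²u₁ + η f(u₁, v₁) + q (u₂ − u₁)
    ∂v₁/∂t =   ∇²v₁ + η g(u₁, v₁) + q (v₂ − v₁)
    ∂u₂/∂t = D ∇²u₂ + η f(u₂, v₂) − q (u₂ − u₁)
    ∂v₂/∂t =   ∇²v₂ + η g(u₂, v₂) − q (v₂ − v₁)

with layer 1 the inner (invisible, pre-patterned) tissue layer and layer 2
the outer (visible) one.  The layers are flat and congruent, so the
exchange `q(·₂ − ·₁)` is strictly pointwise in (x, y).  Both layers use
the same kinetic constants by default — there is no biological reason to
assume otherwise — but the interface keeps two parameter sets so the
layers *can* differ (e.g. in time scale η).

### Reference parameter set

The named parameter set `table1` is used everywhere by default:

| parameter | value    | meaning                              |
|-----------|----------|--------------------------------------|
| a         | 0.05775  | linear cross-activation u ← v        |
| b         | −0.30525 | linear decay of v                    |
| h         | −1.30000 | linear cross-inhibition v ← u        |
| C         | 0.02000  | quadratic/cubic ratio (front speed)  |
| η         | 0.47000  | system-size / rate scale             |
| D         | 0.46600  | diffusion ratio D_u / D_v            |

At these values the kinetics have exactly three fixed points: a saddle at
the origin (det J = b − a·h = −0.230175 < 0) and two near-mirror stable
nodes at (−0.787394, 0.954417) and (0.803894, −0.974417).  The regime is
**bistable**, not Turing: the homogeneous state of interest is already
unstable at zero wavenumber, and diffusion only damps (the dispersion
relation is maximal at k² = 0).  Patterns arise from travelling fronts
between the two stable phases whose velocity is regulated by the
asymmetry parameter C and which arrest at finite curvature, freezing the
domain geometry into the visible motif.

## Numerical scheme

Explicit Euler finite differences on a rectangular lattice (default
200 × 100, dx = 1; η carries the physical scale).  The Laplacian is the
5-point stencil with mirror-cell Neumann boundaries (ghost = adjacent
interior cell), which keeps the discrete grid sum of the Laplacian at
zero — no morphogen crosses the boundary.  Opposite neighbours are summed
first, `(up+down) + (left+right)`, so reflections of the initial state
produce bit-exact reflections of the trajectory.

Default integration: dt = 0.01 for 240 000 steps.  The diffusive CFL
bound (dt ≤ dx²/4 for the fastest field) is satisfied by a factor of 25.
A step-halving check (dt 0.01 → 0.005 on a 64 × 64 seeded run) moves the
final fields by less than 0.05 in sup-norm, and the per-field change over
the final step is logged as a convergence indicator.  Reduced-scale
analyses in the tests and the acceptance script use a 128 × 64 grid and
40 000 steps; the pattern classes are already frozen well before that
horizon (40 000- and 240 000-step runs classify identically in the
calibration scans), so the reduced runs probe the same steady states.

The production stepper is a numba-compiled fused kernel that repeats the
per-cell update with exactly the same arithmetic ordering as the
vectorised `euler_step` (no fastmath); the tests assert bit-identity
between the two paths and against a scalar quadruple-loop oracle.  A
pure-numpy fallback runs when numba is unavailable.  Divergence of the
explicit scheme is detected every step and reported with the offending
step index, never silently.

## Initial conditions

* **Inner layer:** `u₁` is a comb: +1 everywhere, −1 on a 3-row top band
  and on 12 equally spaced vertical teeth (5 cells wide) reaching the
  bottom edge.  This encodes the whitish vertical lines (10–15 on the
  flank) that orient the pattern; 12 is the midpoint of the biological
  count.  Tooth width 5 is the narrowest domain of the disfavoured phase
  that survives as a frozen front at the reference parameters — 3-cell
  teeth evaporate before the outer layer can feel them.  `v₁` is pure
  noise.
* **Outer layer:** `u₂ = u₀₂ + ζ`, `v₂ = ζ`, with ζ i.i.d. uniform noise
  of full width 0.02 and zero mean.  `u₀₂` is the species-dependent
  ambient morphogen level.
* One seed spawns four independent substreams (u₁, v₁, u₂, v₂):
  reproducible, uncorrelated fields.  By default the comb also receives
  noise (negligible against ±1); a flag disables it.

## The pigment phase

The morphogen `u` is treated as an inhibitor of melanophore
proliferation, so the dark (melanophore-dense) pattern lives where the
outer layer shows a morphogen *deficiency*.  All pattern classification
therefore operates on `pigment_phase(u2) = −u2` thresholded at 0.  This
orientation makes the observable transitions come out right: raising u₀₂
moves the steady pattern from closed cells through stripes to scattered
dots, and the pure-dot regime (the *P. corruscans* pattern) occurs at
high morphogen level with weak coupling.

## Morphometry

The thresholded pigment mask is decomposed into 8-connected components
(holes 4-connected).  Per component: area, perimeter, holes
(1 − Euler number), best-fit-ellipse elongation, and isoperimetric
compactness 4π·area/perimeter².  Motifs:

* **cell** — any component with ≥ 1 hole; it contributes one cell per
  enclosed loop (on reticulated skins loops share walls, so one network
  is many cells; six separate rings still count six);
* **stripe** — hole-free but elongated (≥ 3) **or** thin
  (compactness ≤ 0.35; ellipse elongation misses branched labyrinths,
  whose best-fit ellipse is nearly round).  A holey component whose
  hole-*filled* shape is still thin or elongated is a labyrinth carrying
  loops and contributes its stripe backbone as well (an annulus fills to
  a compact disk and does not);
* **dot** — the compact hole-free remainder.

Components below 5 cells are discarded as noise; a hole-free component
covering ≥ 97 % of the domain is a homogeneous sea, not a motif.  Region
classes from motif count fractions: (1) cells ≥ 0.8; (4) dots ≥ 0.8;
(2) all three motifs present with cell fraction ≥ 0.1; (3) otherwise.
All cutoffs are explicit configuration (`MotifThresholds`): the region
taxonomy is qualitative and these are the package's operational
stand-ins, calibrated once on the reference dynamics and then frozen.

## Phase diagram and presets

Sweeping (u₀₂, q) and classifying each steady `u₂` reconstructs the
four-region phase diagram.  By default every sweep cell reuses the same
seed ("same initial random conditions"); with several seeds the modal
class is kept (ties break to the lowest class), which stabilises cells
near the smooth region boundaries.  Blow-ups are recorded per cell and
never abort a sweep.

Two calibration facts shape the axes:

* The usable u₀₂ window is narrow — |u₀₂| of a few 10⁻⁴ at noise width
  0.02.  A region's fate is decided by the sign of its diffusion-smoothed
  initial field relative to the separatrix through the saddle, and
  smoothing shrinks the effective noise amplitude far below its nominal
  width.  Larger |u₀₂| gives a homogeneous (featureless) steady state at
  q = 0.
* The q axis is genuinely small (0 … ~10⁻²): beyond q ≈ 5·10⁻³ the outer
  layer is slaved to the comb and shows only vertical stripes; the
  species-relevant variation happens below that.

Region presets pin one (u₀₂, q) pair inside each region, calibrated from
this package's own sweeps at the default grid and kept fixed so that
documentation and tests stay stable.  Any interior point of a region
would serve; near region boundaries individual seeds can land in an
adjacent class — that smoothness is a property of the model, not an
artefact.

## What the synthetic conditions do and do not show

All inputs are synthetic by construction (the model has no external
data): the comb stands in for real vertical lines, uniform noise for
developmental variability, and a rectangle for the flank.  Passing tests
show that the *model* reproduces the counted qualitative structure —
three fixed points, three motifs, four regions, the cells→dots transition
in u₀₂ — under these idealised conditions.  They do not show likeness to
photographs of particular fish, body-shaped domains, dendritic line
geometry, or histological mechanism; all of that is out of scope.

## Known limitations

* Explicit Euler only; no adaptive or implicit stepping (a blow-up is
  reported, not avoided).
* The pre-pattern is an initial condition only, not a persistent source
  term; whether real vertical lines act as a standing constraint is an
  open biological question.
* Count-based region fractions make class 2 (the three-motif crossover)
  intrinsically seed-sensitive near its boundaries; the modal-over-seeds
  machinery mitigates but cannot remove this.
* The motif cutoffs (elongation 3, compactness 0.35, min area 5) are
  reasonable operational choices, not fitted quantities.
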