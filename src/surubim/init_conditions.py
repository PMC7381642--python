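"""Initial conditions: comb-like inner-layer pre-pattern and seeded noise.

The inner layer starts from a "comb": morphogen level +1 everywhere except
-1 on a top horizontal band and on equally spaced vertical teeth reaching
the bottom edge.  This stands in for the thin whitish vertical lines (10-15
of them on the flank) that compartmentalise the pattern of most surubim
species.  The outer, visible layer starts flat at a level ``u02`` -- the
species-dependent ambient morphogen abundance -- and every field receives
i.i.d. uniform noise of small full width (default 0.02, zero mean) from a
seeded generator, so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import FieldSet, GridSpec

__all__ = [
    "PrePatternSpec",
    "InitSpec",
    "comb_prepattern",
    "noisy_field",
    "build_initial_state",
]


@dataclass(frozen=True)
class PrePatternSpec:
    """Geometry of the comb-like inner-layer pre-pattern.

    ``n_stripes`` vertical teeth of ``stripe_width`` columns descend from a
    top band of ``top_band_height`` rows to the bottom edge; teeth centres
    sit at columns ``round((j + 0.5) * nx / n_stripes)``.  Teeth must leave
    at least one column of gap between neighbours.

    The default width of 5 cells is the narrowest tooth that survives as a
    frozen domain of the bistable kinetics at the reference parameters;
    narrower teeth evaporate before the outer layer can feel them.
    """

    n_stripes: int = 12
    stripe_width: int = 5
    top_band_height: int = 3
    high_value: float = 1.0
    low_value: float = -1.0

    def __post_init__(self) -> None:
        if self.n_stripes < 1:
            raise ValueError(f"n_stripes must be >= 1, got {self.n_stripes}")
        if self.stripe_width < 1:
            raise ValueError(f"stripe_width must be >= 1, got {self.stripe_width}")
        if self.top_band_height < 0:
            raise ValueError("top_band_height must be >= 0")
        if not (np.isfinite(self.high_value) and np.isfinite(self.low_value)):
            raise ValueError("pre-pattern values must be finite")


@dataclass(frozen=True)
class InitSpec:
    """Outer-layer level, noise amplitude and RNG seed.

    ``u02`` is the mean initial morphogen level of the outer layer, the
    quantity that (with the coupling ``q``) distinguishes the species.
    ``noise_width`` is the full width of the zero-mean flat distribution
    added to every field.  ``noisy_prepattern`` also perturbs the comb of
    the inner layer; the 0.02 default amplitude is negligible against the
    +-1 pre-pattern either way.
    """

    u02: float = 0.0
    noise_width: float = 0.02
    seed: int = 0
    noisy_prepattern: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.u02):
            raise ValueError(f"u02 must be finite, got {self.u02}")
        if not (np.isfinite(self.noise_width) and self.noise_width >= 0):
            raise ValueError(f"noise_width must be >= 0, got {self.noise_width}")


def comb_prepattern(grid: GridSpec, spec: PrePatternSpec) -> np.ndarray:
    """Build the comb-shaped inner-layer field on ``grid``.

    Returns an (ny, nx) array equal to ``high_value`` everywhere except
    ``low_value`` on the top band and on the vertical teeth (row 0 is the
    top, dorsal side).  Rejects geometries whose teeth would touch or
    overlap.
    """
    nx, ny = grid.nx, grid.ny
    spacing = nx / spec.n_stripes
    if spec.stripe_width >= spacing:
        raise ValueError(
            f"teeth overlap: stripe_width {spec.stripe_width} >= spacing "
            f"{spacing:.2f} (nx={nx}, n_stripes={spec.n_stripes})"
        )
    if spec.top_band_height >= ny:
        raise ValueError("top_band_height must be smaller than ny")
    fld = np.full((ny, nx), float(spec.high_value))
    fld[: spec.top_band_height, :] = spec.low_value
    for j in range(spec.n_stripes):
        # half-up rounding: platform-stable, unlike round-half-to-even
        centre = int(np.floor((j + 0.5) * nx / spec.n_stripes + 0.5))
        start = max(0, centre - spec.stripe_width // 2)
        fld[:, start : start + spec.stripe_width] = spec.low_value
    return fld


def noisy_field(
    grid: GridSpec,
    level: float,
    spec: InitSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``level`` plus i.i.d. Uniform(-w/2, +w/2) noise, w = noise_width.

    Uses ``rng`` when given (so a caller can hand out independent
    substreams), otherwise a fresh generator seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    half = spec.noise_width / 2.0
    if half == 0.0:
        return np.full(grid.shape, float(level))
    return level + rng.uniform(-half, half, size=grid.shape)


def build_initial_state(
    grid: GridSpec, pre: PrePatternSpec, init: InitSpec
) -> FieldSet:
    """Assemble the four initial fields.

    u1 = comb pre-pattern (+ noise), v1 = noise, u2 = u02 + noise,
    v2 = noise.  One seed feeds four independent substreams (one per
    field), so fields are uncorrelated yet jointly reproducible.
    """
    streams = np.random.SeedSequence(init.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]
    comb = comb_prepattern(grid, pre)
    if init.noisy_prepattern:
        u1 = comb + noisy_field(grid, 0.0, init, rngs[0])
    else:
        u1 = comb
    v1 = noisy_field(grid, 0.0, init, rngs[1])
    u2 = noisy_field(grid, init.u02, init, rngs[2])
    v2 = noisy_field(grid, 0.0, init, rngs[3])
    return FieldSet(u1, v1, u2, v2)
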