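"""Spatial integration of the two coupled BVAM layers.

Explicit Euler finite differences on a rectangular grid.  Layer 1 is the
inner (pre-patterned, invisible) skin layer, layer 2 the outer (visible)
one; the layers sit flat on top of each other, so the linear exchange
``q (x2 - x1)`` acts pointwise in (x, y).  Zero-flux (Neumann) boundaries
model the finite extent of the fish flank: nothing crosses the domain edge.

The update of one Euler step is

    u1 += dt * ( D1 lap(u1) + eta1 f(u1, v1) + q (u2 - u1) )
    v1 += dt * (    lap(v1) + eta1 g(u1, v1) + q (v2 - v1) )
    u2 += dt * ( D2 lap(u2) + eta2 f(u2, v2) - q (u2 - u1) )
    v2 += dt * (    lap(v2) + eta2 g(u2, v2) - q (v2 - v1) )

with f, g from :mod:`surubim.kinetics`.  The arithmetic order of every
expression is fixed so that the vectorised stepper is bit-identical to a
scalar cell-by-cell reference loop, which the tests exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, reaction_terms

__all__ = [
    "GridSpec",
    "FieldSet",
    "CouplingParams",
    "IntegrationSpec",
    "SimulationResult",
    "BlowUpError",
    "laplacian_neumann",
    "euler_step",
    "simulate",
]

logger = logging.getLogger(__name__)


class BlowUpError(RuntimeError):
    """The explicit Euler update produced non-finite values.

    ``step`` carries the 1-based index of the offending step when raised
    from :func:`simulate` (``None`` from a bare :func:`euler_step`).
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice: ``nx`` columns (rostro-caudal axis), ``ny`` rows
    (dorso-ventral axis), spacing ``dx``.

    The default 200 x 100 domain stands for half of the dorsal flank of the
    fish, elongated along the body axis; with ``dx = 1`` the physical scale
    of the pattern is carried entirely by ``eta``.
    """

    nx: int = 200
    ny: int = 100
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if not (np.isfinite(self.dx) and self.dx > 0):
            raise ValueError(f"dx must be positive and finite, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (ny, nx): rows are the vertical axis."""
        return (self.ny, self.nx)


@dataclass(eq=False)
class FieldSet:
    """The four morphogen fields u1, v1, u2, v2 on a shared 2-D grid."""

    u1: np.ndarray
    v1: np.ndarray
    u2: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u1", "v1", "u2", "v2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        shape = self.u1.shape
        if self.u1.ndim != 2:
            raise ValueError(f"fields must be 2-D, got shape {shape}")
        for name in ("v1", "u2", "v2"):
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"field {name} has shape {getattr(self, name).shape}, "
                    f"expected {shape}"
                )
        for name in ("u1", "v1", "u2", "v2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in field {name}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u1.shape

    def copy(self) -> "FieldSet":
        return FieldSet(
            self.u1.copy(), self.v1.copy(), self.u2.copy(), self.v2.copy()
        )

    def __repr__(self) -> str:  # arrays are too noisy for the default repr
        ny, nx = self.shape
        return f"FieldSet(shape=({ny}, {nx}))"


@dataclass(frozen=True)
class CouplingParams:
    """Strength ``q`` of the pointwise linear exchange between the layers."""

    q: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.q):
            raise ValueError(f"coupling q must be finite, got {self.q}")


@dataclass(frozen=True)
class IntegrationSpec:
    """Explicit-Euler integration settings.

    The defaults -- ``dt = 0.01`` for 240 000 steps -- are the full
    production run at which the pattern fronts have reliably arrested;
    reduced step counts are used for quick looks and tests.
    """

    dt: float = 0.01
    n_steps: int = 240_000
    snapshot_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.snapshot_every is not None and self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1 or None")


@dataclass
class SimulationResult:
    """Final state plus sparse snapshots and a convergence indicator."""

    final: FieldSet
    n_steps: int
    #: max |change| of each field over the final Euler step; near-zero
    #: values indicate the fronts have arrested.
    last_step_delta: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)


def laplacian_neumann(fld: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Five-point Laplacian with mirror (zero-flux) boundaries.

    Ghost cells equal the adjacent interior cell, so the normal gradient
    vanishes at the boundary and the grid sum of the result telescopes to
    zero: the discrete scheme conserves total morphogen under diffusion.
    The summation order ``(up+down) + (left+right)`` makes the stencil
    bit-exactly equivariant under left-right and up-down reflections.
    """
    fld = np.asarray(fld, dtype=float)
    if fld.ndim != 2 or min(fld.shape) < 3:
        raise ValueError(f"field must be 2-D and at least 3x3, got {fld.shape}")
    p = np.pad(fld, 1, mode="edge")
    vert = p[:-2, 1:-1] + p[2:, 1:-1]
    horz = p[1:-1, :-2] + p[1:-1, 2:]
    return (vert + horz - 4.0 * fld) / (dx * dx)


def euler_step(
    state: FieldSet,
    p1: KineticParams,
    p2: KineticParams,
    c: CouplingParams,
    dt: float,
    dx: float = 1.0,
) -> FieldSet:
    """One explicit Euler update of all four fields (returns a new state)."""
    u1, v1, u2, v2 = state.u1, state.v1, state.u2, state.v2
    q = c.q
    # overflow here is a diagnosed failure mode (BlowUpError), not a warning
    with np.errstate(over="ignore", invalid="ignore"):
        f1, g1 = reaction_terms(u1, v1, p1)
        f2, g2 = reaction_terms(u2, v2, p2)
        cu = u2 - u1
        cv = v2 - v1
        nu1 = u1 + dt * (p1.D * laplacian_neumann(u1, dx) + p1.eta * f1 + q * cu)
        nv1 = v1 + dt * (laplacian_neumann(v1, dx) + p1.eta * g1 + q * cv)
        nu2 = u2 + dt * (p2.D * laplacian_neumann(u2, dx) + p2.eta * f2 - q * cu)
        nv2 = v2 + dt * (laplacian_neumann(v2, dx) + p2.eta * g2 - q * cv)
    try:
        return FieldSet(nu1, nv1, nu2, nv2)
    except ValueError as exc:
        raise BlowUpError(f"Euler update diverged: {exc}") from exc


def _make_kernel():
    """Compile the fused Euler stepper.

    The kernel repeats :func:`euler_step` in compiled code with the exact
    same per-cell arithmetic order (no fastmath), so its trajectories are
    bit-identical to the vectorised path; the tests assert this.  Returns
    ``None`` when numba is unavailable, in which case :func:`simulate`
    falls back to looping over :func:`euler_step`.
    """
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is a hard wheel to miss
        return None

    @numba.njit(cache=True)
    def kernel(u1, v1, u2, v2, n_steps, dt, dx,
               a1, b1, C1, h1, eta1, D1,
               a2, b2, C2, h2, eta2, D2, q):
        ny, nx = u1.shape
        cu1, cv1 = u1.copy(), v1.copy()
        cu2, cv2 = u2.copy(), v2.copy()
        nu1, nv1 = np.empty_like(u1), np.empty_like(u1)
        nu2, nv2 = np.empty_like(u1), np.empty_like(u1)
        for step in range(1, n_steps + 1):
            bad = False
            for i in range(ny):
                im = i - 1 if i > 0 else 0
                ip = i + 1 if i < ny - 1 else ny - 1
                for j in range(nx):
                    jm = j - 1 if j > 0 else 0
                    jp = j + 1 if j < nx - 1 else nx - 1
                    x1 = cu1[i, j]
                    y1 = cv1[i, j]
                    x2 = cu2[i, j]
                    y2 = cv2[i, j]
                    # mirror-cell Neumann 5-point stencil, (up+down)+(left+right)
                    lu1 = ((cu1[im, j] + cu1[ip, j])
                           + (cu1[i, jm] + cu1[i, jp]) - 4.0 * x1) / (dx * dx)
                    lv1 = ((cv1[im, j] + cv1[ip, j])
                           + (cv1[i, jm] + cv1[i, jp]) - 4.0 * y1) / (dx * dx)
                    lu2 = ((cu2[im, j] + cu2[ip, j])
                           + (cu2[i, jm] + cu2[i, jp]) - 4.0 * x2) / (dx * dx)
                    lv2 = ((cv2[im, j] + cv2[ip, j])
                           + (cv2[i, jm] + cv2[i, jp]) - 4.0 * y2) / (dx * dx)
                    f1 = x1 + a1 * y1 - C1 * x1 * y1 - x1 * (y1 * y1)
                    g1 = b1 * y1 + h1 * x1 + C1 * x1 * y1 + x1 * (y1 * y1)
                    f2 = x2 + a2 * y2 - C2 * x2 * y2 - x2 * (y2 * y2)
                    g2 = b2 * y2 + h2 * x2 + C2 * x2 * y2 + x2 * (y2 * y2)
                    cu = x2 - x1
                    cv = y2 - y1
                    r1 = x1 + dt * (D1 * lu1 + eta1 * f1 + q * cu)
                    r2 = y1 + dt * (lv1 + eta1 * g1 + q * cv)
                    r3 = x2 + dt * (D2 * lu2 + eta2 * f2 - q * cu)
                    r4 = y2 + dt * (lv2 + eta2 * g2 - q * cv)
                    nu1[i, j] = r1
                    nv1[i, j] = r2
                    nu2[i, j] = r3
                    nv2[i, j] = r4
                    if not (np.isfinite(r1) and np.isfinite(r2)
                            and np.isfinite(r3) and np.isfinite(r4)):
                        bad = True
            cu1, nu1 = nu1, cu1
            cv1, nv1 = nv1, cv1
            cu2, nu2 = nu2, cu2
            cv2, nv2 = nv2, cv2
            if bad:
                return cu1, cv1, cu2, cv2, step
        return cu1, cv1, cu2, cv2, 0

    return kernel


_KERNEL = _make_kernel()


def _advance(
    state: FieldSet,
    n_steps: int,
    p1: KineticParams,
    p2: KineticParams,
    c: CouplingParams,
    dt: float,
    dx: float,
    step_offset: int = 0,
) -> FieldSet:
    """Apply ``n_steps`` Euler updates (compiled kernel when available)."""
    if n_steps == 0:
        return state
    if _KERNEL is not None:
        u1, v1, u2, v2, bad = _KERNEL(
            state.u1, state.v1, state.u2, state.v2, n_steps, dt, dx,
            p1.a, p1.b, p1.C, p1.h, p1.eta, p1.D,
            p2.a, p2.b, p2.C, p2.h, p2.eta, p2.D, c.q,
        )
        if bad:
            step = step_offset + bad
            raise BlowUpError(
                f"Euler update diverged (non-finite values at step {step})",
                step=step,
            )
        return FieldSet(u1, v1, u2, v2)
    for k in range(1, n_steps + 1):
        try:
            state = euler_step(state, p1, p2, c, dt, dx)
        except BlowUpError as exc:
            step = step_offset + k
            raise BlowUpError(f"{exc} (at step {step})", step=step) from exc
    return state


def simulate(
    initial: FieldSet,
    p1: KineticParams,
    p2: KineticParams,
    c: CouplingParams,
    ispec: IntegrationSpec,
    grid: GridSpec | None = None,
) -> SimulationResult:
    """Integrate the coupled system for ``ispec.n_steps`` Euler steps.

    Deterministic given the initial state: all randomness lives in the
    initial-condition construction.  Snapshots are stored sparsely (every
    ``snapshot_every`` steps) so memory stays flat over long runs.  Raises
    :class:`BlowUpError` carrying the offending step index if the explicit
    scheme diverges.
    """
    dx = grid.dx if grid is not None else 1.0
    if grid is not None and initial.shape != grid.shape:
        raise ValueError(
            f"initial state shape {initial.shape} does not match grid "
            f"shape {grid.shape}"
        )
    n = ispec.n_steps
    state = initial.copy()
    if n == 0:
        return SimulationResult(final=state, n_steps=0)

    # advance in chunks whose boundaries are the snapshot steps plus n-1
    # (to measure the final-step change) and n
    targets = {n - 1, n}
    if ispec.snapshot_every:
        targets.update(range(ispec.snapshot_every, n + 1, ispec.snapshot_every))
    targets.discard(0)
    snapshots: list[tuple[int, FieldSet]] = []
    prev = state  # correct when n == 1 (step n-1 = 0 is the initial state)
    done = 0
    for t in sorted(targets):
        state = _advance(state, t - done, p1, p2, c, ispec.dt, dx, done)
        done = t
        if ispec.snapshot_every and t % ispec.snapshot_every == 0:
            snapshots.append((t, state.copy()))
        if t == n - 1:
            prev = state
    delta = {
        name: float(np.abs(getattr(state, name) - getattr(prev, name)).max())
        for name in ("u1", "v1", "u2", "v2")
    }
    logger.info(
        "simulate: %d steps done, last-step max |delta| %s",
        n,
        {k: f"{v:.3e}" for k, v in delta.items()},
    )
    return SimulationResult(
        final=state, n_steps=n, last_step_delta=delta, snapshots=snapshots
    )
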