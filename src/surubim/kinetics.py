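"""Local BVAM reaction kinetics: fixed points, Jacobians and linear stability.

The BVAM (Barrio-Aragon-Varea-Maini) system is the most general two-species
reaction-diffusion model with quadratic and cubic nonlinearities whose
kinetics conserve mass: the nonlinear terms of the two rates cancel exactly,
so ``f + g`` is linear in ``(u, v)``.  The fields ``u`` and ``v`` are
morphogen densities measured from an average level, so they take positive or
negative values for local excess or deficiency.

This module implements the local (non-spatial) kinetics

    f(u, v) = u + a*v - C*u*v - u*v**2
    g(u, v) = b*v + h*u + C*u*v + u*v**2

together with their analytical backbone: the reduction of ``f = g = 0`` to a
quadratic (giving one, two or three real fixed points), Jacobians, stability
labels and the per-layer dispersion relation.  The spatial simulator applies
the size factor ``eta`` and the diffusion terms; they do not appear in
``reaction_terms``.

The regime of interest here is bistable -- two mirror-like nonzero fixed
points separated by a saddle at the origin -- which produces travelling
fronts rather than Turing modes; the front velocity is regulated by the
quadratic/cubic ratio ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "FixedPoint",
    "PARAMS_TABLE1",
    "RESIDUAL_TOL",
    "STABILITY_TIE_TOL",
    "reaction_terms",
    "fixed_points",
    "jacobian",
    "classify_stability",
    "stability_from_jacobian",
    "dispersion_relation",
]

#: Residual |f|, |g| below which a point is accepted as a fixed point.
RESIDUAL_TOL = 1e-10

#: |Re(lambda)| below which an eigenvalue is treated as marginal.
STABILITY_TIE_TOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Per-layer constants of the BVAM kinetics.

    Parameters
    ----------
    a, b, h : float
        Dimensionless kinetic constants of the linear part.
    C : float
        Ratio of the quadratic to the cubic nonlinearity; controls the
        velocity of bistable fronts (C = 0 makes the kinetics odd-symmetric
        and fronts stationary by symmetry).
    eta : float
        Dimensionless size/rate scale of the system (applied by the
        spatial stepper). Must be positive.
    D : float
        Ratio of the diffusion coefficients D_u / D_v. Must be positive.
    """

    a: float
    b: float
    C: float
    h: float
    eta: float
    D: float

    def __post_init__(self) -> None:
        vals = [self.a, self.b, self.C, self.h, self.eta, self.D]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"kinetic parameters must be finite, got {self}")
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.h == -1.0:
            raise ValueError(
                "degenerate kinetics: 1 + h = 0 breaks the fixed-point "
                "reduction u = -(a+b)/(1+h) * v; choose h != -1"
            )


#: Reference parameter set of the bistable regime used throughout
#: (named preset "table1" in the configuration layer).
PARAMS_TABLE1 = KineticParams(
    a=0.05775, b=-0.30525, C=0.02, h=-1.3, eta=0.47, D=0.466
)


@dataclass(frozen=True)
class FixedPoint:
    """A root of f = g = 0 with its linear-stability classification."""

    u: float
    v: float
    stability: str
    eigenvalues: tuple = field(repr=False)
    #: True when the reduced quadratic has a double root (saddle-node
    #: boundary); the point then stands for two coincident roots.
    degenerate: bool = False


def _as_finite(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {name}")
    return arr if arr.ndim else float(arr)


def reaction_terms(u, v, p: KineticParams):
    """Evaluate the local kinetic rates (f, g) at (u, v).

    Accepts scalars or arrays (broadcast elementwise).  The size factor
    ``eta`` and all spatial terms are applied by the stepper, not here.
    """
    u = _as_finite(u, "u")
    v = _as_finite(v, "v")
    f = u + p.a * v - p.C * u * v - u * v**2
    g = p.b * v + p.h * u + p.C * u * v + u * v**2
    return f, g


def jacobian(u: float, v: float, p: KineticParams) -> np.ndarray:
    """Jacobian of (f, g) with respect to (u, v) at a point."""
    u = float(_as_finite(u, "u"))
    v = float(_as_finite(v, "v"))
    return np.array(
        [
            [1.0 - p.C * v - v**2, p.a - p.C * u - 2.0 * u * v],
            [p.h + p.C * v + v**2, p.b + p.C * u + 2.0 * u * v],
        ]
    )


def stability_from_jacobian(J: np.ndarray, tie_tol: float = STABILITY_TIE_TOL):
    """Classify a 2x2 Jacobian by its eigenvalues.

    Returns ``(label, eigenvalues)`` where label is one of ``stable-node``,
    ``stable-focus``, ``saddle``, ``unstable-node``, ``unstable-focus`` or
    ``center/marginal``.  Real parts within ``tie_tol`` of zero are treated
    as marginal so that labelling is reproducible near bifurcations.
    """
    eigs = np.linalg.eigvals(np.asarray(J, dtype=float))
    re = eigs.real
    oscillatory = np.any(np.abs(eigs.imag) > tie_tol)
    if np.any(np.abs(re) < tie_tol):
        return "center/marginal", eigs
    if re[0] * re[1] < 0:
        return "saddle", eigs
    if np.all(re < 0):
        return ("stable-focus" if oscillatory else "stable-node"), eigs
    return ("unstable-focus" if oscillatory else "unstable-node"), eigs


def classify_stability(fp, p: KineticParams):
    """Stability label and eigenvalues of the kinetics linearised at ``fp``.

    ``fp`` may be a :class:`FixedPoint` or a ``(u, v)`` pair; it must satisfy
    the fixed-point residual invariant.
    """
    u, v = (fp.u, fp.v) if isinstance(fp, FixedPoint) else fp
    f, g = reaction_terms(u, v, p)
    if max(abs(f), abs(g)) > 1e-8:
        raise ValueError(
            f"({u}, {v}) is not a fixed point: residual ({f:.3g}, {g:.3g})"
        )
    return stability_from_jacobian(jacobian(u, v, p))


def _newton_refine(u: float, v: float, p: KineticParams, n_iter: int = 25):
    """Polish a root of f = g = 0 by Newton iteration.

    Guards against cancellation error in the quadratic-formula seed; the
    Jacobian is nonsingular away from the saddle-node boundary.
    """
    for _ in range(n_iter):
        f, g = reaction_terms(u, v, p)
        if max(abs(f), abs(g)) < 1e-14:
            break
        J = jacobian(u, v, p)
        try:
            du, dv = np.linalg.solve(J, [-f, -g])
        except np.linalg.LinAlgError:
            break
        u, v = u + du, v + dv
    return u, v


def fixed_points(p: KineticParams) -> list[FixedPoint]:
    """All real fixed points of the kinetics, with stability labels.

    Summing the two rates cancels the nonlinear terms, so on any fixed point
    ``(1+h)u + (a+b)v = 0``, i.e. ``u = k v`` with ``k = -(a+b)/(1+h)``.
    Substituting into ``f = 0`` leaves ``v (k v^2 + C k v - (k+a)) = 0``:
    the origin plus the real roots of a quadratic.  Returns one, two
    (double root, flagged degenerate) or three points, Newton-refined to a
    kinetics residual below :data:`RESIDUAL_TOL` and sorted by ``u``.
    """
    if p.h == -1.0:  # unreachable through KineticParams, kept for raw use
        raise ValueError("1 + h = 0: fixed-point reduction invalid")
    k = -(p.a + p.b) / (1.0 + p.h)

    points: list[FixedPoint] = []
    label, eigs = stability_from_jacobian(jacobian(0.0, 0.0, p))
    points.append(FixedPoint(0.0, 0.0, label, tuple(eigs)))

    if k != 0.0:
        # v^2 + C v - (k + a)/k = 0
        c0 = -(k + p.a) / k
        disc = p.C * p.C - 4.0 * c0
        if abs(disc) < 1e-14:
            roots = [(-p.C / 2.0, True)]
        elif disc > 0:
            s = np.sqrt(disc)
            roots = [((-p.C + s) / 2.0, False), ((-p.C - s) / 2.0, False)]
        else:
            roots = []
        for v0, degenerate in roots:
            if abs(v0) < 1e-12:  # coincides with the origin
                continue
            u, v = _newton_refine(k * v0, v0, p)
            f, g = reaction_terms(u, v, p)
            if max(abs(f), abs(g)) > RESIDUAL_TOL:
                raise ArithmeticError(
                    f"fixed-point refinement failed at ({u}, {v}): "
                    f"residual ({f:.3g}, {g:.3g})"
                )
            label, eigs = stability_from_jacobian(jacobian(u, v, p))
            points.append(FixedPoint(u, v, label, tuple(eigs), degenerate))

    points.sort(key=lambda fp: fp.u)
    return points


def dispersion_relation(fp, p: KineticParams, k2_values) -> np.ndarray:
    """Largest growth rate Re(lambda) versus squared wavenumber at ``fp``.

    For each ``k2`` the eigenvalues of ``eta * J(fp) - k2 * diag(D, 1)`` are
    computed: the linearisation of one uncoupled layer about a homogeneous
    state.  The inter-layer coupling ``q`` is excluded by construction.
    Used to verify that the working regime sits away from a Turing
    instability (the homogeneous state of interest is already unstable at
    ``k2 = 0``), not to tune parameters.
    """
    u, v = (fp.u, fp.v) if isinstance(fp, FixedPoint) else fp
    J = p.eta * jacobian(u, v, p)
    out = np.empty(len(k2_values), dtype=float)
    for i, k2 in enumerate(np.asarray(k2_values, dtype=float)):
        M = J - k2 * np.diag([p.D, 1.0])
        out[i] = np.linalg.eigvals(M).real.max()
    return out
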