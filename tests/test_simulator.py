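"""Spatial stepper: stencil, oracle equivalence, symmetries, convergence."""

import numpy as np
import pytest

from surubim import (
    PARAMS_TABLE1,
    BlowUpError,
    CouplingParams,
    FieldSet,
    GridSpec,
    IntegrationSpec,
    KineticParams,
    euler_step,
    fixed_points,
    laplacian_neumann,
    simulate,
)
from surubim.simulator import _advance


def euler_step_loop_oracle(state, p1, p2, c, dt, dx):
    """Scalar cell-by-cell reference stepper (quadruple loop).

    Mirrors the production arithmetic expression-for-expression so the
    comparison is bit-exact, while sharing no array code with it.
    """
    ny, nx = state.shape
    out = [np.empty((ny, nx)) for _ in range(4)]
    u1, v1, u2, v2 = state.u1, state.v1, state.u2, state.v2
    q = c.q
    for i in range(ny):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < ny - 1 else ny - 1
        for j in range(nx):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < nx - 1 else nx - 1

            def lap(f):
                return ((f[im, j] + f[ip, j]) + (f[i, jm] + f[i, jp])
                        - 4.0 * f[i, j]) / (dx * dx)

            x1, y1 = u1[i, j], v1[i, j]
            x2, y2 = u2[i, j], v2[i, j]
            f1 = x1 + p1.a * y1 - p1.C * x1 * y1 - x1 * (y1 * y1)
            g1 = p1.b * y1 + p1.h * x1 + p1.C * x1 * y1 + x1 * (y1 * y1)
            f2 = x2 + p2.a * y2 - p2.C * x2 * y2 - x2 * (y2 * y2)
            g2 = p2.b * y2 + p2.h * x2 + p2.C * x2 * y2 + x2 * (y2 * y2)
            cu = x2 - x1
            cv = y2 - y1
            out[0][i, j] = x1 + dt * (p1.D * lap(u1) + p1.eta * f1 + q * cu)
            out[1][i, j] = y1 + dt * (lap(v1) + p1.eta * g1 + q * cv)
            out[2][i, j] = x2 + dt * (p2.D * lap(u2) + p2.eta * f2 - q * cu)
            out[3][i, j] = y2 + dt * (lap(v2) + p2.eta * g2 - q * cv)
    return FieldSet(*out)


def assert_states_equal(a, b, exact=True):
    for name in ("u1", "v1", "u2", "v2"):
        x, y = getattr(a, name), getattr(b, name)
        if exact:
            assert np.array_equal(x, y), f"field {name} differs"
        else:
            assert np.allclose(x, y), f"field {name} differs"


class TestLaplacian:
    def test_annihilates_constants(self):
        assert np.all(laplacian_neumann(np.full((5, 7), 3.25)) == 0.0)

    def test_unit_spike_stencil(self):
        f = np.zeros((7, 7))
        f[3, 3] = 1.0
        lap = laplacian_neumann(f, dx=1.0)
        assert lap[3, 3] == -4.0
        for i, j in [(2, 3), (4, 3), (3, 2), (3, 4)]:
            assert lap[i, j] == 1.0
        assert np.count_nonzero(lap) == 5

    def test_zero_flux_conserves_total(self, rng):
        """Mirror boundaries telescope: the grid sum of the Laplacian
        vanishes, i.e. diffusion moves morphogen without creating it."""
        for _ in range(5):
            f = rng.normal(size=(12, 17))
            assert abs(laplacian_neumann(f).sum()) < 1e-10

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            laplacian_neumann(np.zeros((2, 5)))


class TestEulerStep:
    def test_uniform_origin_state_is_exactly_stationary(self, table1):
        state = FieldSet(*(np.zeros((6, 6)) for _ in range(4)))
        new = euler_step(state, table1, table1, CouplingParams(0.0), 0.01)
        assert_states_equal(state, new)

    def test_uniform_fixed_point_state_is_stationary(self, table1):
        fp = [f for f in fixed_points(table1) if f.u > 0][0]
        shape = (6, 6)
        state = FieldSet(
            np.full(shape, fp.u), np.full(shape, fp.v),
            np.full(shape, fp.u), np.full(shape, fp.v),
        )
        new = euler_step(state, table1, table1, CouplingParams(0.0), 0.01)
        for name in ("u1", "v1", "u2", "v2"):
            assert np.allclose(
                getattr(new, name), getattr(state, name), atol=1e-12
            )

    def test_identical_layers_make_coupling_inert(self, table1, rng):
        f = rng.uniform(-1, 1, size=(8, 8))
        g = rng.uniform(-1, 1, size=(8, 8))
        state = FieldSet(f, g, f.copy(), g.copy())
        coupled = euler_step(state, table1, table1, CouplingParams(0.7), 0.01)
        uncoupled = euler_step(state, table1, table1, CouplingParams(0.0), 0.01)
        assert_states_equal(coupled, uncoupled)

    def test_matches_scalar_loop_oracle_over_100_steps(self, table1, random_state):
        """Vectorised stepper vs quadruple-loop reference: bit-identical."""
        c = CouplingParams(0.001)
        vec, loop = random_state, random_state
        for _ in range(100):
            vec = euler_step(vec, table1, table1, c, 0.01)
            loop = euler_step_loop_oracle(loop, table1, table1, c, 0.01, 1.0)
        assert_states_equal(vec, loop)

    def test_compiled_path_matches_vectorised_path(self, table1, random_state):
        c = CouplingParams(0.0013)
        vec = random_state
        for _ in range(50):
            vec = euler_step(vec, table1, table1, c, 0.01)
        fast = _advance(random_state.copy(), 50, table1, table1, c, 0.01, 1.0)
        assert_states_equal(vec, fast)

    def test_blowup_raises(self, table1, random_state):
        with pytest.raises(BlowUpError):
            state = random_state
            for _ in range(100):
                state = euler_step(state, table1, table1, CouplingParams(0.0), 50.0)


class TestSimulate:
    def test_zero_steps_returns_initial(self, table1, random_state):
        res = simulate(random_state, table1, table1, CouplingParams(0.0),
                       IntegrationSpec(n_steps=0))
        assert_states_equal(res.final, random_state)

    def test_simulate_is_repeated_euler_step(self, table1, random_state):
        c = CouplingParams(0.002)
        res = simulate(random_state, table1, table1, c,
                       IntegrationSpec(n_steps=37))
        manual = random_state
        for _ in range(37):
            manual = euler_step(manual, table1, table1, c, 0.01)
        assert_states_equal(res.final, manual)

    def test_deterministic_given_state(self, table1, random_state):
        spec = IntegrationSpec(n_steps=200)
        a = simulate(random_state, table1, table1, CouplingParams(0.001), spec)
        b = simulate(random_state, table1, table1, CouplingParams(0.001), spec)
        assert_states_equal(a.final, b.final)

    def test_snapshots_at_requested_interval(self, table1, random_state):
        res = simulate(random_state, table1, table1, CouplingParams(0.0),
                       IntegrationSpec(n_steps=100, snapshot_every=30))
        assert [s for s, _ in res.snapshots] == [30, 60, 90]
        mid = simulate(random_state, table1, table1, CouplingParams(0.0),
                       IntegrationSpec(n_steps=60))
        assert_states_equal(res.snapshots[1][1], mid.final)

    def test_blowup_carries_step_index(self, table1, random_state):
        with pytest.raises(BlowUpError) as err:
            simulate(random_state, table1, table1, CouplingParams(0.0),
                     IntegrationSpec(dt=50.0, n_steps=1000))
        assert err.value.step is not None
        assert 1 <= err.value.step < 1000

    def test_last_step_delta_reported(self, table1, random_state):
        res = simulate(random_state, table1, table1, CouplingParams(0.0),
                       IntegrationSpec(n_steps=10))
        assert set(res.last_step_delta) == {"u1", "v1", "u2", "v2"}
        assert all(v >= 0 for v in res.last_step_delta.values())

    def test_single_step_delta_measured_from_initial(self, table1, random_state):
        res = simulate(random_state, table1, table1, CouplingParams(0.0),
                       IntegrationSpec(n_steps=1))
        one = euler_step(random_state, table1, table1, CouplingParams(0.0), 0.01)
        expect = float(np.abs(one.u2 - random_state.u2).max())
        assert res.last_step_delta["u2"] == expect


class TestTrajectoryInvariants:
    def test_q_zero_decouples_layers_bitwise(self, table1, rng):
        """With q=0 the outer layer's trajectory is identical whether the
        inner layer is present or replaced by unrelated fields."""
        shape = (10, 12)
        u2, v2 = rng.uniform(-1, 1, (2,) + shape)
        other1 = rng.uniform(-1, 1, (2,) + shape)
        other2 = rng.uniform(-1, 1, (2,) + shape)
        spec = IntegrationSpec(n_steps=300)
        a = simulate(FieldSet(other1[0], other1[1], u2, v2), table1, table1,
                     CouplingParams(0.0), spec)
        b = simulate(FieldSet(other2[0], other2[1], u2, v2), table1, table1,
                     CouplingParams(0.0), spec)
        assert np.array_equal(a.final.u2, b.final.u2)
        assert np.array_equal(a.final.v2, b.final.v2)

    def test_odd_symmetry_of_trajectories_without_quadratic_term(self, rng):
        """With C=0 the kinetics are odd, so negating the initial fields
        negates the whole trajectory bit-for-bit."""
        p = KineticParams(a=0.05775, b=-0.30525, C=0.0, h=-1.3, eta=0.47, D=0.466)
        fields = rng.uniform(-1, 1, (4, 9, 11))
        spec = IntegrationSpec(n_steps=400)
        pos = simulate(FieldSet(*fields), p, p, CouplingParams(0.003), spec)
        neg = simulate(FieldSet(*(-fields)), p, p, CouplingParams(0.003), spec)
        for name in ("u1", "v1", "u2", "v2"):
            assert np.array_equal(
                getattr(neg.final, name), -getattr(pos.final, name)
            )

    def test_reflection_equivariance(self, table1, rng):
        """Zero-flux boundaries preserve left-right mirror symmetry
        exactly (the stencil sums opposite neighbours first)."""
        fields = rng.uniform(-1, 1, (4, 9, 14))
        spec = IntegrationSpec(n_steps=250)
        fwd = simulate(FieldSet(*fields), table1, table1,
                       CouplingParams(0.002), spec)
        rev = simulate(FieldSet(*fields[:, :, ::-1].copy()), table1, table1,
                       CouplingParams(0.002), spec)
        for name in ("u1", "v1", "u2", "v2"):
            assert np.array_equal(
                getattr(rev.final, name), getattr(fwd.final, name)[:, ::-1]
            )


class TestConvergence:
    def test_step_halving_changes_little(self, table1, seeded_initial_state):
        """Halving dt (20k steps at 0.01 vs 40k at 0.005) moves the final
        fields by less than 0.05 in sup-norm: the explicit scheme is
        resolving the front dynamics, not just stable."""
        grid, state = seeded_initial_state
        c = CouplingParams(0.0)
        coarse = simulate(state, table1, table1, c,
                          IntegrationSpec(dt=0.01, n_steps=20000), grid)
        fine = simulate(state, table1, table1, c,
                        IntegrationSpec(dt=0.005, n_steps=40000), grid)
        sup = max(
            np.abs(getattr(coarse.final, n) - getattr(fine.final, n)).max()
            for n in ("u1", "v1", "u2", "v2")
        )
        assert sup < 0.05

    def test_fields_stay_in_stability_envelope(self, table1, seeded_initial_state):
        """Morphogen deviations remain within [-3, 3] for a long seeded
        run (empirical boundedness of the bistable regime)."""
        grid, state = seeded_initial_state
        res = simulate(state, table1, table1, CouplingParams(0.001),
                       IntegrationSpec(n_steps=40000), grid)
        for name in ("u1", "v1", "u2", "v2"):
            arr = getattr(res.final, name)
            assert np.abs(arr).max() <= 3.0


class TestSpecs:
    def test_grid_rejects_small_and_bad_dx(self):
        with pytest.raises(ValueError):
            GridSpec(2, 10)
        with pytest.raises(ValueError):
            GridSpec(10, 10, dx=0.0)

    def test_fieldset_shape_and_finiteness(self):
        with pytest.raises(ValueError):
            FieldSet(np.zeros((4, 4)), np.zeros((4, 5)),
                     np.zeros((4, 4)), np.zeros((4, 4)))
        bad = np.zeros((4, 4))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            FieldSet(bad, np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))

    def test_integration_spec_validation(self):
        with pytest.raises(ValueError):
            IntegrationSpec(dt=0.0)
        with pytest.raises(ValueError):
            IntegrationSpec(n_steps=-1)
        with pytest.raises(ValueError):
            IntegrationSpec(snapshot_every=0)
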