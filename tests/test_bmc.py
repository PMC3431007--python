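"""Generator matrices, matrix-exponential propagation and the ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from pulsedcest.bmc import (
    InvalidModelError,
    Pool,
    PoolSystem,
    crush,
    expm_affine,
    generator,
    mt_saturation_rate,
    propagate,
    steady_state,
)


@pytest.fixture(scope="module")
def water_only():
    return PoolSystem([Pool("w", t1=3.0, t2=0.060, m0=100.0)], b0=4.7)


class TestGenerator:
    def test_free_relaxation_eigenvalues(self, water_only):
        A, b = generator(water_only, 0.0, 0.0)
        eig = np.sort(np.linalg.eigvals(A).real)
        np.testing.assert_allclose(eig, sorted([-1 / 0.060, -1 / 0.060, -1 / 3.0]), rtol=1e-12)

    def test_zero_exchange_decouples(self, two_pool_system):
        pools = [
            two_pool_system.pools[0],
            Pool("labile", t1=1.0, t2=0.0085, m0=0.33, exchange_rate=0.0, shift_ppm=1.9),
        ]
        system = PoolSystem(pools, b0=4.7)
        A, _ = generator(system, 500.0, 1.0)
        assert np.all(A[:3, 3:] == 0)
        assert np.all(A[3:, :3] == 0)

    def test_equilibrium_is_fixed_point(self, three_pool_system):
        A, b = generator(three_pool_system, 0.0, 2.5)
        m_eq = three_pool_system.equilibrium()
        np.testing.assert_allclose(A @ m_eq + b, 0.0, atol=1e-12)

    def test_batched_matches_scalar(self, three_pool_system):
        omega1 = np.array([0.0, 100.0, 400.0])
        offs = np.array([-1.0, 0.0, 1.9])
        A, b = generator(three_pool_system, omega1[:, None], offs[None, :])
        for i, w1 in enumerate(omega1):
            for j, o in enumerate(offs):
                As, bs = generator(three_pool_system, w1, o)
                np.testing.assert_allclose(A[i, j], As)
                np.testing.assert_allclose(b[i, j], bs)

    def test_negative_relaxation_rejected(self):
        with pytest.raises(InvalidModelError):
            Pool("w", t1=-1.0, t2=0.1, m0=1.0)


class TestMtSaturationRate:
    def test_zero_rf(self):
        assert mt_saturation_rate(0.0, 100.0, 10e-6) == 0.0

    def test_lineshape_peak_closed_form(self):
        w1, t2 = 300.0, 10e-6
        expected = np.pi * w1**2 * t2 / np.sqrt(2 * np.pi)
        assert mt_saturation_rate(w1, 0.0, t2) == pytest.approx(expected, rel=1e-12)

    def test_even_in_offset(self):
        d = np.linspace(0, 5e5, 7)
        np.testing.assert_allclose(
            mt_saturation_rate(300.0, d, 10e-6), mt_saturation_rate(300.0, -d, 10e-6)
        )


class TestPropagate:
    def test_zero_duration_identity(self, three_pool_system):
        m = three_pool_system.equilibrium() * 0.7
        np.testing.assert_array_equal(propagate(three_pool_system, 100.0, 1.0, 0.0, m), m)

    def test_t1_recovery_closed_form(self, water_only):
        m0 = np.zeros(3)
        m = propagate(water_only, 0.0, 0.0, 3.0, m0)
        assert m[2] / 100.0 == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_matches_scipy_expm(self, three_pool_system):
        A, b = generator(three_pool_system, 600.0, 1.3)
        d = A.shape[0]
        aug = np.zeros((d + 1, d + 1))
        aug[:d, :d], aug[:d, d] = A, b
        E = expm(aug * 0.017)
        P, q = expm_affine(A, b, 0.017)
        np.testing.assert_allclose(P, E[:d, :d], atol=1e-13)
        np.testing.assert_allclose(q, E[:d, d], atol=1e-13)

    def test_ode_oracle_three_pool(self, three_pool_system):
        A, b = generator(three_pool_system, 450.0, 2.1)
        m0 = three_pool_system.equilibrium()
        sol = solve_ivp(
            lambda t, m: A @ m + b, (0, 0.5), m0, rtol=1e-12, atol=1e-12, method="LSODA"
        )
        m_exact = propagate(three_pool_system, 450.0, 2.1, 0.5, m0)
        np.testing.assert_allclose(m_exact, sol.y[:, -1], atol=1e-8)

    def test_steady_state_long_time_limit(self, three_pool_system):
        m0 = three_pool_system.equilibrium()
        m_long = propagate(three_pool_system, 350.0, 1.9, 60.0, m0)
        np.testing.assert_allclose(m_long, steady_state(three_pool_system, 350.0, 1.9), atol=1e-8)

    def test_independent_relaxation_without_exchange(self):
        system = PoolSystem(
            [
                Pool("w", t1=2.0, t2=0.05, m0=10.0),
                Pool("labile", t1=0.7, t2=0.01, m0=1.0, exchange_rate=0.0, shift_ppm=1.9),
            ],
            b0=4.7,
        )
        m0 = np.array([0.3, -0.2, 4.0, 0.05, 0.1, 0.2])
        t = 0.37
        m = propagate(system, 0.0, 0.0, t, m0)
        # each pool relaxes mono-exponentially in its own rotating frame
        for i, p in enumerate(system.pools):
            z0, z = m0[3 * i + 2], m[3 * i + 2]
            assert z == pytest.approx(p.m0 + (z0 - p.m0) * np.exp(-t / p.t1), rel=1e-9)
            r0 = np.hypot(m0[3 * i], m0[3 * i + 1])
            r = np.hypot(m[3 * i], m[3 * i + 1])
            assert r == pytest.approx(r0 * np.exp(-t / p.t2), rel=1e-9)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    omega1=st.floats(0.0, 2000.0),
    offset=st.floats(-4.0, 4.0),
    c_labile=st.floats(0.0, 500.0),
    duration=st.floats(1e-4, 0.2),
)
def test_expm_agrees_with_ode_oracle(omega1, offset, c_labile, duration):
    """Matrix-exponential and adaptive-ODE propagation agree across parameter draws."""
    system = PoolSystem(
        [
            Pool("w", t1=3.0, t2=0.060, m0=100.0),
            Pool("labile", t1=1.0, t2=0.0085, m0=0.33, exchange_rate=c_labile, shift_ppm=1.9),
            Pool("mt", t1=1.0, t2=10e-6, m0=2.0, exchange_rate=30.0),
        ],
        b0=4.7,
    )
    A, b = generator(system, omega1, offset)
    m0 = system.equilibrium()
    sol = solve_ivp(lambda t, m: A @ m + b, (0, duration), m0, rtol=1e-11, atol=1e-11)
    m = propagate(system, omega1, offset, duration, m0)
    np.testing.assert_allclose(m, sol.y[:, -1], atol=2e-8)


class TestCrush:
    def test_equilibrium_unchanged(self, three_pool_system):
        m = three_pool_system.equilibrium()
        np.testing.assert_array_equal(crush(three_pool_system, m), m)

    def test_longitudinal_preserved_idempotent(self, three_pool_system):
        rng = np.random.default_rng(7)
        m = rng.normal(size=three_pool_system.dim)
        c = crush(three_pool_system, m)
        np.testing.assert_array_equal(c[2], m[2])
        np.testing.assert_array_equal(c[5], m[5])
        np.testing.assert_array_equal(c[6], m[6])
        assert c[0] == c[1] == c[3] == c[4] == 0.0
        np.testing.assert_array_equal(crush(three_pool_system, c), c)


def test_superposition_of_homogeneous_part(three_pool_system):
    """Propagation is linear-affine: differences from any reference propagate linearly."""
    rng = np.random.default_rng(3)
    m1, m2 = rng.normal(size=(2, three_pool_system.dim))
    args = (three_pool_system, 240.0, 0.7, 0.05)
    p1 = propagate(*args, m1)
    p2 = propagate(*args, m2)
    p12 = propagate(*args, m1 + 0.5 * (m2 - m1))
    np.testing.assert_allclose(p12, p1 + 0.5 * (p2 - p1), atol=1e-10)


def test_pool_system_validation():
    with pytest.raises(InvalidModelError):
        PoolSystem([Pool("labile", 1.0, 0.01, 1.0)], b0=4.7)
    with pytest.raises(InvalidModelError):
        PoolSystem(
            [Pool("w", 3.0, 0.06, 100.0), Pool("w", 3.0, 0.06, 100.0)], b0=4.7
        )
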