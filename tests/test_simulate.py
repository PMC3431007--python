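"""Z-spectrum simulation under pulsed, AF and AP saturation schemes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pulsedcest import (
    Pool,
    PoolSystem,
    PulseTrain,
    ZSpectrum,
    peak_amplitude,
    simulate_cw,
    simulate_equivalent,
    simulate_pulsed,
)
from pulsedcest.bmc import crush_matrix, generator
from pulsedcest.pulses import GAMMA_RAD_PER_T, gaussian_envelope

class TestZSpectrum:
    def test_validation(self):
        with pytest.raises(ValueError):
            ZSpectrum([1.0, 0.5], [0.9])
        with pytest.raises(ValueError):
            ZSpectrum([1.0, 0.5], [0.9, 0.8])  # decreasing offsets
        with pytest.raises(ValueError):
            ZSpectrum([0.0, 1.0], [2.0, 0.5])  # not a normalized signal

    def test_interp_range_check(self):
        zs = ZSpectrum([-1.0, 0.0, 1.0], [0.9, 0.2, 0.9])
        assert zs.interp(0.5) == pytest.approx(0.55)
        with pytest.raises(ValueError):
            zs.interp(1.5)


class TestPulsed:
    def test_zero_flip_angle_null_saturation(self, two_pool_system, offsets_41):
        train = PulseTrain("gaussian", 0.0, 0.040, 0.5, n_pulses=50)
        zs = simulate_pulsed(two_pool_system, train, 8, offsets_41)
        np.testing.assert_allclose(zs.signal, 1.0, atol=1e-12)

    def test_rect_full_duty_degenerates_to_cw(self, two_pool_system):
        offsets = np.linspace(-3.0, 3.0, 13)
        train = PulseTrain("rect", 180.0, 0.040, 1.0, n_pulses=50, crushers=False)
        pulsed = simulate_pulsed(two_pool_system, train, 1, offsets)
        cw = simulate_cw(two_pool_system, peak_amplitude(train), train.t_sat, offsets)
        np.testing.assert_allclose(pulsed.signal, cw.signal, atol=1e-10)

    def test_signals_physical(self, two_pool_system, invitro_train, offsets_41):
        zs = simulate_pulsed(two_pool_system, invitro_train, 32, offsets_41)
        assert np.all(zs.signal >= 0.0) and np.all(zs.signal <= 1.0)

    def test_ode_oracle_time_varying_envelope(self, two_pool_system, invitro_train):
        """Full pulsed propagation vs adaptive integration of the continuous envelope."""
        offsets = [-1.9, 0.19, 1.9]
        disc = simulate_pulsed(two_pool_system, invitro_train, 1024, offsets)
        peak = peak_amplitude(invitro_train)
        t_p, delay = invitro_train.t_p, invitro_train.delay
        C = crush_matrix(two_pool_system)
        for k, off in enumerate(offsets):
            m = two_pool_system.equilibrium()

            def rhs(t, y, off=off):
                w1 = GAMMA_RAD_PER_T * gaussian_envelope(t, t_p, peak)
                A, b = generator(two_pool_system, w1, off)
                return A @ y + b

            A_d, b_d = generator(two_pool_system, 0.0, off)
            for p in range(invitro_train.n_pulses):
                m = solve_ivp(rhs, (0, t_p), m, rtol=1e-11, atol=1e-12, method="LSODA").y[:, -1]
                if p < invitro_train.n_pulses - 1:
                    m = solve_ivp(
                        lambda t, y: A_d @ y + b_d, (0, delay), m, rtol=1e-11, atol=1e-12
                    ).y[:, -1]
                    m = C @ m
            assert disc.signal[k] == pytest.approx(m[2] / 100.0, abs=1e-6)


class TestCw:
    def test_zero_power_or_time(self, two_pool_system, offsets_41):
        for b1, t in ((0.0, 2.0), (1e-6, 0.0)):
            zs = simulate_cw(two_pool_system, b1, t, offsets_41)
            np.testing.assert_allclose(zs.signal, 1.0, atol=1e-12)

    def test_direct_saturation_symmetry(self, offsets_41):
        """Without a labile pool the z-spectrum is mirror symmetric about water."""
        system = PoolSystem([Pool("w", 3.0, 0.060, 100.0)], b0=4.7)
        zs = simulate_cw(system, 0.5e-6, 2.0, offsets_41)
        np.testing.assert_allclose(zs.signal, zs.signal[::-1], atol=1e-12)


class TestEquivalent:
    def test_ap_exact_for_rect_full_duty(self, two_pool_system):
        offsets = np.linspace(-3.0, 3.0, 13)
        train = PulseTrain("rect", 180.0, 0.040, 1.0, n_pulses=50, crushers=False)
        ap = simulate_equivalent(two_pool_system, train, "ap", offsets)
        pulsed = simulate_pulsed(two_pool_system, train, 1, offsets)
        np.testing.assert_allclose(ap.signal, pulsed.signal, atol=1e-10)

    def test_ap_deviations_localized_near_resonances(
        self, two_pool_system, invitro_train, offsets_41
    ):
        """AP tracks the discretized spectrum except near 0 ppm and the labile shift."""
        disc = simulate_pulsed(two_pool_system, invitro_train, 32, offsets_41)
        ap = simulate_equivalent(two_pool_system, invitro_train, "ap", offsets_41)
        dev = np.abs(ap.signal - disc.signal)
        near = (np.abs(offsets_41) <= 0.4) | (np.abs(offsets_41 - 1.9) <= 0.4)
        assert dev[near].max() > dev[~near].max()
        # the largest deviations sit inside the highlighted regions
        top = np.argsort(dev)[-2:]
        assert near[top].all()

    def test_af_worse_than_ap(self, two_pool_system, invitro_train, offsets_41):
        disc = simulate_pulsed(two_pool_system, invitro_train, 32, offsets_41)
        ap = simulate_equivalent(two_pool_system, invitro_train, "ap", offsets_41)
        af = simulate_equivalent(two_pool_system, invitro_train, "af", offsets_41)
        rms = lambda z: np.sqrt(np.mean((z.signal - disc.signal) ** 2))
        assert rms(af) > rms(ap)

    def test_unknown_scheme(self, two_pool_system, invitro_train, offsets_41):
        with pytest.raises(ValueError):
            simulate_equivalent(two_pool_system, invitro_train, "rms", offsets_41)


def _system_with_rate(c: float) -> PoolSystem:
    return PoolSystem(
        [
            Pool("w", 3.0, 0.060, 100.0),
            Pool("labile", 1.0, 0.0085, 0.33, exchange_rate=c, shift_ppm=1.9),
        ],
        b0=4.7,
    )


def test_saturation_depth_monotone_in_exchange_rate(invitro_train, offsets_41):
    """Faster labile exchange deepens the on-resonance dip in the slow-to-
    intermediate regime (beyond ~100 /s exchange broadening reverses the trend,
    so the assertion stops there)."""
    i_lab = int(np.argmin(np.abs(offsets_41 - 1.9)))
    depths = [
        1.0 - simulate_pulsed(_system_with_rate(c), invitro_train, 16, offsets_41).signal[i_lab]
        for c in (5.0, 25.0, 50.0, 100.0)
    ]
    assert np.all(np.diff(depths) >= -1e-12)


def test_ap_discrepancy_grows_with_exchange_rate(invitro_train, offsets_41):
    """The AP-vs-discretized discrepancy of the CEST effect increases with the
    exchange rate: both the RMS deviation near the labile resonance and the
    CESTR difference grow monotonically (the whole-spectrum RMS does not — it
    is dominated by the rate-independent water-center mismatch)."""
    from pulsedcest import cestr

    rms_labile, dcestr = [], []
    near = np.abs(offsets_41 - 1.9) <= 0.4
    for c in (28.0, 50.0, 100.0, 200.0):
        system = _system_with_rate(c)
        disc = simulate_pulsed(system, invitro_train, 32, offsets_41)
        ap = simulate_equivalent(system, invitro_train, "ap", offsets_41)
        rms_labile.append(np.sqrt(np.mean((ap.signal[near] - disc.signal[near]) ** 2)))
        dcestr.append(abs(cestr(ap, 1.9) - cestr(disc, 1.9)))
    assert np.all(np.diff(rms_labile) > 0)
    assert np.all(np.diff(dcestr) > 0)


def test_nrmse_convergence_from_four_segments(two_pool_system, invitro_train, offsets_41):
    """Discretization error decreases as the segment count doubles (n >= 4)."""
    bench = simulate_pulsed(two_pool_system, invitro_train, 1024, offsets_41)
    errs = [
        np.sqrt(np.mean((simulate_pulsed(two_pool_system, invitro_train, n, offsets_41).signal
                         - bench.signal) ** 2))
        for n in (4, 8, 16, 32, 64, 128)
    ]
    assert np.all(np.diff(errs) < 0)


def test_empty_offsets_rejected(two_pool_system, invitro_train):
    with pytest.raises(ValueError):
        simulate_pulsed(two_pool_system, invitro_train, 4, [])
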