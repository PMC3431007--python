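import numpy as np
import pytest

from pulsedcest import Pool, PoolSystem, PulseTrain, parse_offsets


@pytest.fixture(scope="session")
def two_pool_system() -> PoolSystem:
    """Water + amine labile pool with published in-vitro parameters at 4.7 T."""
    return PoolSystem(
        [
            Pool("w", t1=3.0, t2=0.060, m0=100.0),
            Pool("labile", t1=1.0, t2=0.0085, m0=0.33, exchange_rate=50.0, shift_ppm=1.9),
        ],
        b0=4.7,
    )


@pytest.fixture(scope="session")
def three_pool_system() -> PoolSystem:
    """Two-pool system plus an agarose-like semisolid MT pool."""
    return PoolSystem(
        [
            Pool("w", t1=3.0, t2=0.060, m0=100.0),
            Pool("labile", t1=1.0, t2=0.0085, m0=0.33, exchange_rate=50.0, shift_ppm=1.9),
            Pool("mt", t1=1.0, t2=10e-6, m0=2.0, exchange_rate=30.0, shift_ppm=0.0),
        ],
        b0=4.7,
    )


@pytest.fixture(scope="session")
def invitro_train() -> PulseTrain:
    """50 Gaussian pulses, FA 180 deg, 40 ms period, 50% duty cycle, crushers."""
    return PulseTrain("gaussian", 180.0, 0.040, 0.5, n_pulses=50, crushers=True)


@pytest.fixture(scope="session")
def offsets_41() -> np.ndarray:
    """The standard 41-point saturation grid, -3.8 to 3.8 ppm in 0.19 ppm steps."""
    return parse_offsets("-3.8:0.19:3.8")
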