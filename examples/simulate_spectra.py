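"""Simulate pulsed vs continuous-equivalent z-spectra for a two-pool system.

Builds the water + creatine-amine model at 4.7 T, saturates it with 50
Gaussian pulses (FA 180 deg, 40 ms period, 50% duty cycle), and compares the
discretized pulsed spectrum against its average-field (AF) and average-power
(AP) continuous equivalents.
"""

import numpy as np

from pulsedcest import (
    Pool,
    PoolSystem,
    PulseTrain,
    cestr,
    continuous_equivalent,
    parse_offsets,
    simulate_equivalent,
    simulate_pulsed,
)

system = PoolSystem(
    [
        Pool("w", t1=3.0, t2=0.060, m0=100.0),
        Pool("labile", t1=1.0, t2=0.0085, m0=0.33, exchange_rate=50.0, shift_ppm=1.9),
    ],
    b0=4.7,
)
train = PulseTrain("gaussian", flip_angle_deg=180.0, t_pd=0.040, duty_cycle=0.5,
                   n_pulses=50, crushers=True)
offsets = parse_offsets("-3.8:0.19:3.8")

ce = continuous_equivalent(train)
print(f"AF = {ce.b1_af * 1e6:.3f} uT, AP = {ce.b1_ap * 1e6:.3f} uT, "
      f"t_sat = {ce.t_sat:.1f} s")

disc = simulate_pulsed(system, train, n_segments=32, offsets_ppm=offsets)
ap = simulate_equivalent(system, train, "ap", offsets)
af = simulate_equivalent(system, train, "af", offsets)

rms = lambda z: np.sqrt(np.mean((z.signal - disc.signal) ** 2))
print(f"RMS deviation from the discretized spectrum:  AP {rms(ap):.4f}, AF {rms(af):.4f}")
print(f"CESTR at +1.9 ppm:  discretized {cestr(disc, 1.9):.4f}, AP {cestr(ap, 1.9):.4f}")
print("-> AP tracks the pulsed spectrum far better than AF; residual AP error")
print("   concentrates near 0 ppm (water) and +1.9 ppm (amine), which inflates")
print("   its apparent CEST effect.")
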