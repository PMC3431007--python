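"""Whole z-spectrum simulation under pulsed and continuous saturation.

The pulsed (discretized) scheme propagates the magnetization from thermal
equilibrium through every piecewise-constant segment of every pulse, the
inter-pulse delays, and optional ideal crusher spoiling; the readout value is
the water Mz immediately after the active part of the final pulse (the
trailing inter-pulse delay is not applied).  The continuous schemes replace
the train by a single constant-amplitude pulse of the same total duration at
either the average-field (AF) or average-power (AP) equivalent amplitude.

All identical pulses of a train share the same per-segment propagators, so
each offset costs one exponential per distinct segment amplitude regardless of
the number of pulses; the symmetric Gaussian envelope halves the distinct
amplitudes again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bmc import PoolSystem, crush_matrix, expm_affine, generator
from .pulses import (
    GAMMA_RAD_PER_T,
    ContinuousEquivalent,
    PulseTrain,
    continuous_equivalent,
    discretize,
)

__all__ = ["ZSpectrum", "simulate_pulsed", "simulate_cw", "simulate_equivalent"]


@dataclass(frozen=True)
class ZSpectrum:
    """Normalized water signal versus saturation offset.

    ``signal`` is water Mz divided by the unsaturated reference, so values lie
    in [0, 1] for noiseless physical simulations (a small tolerance admits
    measurement noise).  Offsets are in ppm relative to the nominal water
    center and must be strictly increasing.
    """

    offsets_ppm: np.ndarray = field(repr=False)
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        off = np.atleast_1d(np.asarray(self.offsets_ppm, dtype=float))
        sig = np.atleast_1d(np.asarray(self.signal, dtype=float))
        object.__setattr__(self, "offsets_ppm", off)
        object.__setattr__(self, "signal", sig)
        if off.shape != sig.shape or off.ndim != 1:
            raise ValueError("offsets and signal must be 1-D arrays of equal length")
        if off.size == 0:
            raise ValueError("empty z-spectrum")
        if off.size > 1 and np.any(np.diff(off) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(sig < -0.05) or np.any(sig > 1.05):
            raise ValueError("signals outside [-0.05, 1.05]; not a normalized z-spectrum")

    def __len__(self) -> int:
        return self.offsets_ppm.size

    def interp(self, offset_ppm) -> np.ndarray:
        """Linear interpolation of the signal at arbitrary offsets (in range)."""
        offset_ppm = np.asarray(offset_ppm, dtype=float)
        lo, hi = self.offsets_ppm[0], self.offsets_ppm[-1]
        if np.any(offset_ppm < lo) or np.any(offset_ppm > hi):
            raise ValueError(f"offset outside spectrum range [{lo}, {hi}] ppm")
        return np.interp(offset_ppm, self.offsets_ppm, self.signal)

    def shifted(self, delta_ppm: float) -> "ZSpectrum":
        """Same signal on an offset axis translated by ``delta_ppm``."""
        return ZSpectrum(self.offsets_ppm + delta_ppm, self.signal.copy())


def _as_offsets(offsets_ppm) -> np.ndarray:
    off = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    if off.size == 0:
        raise ValueError("offsets_ppm must be non-empty")
    return off


def _apply(P: np.ndarray, m: np.ndarray, q: np.ndarray | None = None) -> np.ndarray:
    out = np.einsum("...ij,...j->...i", P, m)
    return out if q is None else out + q


def _pulse_propagators(system: PoolSystem, train: PulseTrain, n_segments: int, offsets: np.ndarray):
    """Affine map ``(P, q)`` of one full discretized pulse, per offset.

    Exploits the mirror symmetry of the envelope: only the first half of the
    segment amplitudes needs a matrix exponential.
    """
    seg = discretize(train, n_segments)
    n = seg.n_segments
    if train.shape == "rect":
        uniq = seg.amplitudes[:1]
        index = np.zeros(n, dtype=int)
    else:
        uniq = seg.amplitudes[: (n + 1) // 2]
        index = np.minimum(np.arange(n), n - 1 - np.arange(n))
    omega1 = GAMMA_RAD_PER_T * uniq
    A, b = generator(system, omega1[None, :], offsets[:, None])
    P, q = expm_affine(A, b, seg.segment_duration)  # (n_off, n_uniq, d, d)

    d = system.dim
    n_off = offsets.size
    P_tot = np.broadcast_to(np.eye(d), (n_off, d, d)).copy()
    q_tot = np.zeros((n_off, d))
    for k in range(n):
        Pk = P[:, index[k]]
        q_tot = _apply(Pk, q_tot, q[:, index[k]])
        P_tot = Pk @ P_tot
    return P_tot, q_tot


def _delay_propagators(system: PoolSystem, delay: float, offsets: np.ndarray):
    A, b = generator(system, 0.0, offsets)
    return expm_affine(A, b, delay)


def simulate_pulsed(
    system: PoolSystem,
    train: PulseTrain,
    n_segments: int,
    offsets_ppm,
) -> ZSpectrum:
    """Simulate a z-spectrum under the discretized pulsed saturation scheme.

    Each pulse is approximated by ``n_segments`` piecewise-constant segments
    propagated exactly; between pulses the system relaxes freely for the
    inter-pulse delay, followed by ideal crusher spoiling if the train asks
    for it.  The signal is water Mz / m0 right after the last pulse.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    offsets = _as_offsets(offsets_ppm)
    Pp, qp = _pulse_propagators(system, train, n_segments, offsets)

    m = np.broadcast_to(system.equilibrium(), (offsets.size, system.dim)).copy()
    inter = None
    if train.n_pulses > 1:
        if train.delay > 0:
            Pd, qd = _delay_propagators(system, train.delay, offsets)
        else:
            Pd = np.broadcast_to(np.eye(system.dim), Pp.shape).copy()
            qd = np.zeros_like(qp)
        if train.crushers:
            C = crush_matrix(system)
            Pd, qd = C @ Pd, _apply(C[None], qd)
        # one full period: pulse, delay, (crush)
        inter = (Pd @ Pp, _apply(Pd, qp, qd))

    for _ in range(train.n_pulses - 1):
        m = _apply(inter[0], m, inter[1])
    m = _apply(Pp, m, qp)

    signal = m[:, 2] / system.water.m0
    return ZSpectrum(offsets, signal)


def simulate_cw(system: PoolSystem, b1: float, t_sat: float, offsets_ppm) -> ZSpectrum:
    """Simulate a z-spectrum under continuous saturation of amplitude ``b1`` (T)."""
    if b1 < 0 or t_sat < 0:
        raise ValueError("b1 and t_sat must be >= 0")
    offsets = _as_offsets(offsets_ppm)
    m = np.broadcast_to(system.equilibrium(), (offsets.size, system.dim)).copy()
    if t_sat > 0:
        A, b = generator(system, GAMMA_RAD_PER_T * b1, offsets)
        P, q = expm_affine(A, b, t_sat)
        m = _apply(P, m, q)
    return ZSpectrum(offsets, m[:, 2] / system.water.m0)


def simulate_equivalent(
    system: PoolSystem,
    train: PulseTrain,
    scheme: str,
    offsets_ppm,
    equivalent: ContinuousEquivalent | None = None,
) -> ZSpectrum:
    """Simulate the CW z-spectrum of a train's AF or AP continuous equivalent.

    ``scheme`` is ``"af"`` (time-mean B1) or ``"ap"`` (root-mean-square B1);
    the saturation time is the train's total duration ``n_pulses * t_pd``.
    """
    ce = equivalent if equivalent is not None else continuous_equivalent(train)
    scheme = scheme.lower()
    if scheme == "af":
        b1 = ce.b1_af
    elif scheme == "ap":
        b1 = ce.b1_ap
    else:
        raise ValueError("scheme must be 'af' or 'ap'")
    return simulate_cw(system, b1, ce.t_sat, offsets_ppm)
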