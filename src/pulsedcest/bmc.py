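"""Bloch-McConnell generator matrices and exact piecewise-constant propagation.

The magnetization of a multi-pool exchange system under constant RF obeys a
linear-affine ODE, ``dM/dt = A M + b``.  Full Bloch pools (water and labile
protons) contribute three rows each (Mx, My, Mz); a semisolid MT pool is
longitudinal-only, its RF saturation entering as a rate ``W = pi * omega1^2 *
g(delta)`` with a Gaussian absorption lineshape ``g``.  Exchange back-rates are
derived from the equilibrium condition, e.g. ``C_w = C_labile * M_labile0 /
M_w0``, so thermal equilibrium is an exact fixed point at zero RF.

Propagation over a piecewise-constant interval is the exact matrix exponential
of the augmented (affine) generator.  A batched scaling-and-squaring Taylor
evaluation handles the large stacks of small matrices produced when whole
z-spectra are simulated; it agrees with ``scipy.linalg.expm`` to machine
precision.

State vector layout: ``[Mx, My, Mz]`` per Bloch pool in system order, then one
``Mz`` per MT pool, normalized so that water equilibrium Mz equals ``m0_w``.

Rotating-frame convention: RF along +x; the offset term is ``delta = 2 pi f0 *
(offset_ppm - pool_shift_ppm) * 1e-6`` on the z-rotation, positive ppm being
downfield.  All pool shifts ride on the (possibly fitted) water center
frequency ``water_center_ppm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pulses import GAMMA_HZ_PER_T, GAMMA_RAD_PER_T

__all__ = [
    "Pool",
    "PoolSystem",
    "InvalidModelError",
    "generator",
    "mt_saturation_rate",
    "propagate",
    "crush",
    "expm_affine",
]


class InvalidModelError(ValueError):
    """Raised for pool systems violating physical invariants."""


@dataclass(frozen=True)
class Pool:
    """One proton pool: relaxation, size, exchange rate and chemical shift.

    ``exchange_rate`` is the rate (s^-1) at which magnetization leaves this
    pool toward water (zero for water itself).  ``shift_ppm`` is relative to
    the water center.  For an MT pool, ``t2`` is the Gaussian lineshape width
    parameter rather than a Bloch transverse relaxation time.
    """

    name: str
    t1: float
    t2: float
    m0: float
    exchange_rate: float = 0.0
    shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0.0 or self.t2 <= 0.0:
            raise InvalidModelError(f"pool {self.name!r}: relaxation times must be positive")
        if self.m0 < 0.0 or self.exchange_rate < 0.0:
            raise InvalidModelError(f"pool {self.name!r}: m0 and exchange rate must be >= 0")


@dataclass(frozen=True)
class PoolSystem:
    """Ordered pool collection (water first) at a given static field.

    Pools named ``"mt"`` are treated as longitudinal-only semisolid pools.
    ``water_center_ppm`` is the water frequency shift (B0 inhomogeneity); all
    pool resonances ride on it.
    """

    pools: tuple = field()
    b0: float = 4.7
    water_center_ppm: float = 0.0

    def __init__(self, pools: Sequence[Pool], b0: float = 4.7, water_center_ppm: float = 0.0):
        object.__setattr__(self, "pools", tuple(pools))
        object.__setattr__(self, "b0", float(b0))
        object.__setattr__(self, "water_center_ppm", float(water_center_ppm))
        if not self.pools or self.pools[0].name != "w":
            raise InvalidModelError("first pool must be water (name 'w')")
        if sum(p.name == "w" for p in self.pools) != 1:
            raise InvalidModelError("exactly one water pool required")
        if self.b0 <= 0.0:
            raise InvalidModelError("b0 must be positive")

    @property
    def water(self) -> Pool:
        return self.pools[0]

    @property
    def bloch_pools(self) -> tuple:
        return tuple(p for p in self.pools if p.name != "mt")

    @property
    def mt_pools(self) -> tuple:
        return tuple(p for p in self.pools if p.name == "mt")

    @property
    def dim(self) -> int:
        """State dimension: 3 per Bloch pool plus 1 per MT pool."""
        return 3 * len(self.bloch_pools) + len(self.mt_pools)

    @property
    def f0_hz(self) -> float:
        """Water Larmor frequency in Hz."""
        return GAMMA_HZ_PER_T * self.b0

    def ppm_to_rad(self, ppm) -> np.ndarray:
        """Convert a chemical-shift offset in ppm to rad/s at this field."""
        return 2.0 * math.pi * self.f0_hz * 1e-6 * np.asarray(ppm, dtype=float)

    def with_water_center(self, ppm: float) -> "PoolSystem":
        return PoolSystem(self.pools, b0=self.b0, water_center_ppm=ppm)

    def equilibrium(self) -> np.ndarray:
        """Thermal-equilibrium state vector."""
        m = np.zeros(self.dim)
        for i, p in enumerate(self.bloch_pools):
            m[3 * i + 2] = p.m0
        for j, p in enumerate(self.mt_pools):
            m[3 * len(self.bloch_pools) + j] = p.m0
        return m


def mt_saturation_rate(omega1, delta, t2_mt: float):
    """RF saturation rate of a semisolid pool with a Gaussian lineshape.

    ``W = pi * omega1^2 * g(delta)`` with ``g(delta) = (t2 / sqrt(2 pi)) *
    exp(-(delta * t2)^2 / 2)``; ``omega1`` and ``delta`` in rad/s.
    """
    if t2_mt <= 0.0:
        raise InvalidModelError("t2_mt must be positive")
    omega1 = np.asarray(omega1, dtype=float)
    delta = np.asarray(delta, dtype=float)
    g = t2_mt / math.sqrt(2.0 * math.pi) * np.exp(-0.5 * (delta * t2_mt) ** 2)
    return math.pi * omega1**2 * g


def generator(system: PoolSystem, omega1, offset_ppm):
    """Constant-coefficient generator ``(A, b)`` of ``dM/dt = A M + b``.

    ``omega1`` is the RF amplitude in rad/s and ``offset_ppm`` the saturation
    offset; both may be broadcastable arrays, in which case ``A`` has shape
    ``(*batch, dim, dim)`` and ``b`` shape ``(*batch, dim)``.
    """
    omega1 = np.asarray(omega1, dtype=float)
    offset_ppm = np.asarray(offset_ppm, dtype=float)
    if np.any(omega1 < 0):
        raise InvalidModelError("omega1 must be non-negative")
    batch = np.broadcast_shapes(omega1.shape, offset_ppm.shape)
    omega1 = np.broadcast_to(omega1, batch)
    offset_ppm = np.broadcast_to(offset_ppm, batch)

    d = system.dim
    bloch = system.bloch_pools
    nb = len(bloch)
    water = system.water
    A = np.zeros(batch + (d, d))
    b = np.zeros(batch + (d,))
    wz = 2  # water Mz row index

    for i, p in enumerate(bloch):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        delta = system.ppm_to_rad(offset_ppm - (system.water_center_ppm + p.shift_ppm))
        A[..., x, x] -= 1.0 / p.t2
        A[..., y, y] -= 1.0 / p.t2
        A[..., z, z] -= 1.0 / p.t1
        A[..., x, y] -= delta
        A[..., y, x] += delta
        A[..., y, z] += omega1
        A[..., z, y] -= omega1
        b[..., z] = p.m0 / p.t1
        if i > 0:
            # exchange with water, all three components
            k_from = p.exchange_rate
            k_to = p.exchange_rate * p.m0 / water.m0 if water.m0 > 0 else 0.0
            for c in range(3):
                A[..., x + c, x + c] -= k_from
                A[..., x + c, c] += k_to
                A[..., c, x + c] += k_from
                A[..., c, c] -= k_to

    for j, p in enumerate(system.mt_pools):
        r = 3 * nb + j
        delta = system.ppm_to_rad(offset_ppm - (system.water_center_ppm + p.shift_ppm))
        w_sat = mt_saturation_rate(omega1, delta, p.t2)
        k_from = p.exchange_rate
        k_to = p.exchange_rate * p.m0 / water.m0 if water.m0 > 0 else 0.0
        A[..., r, r] -= 1.0 / p.t1 + k_from
        A[..., r, r] -= w_sat
        A[..., r, wz] += k_to
        A[..., wz, r] += k_from
        A[..., wz, wz] -= k_to
        b[..., r] = p.m0 / p.t1

    return A, b


def _expm_batched(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small matrices.

    Scaling-and-squaring with a fixed-order Taylor evaluation; the scaling
    power is chosen from the largest matrix norm in the stack so that the
    scaled norm is <= 0.5, giving ~1e-17 truncation error at order 16.
    """
    A = np.asarray(A, dtype=float)
    norm = float(np.abs(A).sum(axis=-1).max()) if A.size else 0.0
    s = max(0, int(math.ceil(math.log2(norm / 0.5)))) if norm > 0.5 else 0
    X = A / (2.0**s)
    d = A.shape[-1]
    eye = np.eye(d)
    E = eye + X
    T = X
    for k in range(2, 17):
        T = T @ X / k
        E = E + T
    for _ in range(s):
        E = E @ E
    return E


def expm_affine(A: np.ndarray, b: np.ndarray, duration: float):
    """Exact propagator of ``dM/dt = A M + b`` over ``duration``.

    Returns ``(P, q)`` such that ``M(duration) = P @ M(0) + q``, computed as
    the exponential of the augmented generator ``[[A, b], [0, 0]]``.  Accepts
    stacked inputs.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    d = A.shape[-1]
    aug = np.zeros(A.shape[:-2] + (d + 1, d + 1))
    aug[..., :d, :d] = A * duration
    aug[..., :d, d] = b * duration
    E = _expm_batched(aug)
    return E[..., :d, :d], E[..., :d, d]


def propagate(system: PoolSystem, omega1: float, offset_ppm: float, duration: float, m_init: np.ndarray) -> np.ndarray:
    """Propagate a magnetization state under constant RF for ``duration`` seconds.

    Exact solution via the matrix exponential of the augmented generator;
    ``duration = 0`` returns ``m_init`` unchanged.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    m = np.asarray(m_init, dtype=float)
    if duration == 0:
        return m.copy()
    A, b = generator(system, omega1, offset_ppm)
    P, q = expm_affine(A, b, duration)
    return P @ m + q


def crush_matrix(system: PoolSystem) -> np.ndarray:
    """Ideal-spoiling operator: zeros transverse components, keeps longitudinal."""
    keep = np.zeros(system.dim)
    for i in range(len(system.bloch_pools)):
        keep[3 * i + 2] = 1.0
    keep[3 * len(system.bloch_pools):] = 1.0
    return np.diag(keep)


def crush(system: PoolSystem, m: np.ndarray) -> np.ndarray:
    """Apply ideal crusher spoiling to a state (idempotent, Mz preserved)."""
    return crush_matrix(system) @ np.asarray(m, dtype=float)


def steady_state(system: PoolSystem, omega1: float, offset_ppm: float) -> np.ndarray:
    """Long-time limit ``-A^-1 b`` of propagation under constant RF."""
    A, b = generator(system, omega1, offset_ppm)
    return -np.linalg.solve(A, b)
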