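"""Synthetic creatine/agarose phantom datasets with known ground truth.

Emulates the tissue-like multi-vial phantoms used to validate CEST
quantification: vials of creatine in agarose at two concentrations (100 and
125 mM, i.e. labile amine proton concentrations of 0.33 and 0.4125 M against
100 M water protons) titrated to pH 5.5, 6.0 and 6.5.  The base-catalysed
amine exchange rate rises tenfold per pH unit, anchored at 50 s^-1 for pH 6 —
a modelling convenience producing realistically graded vials, not a
calibrated titration curve.  Agarose supplies a semisolid MT pool everywhere.

Instrumental imperfections follow what a shimmed phantom scan shows: a smooth
B0 shift map within +-0.2 ppm and a smooth B1 scale map within +-10 %, both
low-order 2-D polynomials with seeded random coefficients, plus additive
Gaussian noise on the normalized signal (Rician effects are negligible at
phantom SNR).  Every generated voxel stores its ground truth, so fitting and
B0-mapping stages can be validated by round trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bmc import Pool, PoolSystem
from .pulses import PulseTrain
from .simulate import ZSpectrum, simulate_equivalent, simulate_pulsed

__all__ = ["Vial", "PhantomSpec", "PhantomDataset", "generate", "ph_to_exchange", "default_phantom_spec"]


def ph_to_exchange(ph: float, base_rate_at_ph6: float = 50.0) -> float:
    """Base-catalysed amine exchange rate for a given pH.

    ``rate = base_rate * 10**(ph - 6)``: a monotone decade-per-pH-unit scaling
    anchored at pH 6, used to generate pH-graded vials.
    """
    if not 4.0 <= ph <= 9.0:
        raise ValueError("ph must lie in [4, 9]")
    return base_rate_at_ph6 * 10.0 ** (ph - 6.0)


@dataclass(frozen=True)
class Vial:
    """One cylindrical vial: position (fractions of the grid) and contents."""

    center: tuple  # (row, col) as fractions in [0, 1]
    radius: float  # fraction of the grid extent
    c_labile: float  # amine exchange rate, s^-1
    m_labile0: float  # labile proton concentration, M
    label: str = ""


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and physics of a synthetic multi-vial phantom."""

    grid_shape: tuple = (32, 32)
    vials: tuple = ()
    # water / labile / MT physics shared across the phantom
    t1w: float = 3.0
    t2w: float = 0.060
    m_w0: float = 100.0
    t1_labile: float = 1.0
    t2_labile: float = 0.0085
    labile_shift_ppm: float = 1.9
    t1_mt: float = 1.0
    t2_mt: float = 10e-6
    m_mt0: float = 2.0
    c_mt: float = 30.0
    b0: float = 4.7
    # field imperfections and noise
    b0_amplitude_ppm: float = 0.15
    b1_amplitude: float = 0.08
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.b0_amplitude_ppm) > 0.2:
            raise ValueError("B0 shift amplitude must stay within +-0.2 ppm")
        if abs(self.b1_amplitude) > 0.1:
            raise ValueError("B1 scale amplitude must stay within +-10 %")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(f"vials {a.label!r} and {b.label!r} overlap")


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Six-vial layout: 100/125 mM creatine at pH 5.5, 6.0 and 6.5."""
    vials = []
    for row, (conc_mm, m_lab) in zip((0.27, 0.73), ((100, 0.33), (125, 0.4125))):
        for col, ph in zip((0.18, 0.5, 0.82), (5.5, 6.0, 6.5)):
            vials.append(
                Vial(
                    center=(row, col),
                    radius=0.115,
                    c_labile=ph_to_exchange(ph),
                    m_labile0=m_lab,
                    label=f"{conc_mm}mM_pH{ph}",
                )
            )
    return PhantomSpec(vials=tuple(vials), **overrides)


def _smooth_field(rng: np.random.Generator, shape: tuple, amplitude: float) -> np.ndarray:
    """Zero-centered low-order 2-D polynomial scaled to a peak magnitude.

    Quadratic in the normalized coordinates, mimicking smooth shim-like
    spatial structure; coefficients are drawn from ``rng``.
    """
    ny, nx = shape
    y, x = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    terms = np.stack([x, y, x * y, x**2, y**2, x**2 * y, x * y**2])
    coeffs = rng.normal(size=terms.shape[0])
    f = np.tensordot(coeffs, terms, axes=1)
    f -= f.mean()
    peak = np.abs(f).max()
    if peak == 0:
        return np.zeros(shape)
    return amplitude * f / peak


@dataclass(frozen=True)
class PhantomDataset:
    """Per-voxel z-spectra plus the lossless ground truth that generated them."""

    offsets_ppm: np.ndarray = field(repr=False)
    signals: np.ndarray = field(repr=False)  # (ny, nx, n_offsets)
    vial_map: np.ndarray = field(repr=False)  # int vial index, -1 = background
    truth: dict = field(repr=False)  # maps: c_labile, m_labile0, omega_w, b1_scale
    spec: PhantomSpec = field(repr=False)
    train: PulseTrain = field(repr=False)
    engine: str = "discretized"
    n_segments: int = 32

    def spectrum(self, row: int, col: int) -> ZSpectrum:
        return ZSpectrum(self.offsets_ppm, self.signals[row, col])

    def vial_voxels(self, vial_index: int) -> list:
        rows, cols = np.nonzero(self.vial_map == vial_index)
        return list(zip(rows.tolist(), cols.tolist()))

    def to_long_dataframe(self) -> pd.DataFrame:
        ny, nx, _ = self.signals.shape
        rows = []
        for r in range(ny):
            for c in range(nx):
                for o, s in zip(self.offsets_ppm, self.signals[r, c]):
                    rows.append((f"v{r}_{c}", r, c, o, s))
        return pd.DataFrame(rows, columns=["voxel_id", "row", "col", "offset_ppm", "signal"])

    def save(self, directory) -> None:
        """Write spectra (long CSV), ground-truth maps (CSV) and the config (JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_dataframe().to_csv(directory / "spectra.csv", index=False)
        for name, arr in self.truth.items():
            pd.DataFrame(arr).to_csv(directory / f"truth_{name}.csv", index=False, header=False)
        pd.DataFrame(self.vial_map).to_csv(directory / "vial_map.csv", index=False, header=False)
        config = {
            "spec": _spec_to_jsonable(self.spec),
            "train": asdict(self.train),
            "engine": self.engine,
            "n_segments": self.n_segments,
            "offsets_ppm": self.offsets_ppm.tolist(),
        }
        (directory / "config.json").write_text(json.dumps(config, indent=2))


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["vials"] = [asdict(v) for v in spec.vials]
    return d


def _voxel_system(spec: PhantomSpec, c_labile: float, m_labile0: float, omega_w: float) -> PoolSystem:
    pools = [Pool("w", spec.t1w, spec.t2w, spec.m_w0)]
    if m_labile0 > 0:
        pools.append(
            Pool("labile", spec.t1_labile, spec.t2_labile, m_labile0, c_labile, spec.labile_shift_ppm)
        )
    pools.append(Pool("mt", spec.t1_mt, spec.t2_mt, spec.m_mt0, spec.c_mt, 0.0))
    return PoolSystem(pools, b0=spec.b0, water_center_ppm=omega_w)


def generate(
    spec: PhantomSpec,
    train: PulseTrain,
    offsets_ppm,
    engine: str = "discretized",
    n_segments: int = 32,
) -> PhantomDataset:
    """Simulate a phantom dataset voxel by voxel; deterministic given the seed.

    Each voxel's three-pool spectrum uses its local water shift and B1 scale;
    background voxels contain water and MT only (the agar filler).  Zero-mean
    Gaussian noise of sd ``spec.noise_sd`` is added to the normalized signal.
    """
    if engine not in ("discretized", "ap"):
        raise ValueError("engine must be 'discretized' or 'ap'")
    offsets = np.asarray(offsets_ppm, dtype=float)
    ny, nx = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    omega_w_map = _smooth_field(rng, (ny, nx), spec.b0_amplitude_ppm)
    b1_map = 1.0 + _smooth_field(rng, (ny, nx), spec.b1_amplitude)

    vial_map = np.full((ny, nx), -1, dtype=int)
    c_map = np.zeros((ny, nx))
    m_map = np.zeros((ny, nx))
    yy, xx = np.meshgrid(np.linspace(0, 1, ny), np.linspace(0, 1, nx), indexing="ij")
    for i, vial in enumerate(spec.vials):
        inside = (yy - vial.center[0]) ** 2 + (xx - vial.center[1]) ** 2 <= vial.radius**2
        vial_map[inside] = i
        c_map[inside] = vial.c_labile
        m_map[inside] = vial.m_labile0

    signals = np.empty((ny, nx, offsets.size))
    for r in range(ny):
        for c in range(nx):
            system = _voxel_system(spec, c_map[r, c], m_map[r, c], omega_w_map[r, c])
            voxel_train = train.scaled(b1_map[r, c])
            if engine == "discretized":
                zs = simulate_pulsed(system, voxel_train, n_segments, offsets)
            else:
                zs = simulate_equivalent(system, voxel_train, "ap", offsets)
            signals[r, c] = zs.signal
    if spec.noise_sd > 0:
        signals = signals + rng.normal(0.0, spec.noise_sd, size=signals.shape)
        signals = np.clip(signals, -0.05, 1.05)

    truth = {
        "c_labile": c_map,
        "m_labile0": m_map,
        "omega_w": omega_w_map,
        "b1_scale": b1_map,
    }
    return PhantomDataset(
        offsets_ppm=offsets,
        signals=signals,
        vial_map=vial_map,
        truth=truth,
        spec=spec,
        train=train,
        engine=engine,
        n_segments=n_segments,
    )
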