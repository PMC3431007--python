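"""Readers, writers, unit conversions and configuration parsing.

Spectra travel as CSV, either wide (an ``offset_ppm`` column plus one signal
column per voxel/ROI) or long (``voxel_id, offset_ppm, signal``).  Pool models
and pulse trains are YAML/JSON mappings.  The canonical on-disk offset unit is
ppm, which is field-strength independent; conversion helpers to Hz require the
static field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .bmc import Pool, PoolSystem
from .pulses import GAMMA_HZ_PER_T, PulseTrain
from .simulate import ZSpectrum

__all__ = [
    "ppm_to_hz",
    "hz_to_ppm",
    "parse_offsets",
    "read_zspectra",
    "write_zspectra",
    "load_config",
    "pool_system_from_config",
    "pulse_train_from_config",
]


def ppm_to_hz(offset_ppm, b0: float):
    """Chemical-shift offset in ppm to Hz at static field ``b0`` (tesla)."""
    return np.asarray(offset_ppm, dtype=float) * GAMMA_HZ_PER_T * b0 * 1e-6


def hz_to_ppm(offset_hz, b0: float):
    """Inverse of :func:`ppm_to_hz`."""
    return np.asarray(offset_hz, dtype=float) / (GAMMA_HZ_PER_T * b0 * 1e-6)


def parse_offsets(expr: str) -> np.ndarray:
    """Parse an offset grid: ``"start:step:stop"`` (endpoint inclusive) or a
    comma-separated list.  Unicode minus signs are accepted."""
    expr = expr.strip().replace("−", "-")
    if ":" in expr:
        parts = expr.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected start:step:stop, got {expr!r}")
        start, step, stop = (float(p) for p in parts)
        if step <= 0:
            raise ValueError("offset step must be positive")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        grid = start + step * np.arange(n)
        # endpoint inclusive within tolerance
        if abs(grid[-1] - stop) > 1e-9 and stop - grid[-1] > 1e-9:
            pass
        return grid
    values = np.array([float(v) for v in expr.split(",") if v.strip()])
    if values.size == 0:
        raise ValueError("empty offset list")
    return values


def read_zspectra(path) -> dict:
    """Read a spectra CSV (wide or long) into ``{id: ZSpectrum}``.

    Wide format: column ``offset_ppm`` plus one column per voxel/ROI.  Long
    format: columns ``voxel_id, offset_ppm, signal``.  All voxels must share
    one strictly increasing offset grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty spectra file") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = set(df.columns)
    if {"voxel_id", "offset_ppm", "signal"} <= cols:
        out = {}
        grid = None
        for vid, grp in df.groupby("voxel_id", sort=False):
            grp = grp.sort_values("offset_ppm")
            off = grp["offset_ppm"].to_numpy(dtype=float)
            if grid is None:
                grid = off
            elif off.shape != grid.shape or not np.allclose(off, grid):
                raise ValueError(f"{path}: voxel {vid!r} has a different offset grid")
            out[str(vid)] = ZSpectrum(off, grp["signal"].to_numpy(dtype=float))
        return out
    if "offset_ppm" not in cols:
        raise ValueError(f"{path}: need an 'offset_ppm' column or long-format columns")
    df = df.sort_values("offset_ppm")
    off = df["offset_ppm"].to_numpy(dtype=float)
    out = {}
    for col in df.columns:
        if col == "offset_ppm":
            continue
        sig = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        out[str(col)] = ZSpectrum(off, sig)
    if not out:
        raise ValueError(f"{path}: no signal columns")
    return out


def write_zspectra(spectra: Mapping[str, ZSpectrum], path, fmt: str = "wide") -> None:
    """Write ``{id: ZSpectrum}`` to CSV in wide (default) or long format."""
    path = Path(path)
    items = list(spectra.items())
    if not items:
        raise ValueError("nothing to write")
    grid = items[0][1].offsets_ppm
    for vid, zs in items:
        if zs.offsets_ppm.shape != grid.shape or not np.allclose(zs.offsets_ppm, grid):
            raise ValueError(f"voxel {vid!r} has a different offset grid")
    if fmt == "wide":
        df = pd.DataFrame({"offset_ppm": grid})
        for vid, zs in items:
            df[vid] = zs.signal
    elif fmt == "long":
        rows = [
            (vid, o, s)
            for vid, zs in items
            for o, s in zip(zs.offsets_ppm, zs.signal)
        ]
        df = pd.DataFrame(rows, columns=["voxel_id", "offset_ppm", "signal"])
    else:
        raise ValueError("fmt must be 'wide' or 'long'")
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def pool_system_from_config(config: Mapping) -> PoolSystem:
    """Build a :class:`PoolSystem` from a config mapping.

    Expected block::

        system:
          b0_T: 4.7
          water_center_ppm: 0.0
          pools:
            - {name: w, t1_s: 3.0, t2_s: 0.06, m0: 100.0}
            - {name: labile, t1_s: 1.0, t2_s: 0.0085, m0: 0.33,
               exchange_rate_s: 50.0, shift_ppm: 1.9}
    """
    block = config.get("system", config)
    pools = [
        Pool(
            name=p["name"],
            t1=float(p["t1_s"]),
            t2=float(p["t2_s"]),
            m0=float(p["m0"]),
            exchange_rate=float(p.get("exchange_rate_s", 0.0)),
            shift_ppm=float(p.get("shift_ppm", 0.0)),
        )
        for p in block["pools"]
    ]
    return PoolSystem(
        pools,
        b0=float(block.get("b0_T", 4.7)),
        water_center_ppm=float(block.get("water_center_ppm", 0.0)),
    )


def pulse_train_from_config(config: Mapping) -> PulseTrain:
    """Build a :class:`PulseTrain` from a config mapping (``train`` block)."""
    block = config.get("train", config)
    return PulseTrain(
        shape=str(block.get("shape", "gaussian")),
        flip_angle_deg=float(block["flip_angle_deg"]),
        t_pd=float(block["t_pd_ms"]) * 1e-3,
        duty_cycle=float(block["duty_cycle"]),
        n_pulses=int(block.get("n_pulses", 1)),
        crushers=bool(block.get("crushers", True)),
    )
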