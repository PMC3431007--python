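"""Discretization calibration: how many segments per shaped pulse are enough.

The piecewise-constant approximation of a shaped pulse converges to the true
envelope as the segment count grows; a 1024-segment simulation serves as the
benchmark.  The minimal segment count is the smallest power of two whose
pulsed z-spectrum deviates from the benchmark by less than 0.1 % RMS.  Because
z-spectra are already normalized to the unsaturated reference, the default
"normalized RMS error" is the plain RMS of the signal difference; dividing by
the benchmark's RMS is available as an option.

Also provides the average-power adequacy test: a pulse-parameter set is
classified as AP-adequate when both the sum-of-squares difference and the
CESTR difference between its AP and discretized spectra are smaller than those
of a benchmark parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bmc import PoolSystem
from .pulses import PulseTrain
from .simulate import ZSpectrum, simulate_equivalent, simulate_pulsed

__all__ = [
    "nrmse",
    "minimal_segments",
    "segment_grid_study",
    "ap_adequacy",
    "SegmentSearchResult",
    "ApAdequacy",
    "DEFAULT_CANDIDATE_NS",
]

#: Powers of two tried by the minimal-segment search (benchmark is 1024).
DEFAULT_CANDIDATE_NS = (2, 4, 8, 16, 32, 64, 128, 256, 512)


def nrmse(test: ZSpectrum, benchmark: ZSpectrum, relative: bool = False) -> float:
    """RMS deviation between two z-spectra on identical offset grids.

    With ``relative=True`` the RMS difference is divided by the RMS of the
    benchmark signal.
    """
    if test.offsets_ppm.shape != benchmark.offsets_ppm.shape or not np.allclose(
        test.offsets_ppm, benchmark.offsets_ppm
    ):
        raise ValueError("spectra are defined on different offset grids")
    err = float(np.sqrt(np.mean((test.signal - benchmark.signal) ** 2)))
    if relative:
        scale = float(np.sqrt(np.mean(benchmark.signal**2)))
        if scale == 0.0:
            raise ValueError("benchmark spectrum is identically zero")
        err /= scale
    return err


@dataclass(frozen=True)
class SegmentSearchResult:
    """Outcome of a minimal-segment search for one pulse train."""

    train: PulseTrain
    minimal_n: int
    nrmse_by_n: dict = field(repr=False)

    @property
    def nrmse_at_minimal(self) -> float:
        return self.nrmse_by_n.get(self.minimal_n, 0.0)


def minimal_segments(
    system: PoolSystem,
    train: PulseTrain,
    offsets_ppm,
    threshold: float = 0.001,
    benchmark_n: int = 1024,
    candidate_ns: Sequence[int] = DEFAULT_CANDIDATE_NS,
    relative: bool = False,
    full_curve: bool = False,
) -> SegmentSearchResult:
    """Smallest candidate segment count within ``threshold`` of the benchmark.

    Simulates the pulsed z-spectrum at each candidate ``n`` (ascending) and at
    ``benchmark_n``, and returns the smallest candidate whose RMS deviation
    from the benchmark is below ``threshold``; if none qualifies, the
    benchmark count itself is returned.  With ``full_curve=True`` the search
    does not stop at the first qualifying count, so ``nrmse_by_n`` covers all
    candidates.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    offsets = np.asarray(offsets_ppm, dtype=float)
    bench = simulate_pulsed(system, train, benchmark_n, offsets)
    errors: dict = {}
    minimal = benchmark_n
    for n in sorted(candidate_ns):
        spec = simulate_pulsed(system, train, n, offsets)
        errors[n] = nrmse(spec, bench, relative=relative)
        if errors[n] < threshold:
            if minimal == benchmark_n:
                minimal = n
            if not full_curve:
                break
    return SegmentSearchResult(train=train, minimal_n=minimal, nrmse_by_n=errors)


def segment_grid_study(
    system: PoolSystem,
    fa_list_deg: Sequence[float],
    tpd_list_s: Sequence[float],
    dc_list: Sequence[float],
    offsets_ppm,
    shape: str = "gaussian",
    n_pulses: int = 50,
    crushers: bool = True,
    threshold: float = 0.001,
    benchmark_n: int = 1024,
    progress: bool = False,
) -> pd.DataFrame:
    """Minimal segment count over a grid of pulse parameters.

    Sweeps every combination of flip angle, pulse period and duty cycle and
    runs :func:`minimal_segments` for each.  Returns a DataFrame with columns
    ``fa_deg, tpd_ms, dc, minimal_n, nrmse_at_n``; the grid extremes are
    ``df.minimal_n.min()`` / ``df.minimal_n.max()``.
    """
    if not (len(fa_list_deg) and len(tpd_list_s) and len(dc_list)):
        raise ValueError("parameter lists must be non-empty")
    rows = []
    for fa in fa_list_deg:
        for tpd in tpd_list_s:
            for dc in dc_list:
                train = PulseTrain(shape, fa, tpd, dc, n_pulses=n_pulses, crushers=crushers)
                res = minimal_segments(
                    system, train, offsets_ppm, threshold=threshold, benchmark_n=benchmark_n
                )
                rows.append(
                    {
                        "fa_deg": fa,
                        "tpd_ms": tpd * 1e3,
                        "dc": dc,
                        "minimal_n": res.minimal_n,
                        "nrmse_at_n": res.nrmse_at_minimal,
                    }
                )
                if progress:
                    print(f"FA={fa:5.0f} Tpd={tpd*1e3:5.0f} ms DC={dc:.1f} -> N={res.minimal_n}")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ApAdequacy:
    """AP-vs-discretized discrepancy of a train relative to a benchmark train."""

    adequate: bool
    ss_diff: float
    cestr_diff: float
    benchmark_ss_diff: float
    benchmark_cestr_diff: float


def _ap_discrepancies(
    system: PoolSystem,
    train: PulseTrain,
    offsets: np.ndarray,
    labile_offset_ppm: float,
    n_segments: int | None,
    threshold: float,
    benchmark_n: int,
) -> tuple[float, float]:
    from .fitting import cestr  # local import to avoid a cycle

    if n_segments is None:
        n_segments = minimal_segments(
            system, train, offsets, threshold=threshold, benchmark_n=benchmark_n
        ).minimal_n
    disc = simulate_pulsed(system, train, n_segments, offsets)
    ap = simulate_equivalent(system, train, "ap", offsets)
    ss = float(np.sum((ap.signal - disc.signal) ** 2))
    dcestr = abs(cestr(ap, labile_offset_ppm) - cestr(disc, labile_offset_ppm))
    return ss, dcestr


def ap_adequacy(
    system: PoolSystem,
    train: PulseTrain,
    benchmark_train: PulseTrain,
    offsets_ppm,
    labile_offset_ppm: float = 1.9,
    n_segments: int | None = None,
    benchmark_n_segments: int | None = None,
    threshold: float = 0.001,
    benchmark_n: int = 1024,
) -> ApAdequacy:
    """Classify a pulse-parameter set as AP-adequate relative to a benchmark.

    ``ss_diff`` is the sum of squared differences between the AP-equivalent
    and discretized spectra of ``train``; ``cestr_diff`` the absolute CESTR
    difference at the labile offset.  The train is adequate when both are
    strictly smaller than the benchmark train's values.  Segment counts
    default to each train's own minimal-segment calibration.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    ss, dc = _ap_discrepancies(
        system, train, offsets, labile_offset_ppm, n_segments, threshold, benchmark_n
    )
    ss_b, dc_b = _ap_discrepancies(
        system, benchmark_train, offsets, labile_offset_ppm, benchmark_n_segments, threshold, benchmark_n
    )
    return ApAdequacy(
        adequate=bool(ss < ss_b and dc < dc_b),
        ss_diff=ss,
        cestr_diff=dc,
        benchmark_ss_diff=ss_b,
        benchmark_cestr_diff=dc_b,
    )
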