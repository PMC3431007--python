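# Methods

## Model

Magnetization of `n` exchanging proton pools under RF irradiation follows the
Bloch–McConnell equations, written here as one linear-affine system
`dM/dt = A M + b`. Full Bloch pools (water `w`, labile protons) contribute
three state components each; a semisolid MT pool contributes only its
longitudinal component. In the rotating frame with RF along +x:

- transverse decay `−1/T₂`, longitudinal recovery `−1/T₁` with drift
  `b_z = M₀/T₁`;
- off-resonance term `Δ_s = 2π f₀ (δ_rf − δ_s) · 10⁻⁶` rad/s rotating
  (Mx, My), where `f₀ = γ/2π · B₀` and `δ_s` is the pool's shift in ppm;
- RF nutation `ω₁ = γ B₁` rotating (My, Mz);
- exchange at rate `C_s` from pool `s` into water, applied component-wise,
  with the back-rate fixed by equilibrium: `C_w→s = C_s · M₀ˢ/M₀ʷ`. Thermal
  equilibrium is therefore an exact fixed point at zero RF.

The MT pool has no transverse dynamics (its T₂ of microseconds makes the
transverse components slave to the RF on any timescale of interest); RF
saturates its Mz directly at `W = π ω₁² g(Δ)` with the Gaussian absorption
lineshape `g(Δ) = (T₂ᵐᵗ/√2π) exp(−(Δ T₂ᵐᵗ)²/2)`, the appropriate choice for
agarose-based tissue-like samples. Exchange with water couples longitudinal
components only. Super-Lorentzian and Lorentzian lineshapes, NOE pools and
systems beyond three pools are out of scope.

All pool shifts ride on the water center `ω_w` (the fitted B0 offset), so a
nonzero `ω_w` shifts every pool's effective offset identically. Positive ppm
is downfield; `γ/2π = 42.5774785 MHz/T` everywhere.

## Saturation schemes

**Pulsed (discretized).** Each shaped pulse is approximated by `n` equal
segments whose amplitudes sample the envelope at segment midpoints, without
renormalizing the discrete flip angle (the midpoint sum converges to the
nominal flip angle; relative error < 1e-4 at 1024 segments). Per offset the
magnetization starts at thermal equilibrium and is propagated exactly through
every segment, the inter-pulse delay, and — when crushers are enabled —
ideal spoiling that zeroes all transverse components at the end of each
delay (alternating crusher polarity adds nothing under ideal spoiling). The
readout value is water Mz/M₀ immediately after the active part of the last
pulse; the trailing delay is not applied (the alternative convention changes
signals at the 1e-3 level).

**Gaussian envelope.** The envelope is truncated where it falls to 1 % of
peak, fixing `σ = t_p / (2√(2 ln 100))` for active duration `t_p`. This is a
common vendor convention but not universal; the minimal-segment results below
are sensitive to it and can shift by a factor of two under a different
truncation. The peak amplitude is calibrated so `γ ∫ B₁ dt` over one pulse
equals the nominal flip angle (closed form via the error function).

**Continuous equivalents.** `AF = (1/T_pd) ∫ B₁ dt` and
`AP = √((1/T_pd) ∫ B₁² dt)`, both integrals over the full pulse period
including the zero-amplitude delay, with total saturation time
`n_pulses · T_pd`. AF depends only on flip angle and period
(`AF = FA_rad/(γ T_pd)`), not on the envelope shape; `AP ≥ AF` always
(Cauchy–Schwarz), with equality only for constant amplitude.

## Numerics

Propagation over a constant-RF interval is the matrix exponential of the
augmented generator `[[A, b], [0, 0]]`. Simulating spectra produces large
stacks of small (7×7 / 8×8) matrices, which are exponentiated together by
scaling-and-squaring with an order-16 Taylor evaluation; the scaling power is
taken from the largest norm in the stack so the scaled norm is ≤ 0.5, giving
truncation error near machine epsilon. The batched path agrees with
`scipy.linalg.expm` to ~1e-15 and with adaptive ODE integration of the same
generator to the integrator tolerance; both comparisons are in the test
suite, including an oracle that integrates the continuous time-varying
Gaussian envelope through all 50 pulses. Identical pulses share their
segment propagators, and the symmetric envelope halves the number of
distinct amplitudes, so one offset costs `n/2 + 1` exponentials regardless
of the pulse count.

## Segment-count calibration

For a given pulse-parameter set the minimal segment count is the smallest
power of two (2…512) whose pulsed spectrum deviates from the 1024-segment
benchmark by less than 0.1 % RMS on the 41-point offset grid (−3.8 to
+3.8 ppm, 0.19 ppm steps). Because z-spectra are already normalized to the
unsaturated reference, the "normalized RMS error" is taken as the plain RMS
of the signal difference; dividing additionally by the benchmark RMS is
available via `relative=True`. The error curve decreases monotonically from
4 segments upward but *not* from 2 to 4 — the two-segment approximation
happens to alias favorably for some parameter sets — so the search simply
scans ascending counts. For the in-vitro parameters the answer is 32; over
the full calibration grid (5 flip angles × 5 periods × 6 duty cycles) it
ranges from 16 to 128.

The AP-adequacy classifier compares, for a candidate pulse-parameter set,
the sum-of-squares difference and the CESTR difference between its AP and
discretized spectra against those of a benchmark set (the in-vitro
parameters by default): both strictly smaller means the AP approximation is
at least as good as one already validated in vitro.

## Model fitting

The nine free parameters are T₂ʷ, T₂ᵐᵗ, M₀ʷ, M₀ˡᵃᵇ, M₀ᵐᵗ, C_labile, C_mt,
ω_w and a B₁ scale; T₁ʷ is measured, T₁ˡᵃᵇ = 1 s, T₂ˡᵃᵇ = 8.5 ms,
T₁ᵐᵗ = 1 s are fixed (the spectrum is insensitive to them), the labile shift
is +1.9 ppm from water and the MT pool sits on water. Default bounds: T₂ʷ
and M₀ʷ ±20 % of measured, M₀ˡᵃᵇ ±5 % of the literature value (exchange rate
and concentration are strongly correlated, so the concentration must be
constrained), ω_w ±0.2 ppm, B₁ scale ±10 %, C_labile ∈ [1, 1000] s⁻¹, and
wide agarose-phantom brackets for the MT pool (T₂ᵐᵗ ∈ [5, 200] µs,
M₀ᵐᵗ ∈ [0, 10] relative, C_mt ∈ [5, 100] s⁻¹) — these MT brackets are
assumptions and should be overridden when better priors exist.

The optimizer is trust-region-reflective least squares on parameters mapped
into a unit box (magnitudes span eight orders, so raw parameters condition
badly). Starting values are bound midpoints, except T₂ʷ/M₀ʷ at their
measured values and ω_w at the WASSR estimate when supplied. A single start
can stall in a local minimum along the exchange-rate axis when the true rate
is far from the midpoint, so the fit multi-starts C_labile at log-spaced
values across its bounds and keeps the lowest-SSE solution, skipping
restarts once the residual reaches numerical noise. Estimates at a bound are
flagged. The forward model is the discretized simulation at the calibrated
segment count (32 for the in-vitro train) or the AP continuous equivalent;
the B₁-scale parameter multiplies the nominal pulse amplitude and ω_w
shifts all resonances together.

Method comparison reports coefficients of variation and a two-tailed t-test
on a fitted parameter between two groups of fits — Welch two-sample by
default, with a paired option for when the groups share voxels. No
multiple-testing correction is applied (vials are tested independently).

## WASSR B0 mapping

The 15 samples around the minimum of a low-power z-spectrum (seven each
side) are resampled by cubic spline onto a 0.0019 ppm grid. Not-a-knot
boundary conditions are used: they reproduce polynomials through cubic
exactly and behave better at the window edges than the natural-spline
alternative. The maximum-symmetry shift minimizes
`C(δ) = Σᵢ [S(2δ − xᵢ) − S(xᵢ)]²` over a bounded scalar search (±0.1 ppm
around the sampled minimum); reflection points outside the dense window are
excluded from the sum. Estimates beyond ±0.2 ppm — outside what shimmed
inhomogeneity should produce — are flagged rather than rejected. On
simulated low-flip-angle acquisitions the estimator is accurate to a few
mHz; translation equivariance holds within one interpolation step.

## Synthetic phantom

The generator emulates a six-vial creatine/agarose phantom: 100 and 125 mM
creatine (labile amine proton concentrations 0.33 and 0.4125 M against
100 M water protons) at pH 5.5, 6.0 and 6.5 on a 32×32 default grid, with
the agar background carrying water + MT only. The amine exchange rate uses
the base-catalysed convenience map `rate = 50 s⁻¹ · 10^(pH−6)` — a decade
per pH unit anchored at 50 s⁻¹ for pH 6, chosen to bracket the slow-to-
intermediate exchange regime (15.8, 50, 158 s⁻¹), not a calibrated
titration curve. B0 (±0.15 ppm default, enveloped at ±0.2 ppm) and B1
(±8 %, enveloped at ±10 %) imperfections are seeded random quadratic
surfaces, mimicking residual shim structure. Noise is additive Gaussian on
the normalized signal with sd 0.005 by default — magnitude-MR Rician
corrections are negligible at phantom SNR. Every voxel's ground truth is
stored losslessly next to the data.

What the phantom does *not* emulate: EPI distortion and ghosting, fat
signal, motion, temperature-dependent exchange, partial-volume edges, and
incomplete T₁ recovery between repetitions (saturation always starts from
thermal equilibrium). Passing round-trip tests on these phantoms therefore
demonstrates correctness of the forward model, calibration and estimator
machinery — not robustness to acquisition artifacts in real scanner data.

## Problem sizes

Default problem sizes keep every stage interactive on a single core: the
41-point offset grid for spectra and calibration; 150 parameter sets for the
full sweep (~20 s total); 10×10 phantom grids with one fitted voxel per
vial for round-trip checks. Larger grids scale linearly in voxels and
offsets.

## Known limitations

- Three pools maximum (water, one labile, one MT); no NOE or multi-labile
  systems.
- The MT pool exchanges longitudinally only; whether a transverse MT
  component matters is not addressed.
- Gaussian and rectangular envelopes only; vendor pulse-shape files,
  adiabatic and binomial pulses are not supported, and a different Gaussian
  truncation convention rescales the minimal-segment calibration.
- The saturation-depth monotonicity in exchange rate holds only up to
  ~100 s⁻¹ at these powers; beyond that, exchange broadening reverses the
  trend — relevant when interpreting fast-exchange (e.g. PARACEST) regimes,
  where the AP approximation also degrades fastest.
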