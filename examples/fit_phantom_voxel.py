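"""Quantify the amine exchange rate from a synthetic phantom voxel.

Generates a small noiseless six-vial creatine/agarose phantom with smooth B0
and B1 imperfections, then fits the nine-parameter three-pool model to one
voxel with the discretized forward model and checks the recovered exchange
rate and water shift against the stored ground truth.
"""

from pulsedcest import PulseTrain, parse_offsets
from pulsedcest.fitting import FitSpec, fit_zspectrum
from pulsedcest.phantom import default_phantom_spec, generate

train = PulseTrain("gaussian", 180.0, 0.040, 0.5, n_pulses=50, crushers=True)
offsets = parse_offsets("-3.8:0.19:3.8")

spec = default_phantom_spec(grid_shape=(10, 10), noise_sd=0.0, seed=7)
dataset = generate(spec, train, offsets, engine="discretized", n_segments=32)

vial_index = 4  # 125 mM creatine at pH 6.0
vial = spec.vials[vial_index]
row, col = dataset.vial_voxels(vial_index)[0]

fit_spec = FitSpec(engine="discretized", n_segments=32,
                   m_labile0_literature=vial.m_labile0)
fit = fit_zspectrum(dataset.spectrum(row, col), fit_spec, train)

true_w = dataset.truth["omega_w"][row, col]
print(f"vial {vial.label}, voxel ({row}, {col})")
print(f"  C_labile: true {vial.c_labile:7.2f} /s   fitted {fit.params['c_labile']:7.2f} /s")
print(f"  omega_w:  true {true_w:+.4f} ppm  fitted {fit.params['omega_w']:+.4f} ppm")
print(f"  B1 scale: true {dataset.truth['b1_scale'][row, col]:.4f}     "
      f"fitted {fit.params['b1_scale']:.4f}")
print(f"  SSE {fit.sse:.2e}, R^2 {fit.r2:.6f}, converged {fit.converged}")
print("-> with the matching forward model and noiseless data the fit recovers")
print("   the exchange rate and field maps essentially exactly.")
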