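"""Recover equivalent-circuit parameters from a noisy spectrum.

Simulates the non-gelled egg circuit with 1% proportional measurement
noise, then fits the same topology by multi-start complex nonlinear
least squares with box bounds one decade wide around the truth.
"""

import numpy as np

import gelspec as gs
from gelspec.circuit import NON_GELLED_PARAMS, default_frequency_grid

rng = np.random.default_rng(7)
grid = default_frequency_grid(50)
clean = gs.simulate_spectrum(gs.non_gelled_preset(), grid)
mag = clean.magnitude
noisy = gs.ImpedanceSpectrum(
    grid,
    clean.resistance + 0.01 * mag * rng.normal(size=mag.size),
    clean.reactance + 0.01 * mag * rng.normal(size=mag.size))

bounds = gs.decade_bounds(dict(NON_GELLED_PARAMS), 0.5, cap={"CPE.n": 1.0})
result = gs.fit_circuit(noisy, gs.FitSpec(gs.non_gelled_preset(), bounds,
                                          seed=7))

print(f"converged: {result.converged}  weighted residual: "
      f"{result.residual:.3e}")
for name, truth in NON_GELLED_PARAMS.items():
    est = result.estimates[name]
    print(f"  {name:8s} truth {truth:11.4g}  estimate {est:11.4g}  "
          f"rel err {abs(est - truth) / truth:8.2e}")
print("\nWith 1% noise the dominant arc parameters (R2, Q0, n) come back "
      "within a percent or so.  R1 (46 ohm) and L1 contribute almost "
      "nothing to a ~150 kohm spectrum over this band, so noise washes "
      "them out; a noiseless fit recovers all five exactly.")
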