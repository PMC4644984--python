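"""Theory: excitation threshold versus ChR2 conductance and retinal dose.

The four-state ChR2(H134R) photocurrent drives an excitable membrane; the
minimal irradiance that triggers an action potential is bisected for each
conductance. Retinal availability scales the conductance, so the composed
curve E_th(dose) shows a steep high-sensitivity region at low doses and a
flat region at saturating doses; a hyperbola fits the monotone part.
"""

import numpy as np

from opticard import chr2
from opticard import excitability as ex

params = chr2.load_params()

g_grid = np.geomspace(0.15, 10.0, 8)
curve = chr2.eth_vs_g(g_grid, pulse_duration=10.0, params=params,
                      rel_precision=0.02)
print("E_th versus conductance (10-ms pulses):")
print(curve.round(4).to_string(index=False))

mapping = chr2.AtrMapping(form="linear", g0=0.4, slope=2.0)
atr = np.array([0.0, 0.1, 0.25, 0.5, 1.0, 2.0])
dose_curve = chr2.eth_vs_atr(mapping, atr, 10.0, params, rel_precision=0.02)
fit = ex.fit_eth_vs_atr(dose_curve["atr"].to_numpy(), dose_curve["e_th"].to_numpy())
print("\nE_th versus supplemental retinal dose (linear dose->conductance):")
print(dose_curve.round(4).to_string(index=False))
print(f"hyperbolic fit k/(a+a0)+E_inf: k={fit.k:.3f}, a0={fit.a0:.3f}, "
      f"E_inf={fit.e_inf:.4f}, R^2={fit.r_squared:.4f}")
print("A small conductance increase in the steep region yields an order-of-"
      "magnitude threshold drop; beyond ~1 uM the curve is nearly flat.")
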