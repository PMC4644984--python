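# Four-state ChR2(H134R) photocycle constants (light- and voltage-dependent
# Markov scheme with two open and two closed states). All rates in 1/ms,
# voltages in mV. Values are configuration, not claims: edit this file to
# swap in a different empirically derived parameterisation.
g_chr2: 2.0            # maximal conductance scale, nS/pF
e_rev_mv: 0.0          # reversal potential of the ChR2 current
gamma: 0.1             # conductance of open state O2 relative to O1
epsilon1: 0.8535       # quantum efficiency of C1 -> O1 activation
epsilon2: 0.14         # quantum efficiency of C2 -> O2 activation
flux_per_irradiance: 0.2   # photon-flux activation rate per (mW/mm^2), 1/ms
tau_activation_ms: 1.3     # relaxation time of the light-activation variable p
gd1:                   # O1 -> C1 closure: base + amp*tanh(-(V - v0)/dv)
  base: 0.075
  amp: 0.043
  v0: -20.0
  dv: 20.0
gd2: 0.05              # O2 -> C2 closure
gr:                    # C2 -> C1 thermal recovery: base*exp(-k*V)
  base: 4.34e-5
  k: 0.0211539274
e12:                   # O1 -> O2: base + amp*ln(1 + E/e0), E in mW/mm^2
  base: 0.011
  amp: 0.005
  e0: 0.024
e21:                   # O2 -> O1
  base: 0.008
  amp: 0.004
  e0: 0.024
rectifier:             # effective driving f(V) = a - b*exp(-V/c), mV scale
  a: 10.6408
  b: 14.6408
  c: 42.7671
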