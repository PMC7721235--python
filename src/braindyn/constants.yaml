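# Canonical constants of the reduced Wong-Wang neural mass model and the
# Friston 2003 Balloon-Windkessel hemodynamics.  Version-controlled so
# alternate constant sets can be swapped without code changes.
version: 1
kinetics:
  a: 270.0           # input-current gain, (nA)^-1
  b: 108.0           # firing threshold, Hz scale
  d: 0.154           # transfer-function curvature, s
  gamma_kinetic: 0.641   # gating rate scaling, dimensionless (time in s, H in Hz)
  tau_s: 0.1         # synaptic gating time constant, s
  J: 0.2609          # synaptic coupling, nA
hemodynamics:
  kappa: 0.65        # vasodilatory signal decay rate, 1/s
  gamma_h: 0.41      # flow elimination rate, 1/s
  tau_h: 0.98        # hemodynamic transit time, s
  alpha_g: 0.32      # Grubb vessel stiffness exponent
  rho: 0.34          # resting oxygen extraction fraction
  V0: 0.02           # resting venous blood volume fraction
  # 1.5T-era BOLD coefficients: k1 = 7*rho, k2 = 2, k3 = 2*rho - 0.2
  k1: 2.38
  k2: 2.0
  k3: 0.48
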