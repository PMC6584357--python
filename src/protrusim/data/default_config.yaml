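# Default parameters for protrusion-mediated lateral-inhibition runs.
# Rates are per simulation time unit; lengths in um.  The signaling
# defaults sit in the bistable mutual-inhibition regime (Hill exponents
# 2, trans-activation saturating near the uninhibited Delta level), with
# fast Notch onset (R_N/mu >> N_th) and slow Notch decay (1/mu) so that
# a contacted cell is inhibited within one protrusion extension time and
# stays refractory for a while after retraction.  They are calibrated so
# the wild-type protrusion-only run reproduces the observed sequential-
# spacing distribution.

signal_params:
  R_N: 80.0
  R_D: 20.0
  a: 0.01
  k: 2.0
  b: 100.0
  h: 2.0
  mu: 2.0
  rho: 20.0
  alpha: 0.0
  beta: 1.0
  noise_frac: 0.01

differentiation_rule:
  p: 0.01
  N_th: 0.2
  q: 6.0

genotypes:
  wild_type:
    lmax_mean: 42.6
    lmax_sd: 20.2
    T_ext: 0.05
    retraction_rate_factor: 1.7
  lamc1:
    lmax_mean: 12.3
    lmax_sd: 4.7
    # 0.05 * (12.3 / 42.6) * 1.4 — mutant arms extend 1.4x slower per um
    T_ext: 0.020211267605633804
    # retraction lasts 1.1x the extension time
    retraction_rate_factor: 0.9090909090909091

simulation:
  n_cells: 50
  diameter_mean: 11.10
  diameter_sd: 4.51
  dt: 0.01
  n_replicates: 100
  seed: 0
  mode: protrusion_only
  soma_alpha: 0.5
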