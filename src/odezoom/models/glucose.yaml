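# Facilitated-diffusion glucose transport across the yeast plasma membrane
# with G6P inhibition of the carrier.  The four carrier binding reactions at
# the inner/outer membrane faces are fast; carrier translocation (alpha,
# beta) is slow and rate limiting.
#
# Parameter values are NOT from the source study (which does not print
# them); they are synthetic placeholders chosen once so that binding is
# >= 10^3 x faster than translocation and the total carrier LE = 0.01.
name: glucose
closed: true
species:
  Glce: 0.5
  Glci: 0.0
  E_G6Pi: 0.0
  E_Glc_G6Pi: 0.0
  G6Pi: 0.05
  E_Glce: 0.0
  E_Glci: 0.0
  Ee: 0.005
  Ei: 0.005
parameters:
  k1: 10000.0
  k_1: 10000.0
  k2: 10000.0
  k_2: 5000.0
  k3: 10000.0
  k_3: 2000.0
  k4: 10000.0
  k_4: 1000.0
  alpha: 1.0
  beta: 1.0
reactions:
  - "Ee + Glce <-> E_Glce : k1, k_1"
  - "Ei + Glci <-> E_Glci : k2, k_2"
  - "E_Glci + G6Pi <-> E_Glc_G6Pi : k3, k_3"
  - "Ei + G6Pi <-> E_G6Pi : k4, k_4"
  - "E_Glci <-> E_Glce : alpha*(E_Glci - E_Glce)"
  - "Ei <-> Ee : beta*(Ei - Ee)"
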