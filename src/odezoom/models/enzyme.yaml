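# Reversible enzyme kinetics: S + E <-> CS -> CP <-> P + E.
# Rate constants and initial conditions as printed for the case study;
# the substrate->product conversion (k2) is the slow step.
name: enzyme
closed: true
species:
  S: 1.0
  E: 1.0
  P: 0.0
  CS: 0.0
  CP: 0.0
parameters:
  k1: 1000.0
  k_1: 2000.0
  k2: 1.0
  k3: 3000.0
  k_3: 1000.0
reactions:
  - "S + E <-> CS : k1*S*E - k_1*CS"
  - "CS -> CP : k2"
  - "CP <-> P + E : k_3*CP - k3*P*E"
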