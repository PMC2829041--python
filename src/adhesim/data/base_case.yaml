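# Base-case parameter set for the leading-edge adhesion/protrusion model.
# Rate constants in min^-1; gains and ratios dimensionless; D_r in um^2/min.
k_ecm: 0.1
E_s: 0.0
I_n: 0.0
C_s: 10.0
p0: 0.005
v0: 0.01
D_r: 15.0
rate_constants:
  n: {k_d: 0.05}            # v-coupled turnover of nascent adhesions
  s: {k_a: 0.01, k_d: 0.02} # maturation source / spontaneous disassembly
  m: {k_a: 20.0, k_d: 2.0}  # myosin recruitment/release; K_m = 10
  x: {k_a: 40.0, k_d: 4.0}  # paxillin phosphorylation/dephosphorylation
  r: {k_a: 40.0, k_d: 4.0}  # Rac activation/deactivation; K_r = 10
  p: {k_a: 80.0, k_d: 4.0}  # PAK activation/deactivation
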