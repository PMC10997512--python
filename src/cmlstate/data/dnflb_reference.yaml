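# Reference parameterization of the DNFL-B gene circuit.
#
# This set was tuned by a 1-D bifurcation scan so that the effective
# transcriptome force F(B, S) has
#   * exactly one stable state (healthy) at S = 0,
#   * five critical points, three of them stable, at S = S_max,
#   * a nondecreasing number of stable states as S increases, and
#   * a monostable TOTO-transformed landscape inside the untreated
#     (c1, c3) basin.
#
# Subscript convention: for g_a_* the first sign refers to the signal S,
# the second to the transcriptome B; for g_b_* the first sign refers to
# the cell compartment A, the second to B.  "m" = regulator low (H-),
# "p" = regulator high (H+).  Rates are in concentration per unit time,
# degradation in 1/time, thresholds in concentration units.
g_a_mm: 3.0    # A production, S low,  B low  (healthy homeostasis)
g_a_pm: 1.0    # A production, S high, B low  (signal erodes regulation)
g_a_mp: 3.0    # A production, S low,  B high
g_a_pp: 0.15   # A production, S high, B high (regulation collapsed)
g_b_mm: 0.4    # B production, A low,  B low
g_b_pm: 0.8    # B production, A high, B low   (regulated baseline)
g_b_mp: 6.5    # B production, A low,  B high  (runaway dysregulation)
g_b_pp: 1.2    # B production, A high, B high  (self-activation, contained)
k_a: 1.0
k_b: 1.0
x0_s: 0.5
n_s: 4
x0_a: 0.93
n_a: 6
x0_b_on_a: 5.0   # threshold at which B represses A
n_b_on_a: 12
x0_b: 2.0        # transcriptome self-activation threshold
n_b: 6
s: 0.0
s_max: 2.0
gamma_circuit: 1.0
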