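# Dynamic-instability regime: strongly reduced polymerisation onto GDP tips
# (k'/k = 0.01) just below the critical concentration.

[params]
k = 3.2        # uM^-1 s^-1, attachment onto a GTP tip
k_prime = 0.032
w_T = 24.0     # s^-1, GTP-tip detachment
w_D = 290.0    # s^-1, GDP-tip detachment
r_hyd = 0.5    # s^-1 per GTP subunit, random hydrolysis

[protocol]
kind = "constant"
C0 = 11.0      # uM free tubulin

[sim]
duration = 2000.0
sample_dt = 1.0
init_n_D = 0   # grow from an empty nucleation site
init_n_T = 0
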