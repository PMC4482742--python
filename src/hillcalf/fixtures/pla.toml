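# Rabbit plantaris (PLA) — mean in-situ Hill-model parameters (n = 6).
name = "PLA"
F_im = 86.4         # N
l_CCopt = 13.2      # mm
l1 = 0.53           # [l_CCopt]
l2 = 0.88
l3 = 1.19
l4 = 2.05
f_c = 0.85          # [F_im]
v_CCmax = 10.1      # [l_CCopt/s]
curv = 0.41
tau = 0.06          # s
F1_frac = 0.31      # [F_im]
dlSEC1_frac = 0.036 # [l_SEC0]
k_sh = 2.6
k = 21.9            # N/mm
l_SEC0 = 102.0      # mm
k1 = 0.114          # N
k2 = 0.47           # 1/mm
l_PEC0 = 9.8        # mm
mass = 6.31         # g
density = 1.056     # g/cm^3
L_MTC_0 = 112.0     # mm
l_fm = 12.1         # mm
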