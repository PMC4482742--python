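# Rabbit soleus (SOL) — mean in-situ Hill-model parameters (n = 6).
name = "SOL"
F_im = 24.1         # N
l_CCopt = 22.1      # mm
l1 = 0.50           # [l_CCopt]
l2 = 0.82
l3 = 1.14
l4 = 1.95
f_c = 0.85          # [F_im]
v_CCmax = 6.4       # [l_CCopt/s]
curv = 0.15
tau = 0.04          # s
F1_frac = 0.43      # [F_im]
dlSEC1_frac = 0.026 # [l_SEC0]
k_sh = 2.7
k = 14.1            # N/mm
l_SEC0 = 86.9       # mm
k1 = 0.034          # N
k2 = 0.35           # 1/mm
l_PEC0 = 16.0       # mm
mass = 3.26         # g
density = 1.056     # g/cm^3
L_MTC_0 = 102.9     # mm
l_fm = 17.1         # mm
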