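# Rabbit gastrocnemius (GAS) — mean in-situ Hill-model parameters (n = 6).
name = "GAS"
F_im = 161.3        # N, maximum isometric force
l_CCopt = 17.7      # mm, optimal CC length
l1 = 0.44           # [l_CCopt] force-length breakpoints
l2 = 0.82
l3 = 1.14
l4 = 2.21
f_c = 0.85          # [F_im], ascending-limb slope change
v_CCmax = 13.5      # [l_CCopt/s]
curv = 0.47         # a/F_im, force-velocity curvature
tau = 0.06          # s, activation time constant
F1_frac = 0.31      # [F_im], SEC exponential-to-linear transition force
dlSEC1_frac = 0.049 # [l_SEC0], SEC transition elongation
k_sh = 2.2          # SEC shape parameter
k = 30.3            # N/mm, SEC linear stiffness (per-animal fit)
l_SEC0 = 105.3      # mm, SEC slack length
k1 = 0.048          # N, PEC scale
k2 = 0.50           # 1/mm, PEC exponent
l_PEC0 = 12.9       # mm, PEC slack length
mass = 16.04        # g, muscle mass
density = 1.056     # g/cm^3, muscle tissue density
L_MTC_0 = 118.2     # mm, MTC length at 90/90 deg ankle/knee
l_fm = 16.9         # mm, mean fascicle length (mean over digitized animals)
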