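# Named parameter sets used throughout the analysis chain.
#
# Dose-response midpoints, Hill slopes and the feedthrough double-Hill
# parameters are published single-channel / imaging estimates for WT and
# D2594-mutant IP3R1.  Ceilings (pmax), the mean open time and the
# generator-side kinetic/noise settings are this package's documented
# modelling choices (see docs/methods.md); recovery analyses are invariant
# to pmax scaling.

# --- IP3 activation of single-channel Po (bilayer, nPo vs [IP3]) ---
wt_ip3:
  kind: hill
  pmax: 0.1          # modelling choice; maximal Po ceiling for WT
  ec50: 660.0e-9     # mol/L
  h: 1.8
d2594k_ip3:
  kind: hill
  pmax: 0.36         # 3.6-fold the WT ceiling (gain-of-function mutant)
  ec50: 406.0e-9
  h: 2.0

# --- Cytosolic Ca2+ biphasic dependence of Po (at 10 uM IP3) ---
wt_cyto_ca:
  kind: biphasic
  pmax: 0.1
  ec50_act: 78.0e-9
  h_act: 2.0
  ic50_inh: 562.0e-9
  h_inh: 2.0
d2594k_cyto_ca:
  kind: biphasic
  pmax: 0.3          # ~3-fold WT peak Po near 300 nM Ca2+
  ec50_act: 101.0e-9
  h_act: 2.0
  ic50_inh: 1380.0e-9
  h_inh: 2.0
d2594a_cyto_ca:
  kind: biphasic
  pmax: 0.1
  ec50_act: 89.0e-9
  h_act: 2.0
  ic50_inh: 399.0e-9
  h_inh: 2.0

# --- Feedthrough: normalized mean open time vs electrochemical driving force ---
wt_mot_edf:
  kind: mot_edf
  range: 3.0         # modelling choice (peak amplitude above baseline 1)
  va50: 111.5        # mV
  ha: 7.8
  vi50: 170.7        # mV
  hi: 3.7

# --- ATP dose-response of global Ca2+ transient amplitude (plate assay) ---
# pmax here is the Delta-F/F0 driving-amplitude ceiling of the generator.
wt_atp:
  kind: hill
  pmax: 3.0
  ec50: 10.9e-6      # mol/L
  h: 1.5             # slope not published; generator choice
d2594k_atp:
  kind: hill
  pmax: 6.0
  ec50: 3.3e-6
  h: 1.5

# --- Ca2+ puff kinetics (linescan imaging) ---
# rise_time r and decay_tau tau chosen through the closed-form identities of
# the linear-rise / exponential-decay event model so that the generated
# events carry the published 20-80% rise time and full-duration-half-maximum:
#   rise_20_80 = 0.6 r;  FDHM = 0.5 r + tau ln 2.
wt_puffs:
  rate: 0.04         # events / s / cell
  fdhm: 0.68         # s (target)
  rise_time: 0.5833333333333334   # r = 0.35 / 0.6
  decay_tau: 0.5602465742118808   # (0.68 - 0.5 r) / ln 2
d2594k_puffs:
  rate: 0.1
  fdhm: 2.39
  rise_time: 1.2666666666666668   # r = 0.76 / 0.6
  decay_tau: 2.534334288494946    # (2.39 - 0.5 r) / ln 2

# --- Unitary conductance (symmetric 250 mM Cs+) ---
conductance:
  gamma_ps: 248.0
  reversal_mv: 0.0
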