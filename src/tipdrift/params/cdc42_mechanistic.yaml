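# Mechanistic GTPase-cycle Cdc42 model — reference parameter set.
#
# Literature-adapted (GTPase cycle with a cytosolic GEF complex recruited by
# active Cdc42, cooperative GEF self-recruitment, uniform Gbg drive and a weak
# Cla4 brake) and calibrated once on the base r = 2.0 um sphere so that the
# model forms a single polarization cap that escapes the tip of a short
# mating projection within a few hundred seconds while remaining compact.
# Copy numbers are deliberately below wild-type yeast abundances to keep
# stochastic ensembles tractable on one CPU; see docs/methods.md.
#
# Units: um, s, molecules.  Bimolecular rates are areal (um^2/s); all
# reactions fire in membrane voxels.
D_cyt: 10.0        # cytoplasmic diffusion D_c (um^2/s)
D_mem: 0.01        # lateral membrane diffusion (um^2/s, FRAP-range)
k_att: 0.005       # spontaneous membrane attachment of Cdc42-GDP (1/s)
k_det: 0.5         # membrane detachment of Cdc42-GDP (1/s)
k_act0: 0.02       # basal activation by the uniform Gbg input (1/s)
k_act: 15.0        # GEF-catalysed activation of cytosolic Cdc42 (um^2/s)
k_hyd: 0.2         # GTP hydrolysis / GAP action (1/s)
k_gef_on: 1.5      # GEF recruitment by active Cdc42 (um^2/s)
k_gg: 30.0         # cooperative GEF self-recruitment (um^2/s)
k_gef_off: 0.2     # GEF membrane release (1/s)
k_cla_on: 0.3      # Cla4 recruitment by active Cdc42 (um^2/s)
k_cla_off: 0.1     # Cla4 membrane release (1/s)
k_neg: 0.3         # Cla4-mediated GEF ejection, negative feedback (um^2/s)
n_cdc42: 350       # total Cdc42 copies (reference sphere)
n_gef: 60          # total GEF-complex copies
n_cla4: 30         # total Cla4 copies
ic_cap_radius: 1.2 # polarized-IC geodesic cap radius (um): the steady-state
                   # cap width measured on the base sphere
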