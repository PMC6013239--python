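# Simplified positive-feedback Cdc42 model (attach / detach / recruit) —
# reference parameter set, literature-adapted and calibrated on the base
# r = 2.0 um sphere to sit inside the stochastic-clustering window of the
# density switch: transient clusters at the reference density, an empty
# membrane at 1% of it.  Units: um, s, molecules.
D_cyt: 10.0    # cytoplasmic diffusion (um^2/s)
D_mem: 0.01    # membrane diffusion (um^2/s)
k_on: 0.002    # spontaneous membrane attachment (1/s, well-mixed effective)
k_off: 0.3     # membrane detachment (1/s)
k_fb: 1.0      # recruitment of cytosolic by membrane-bound Cdc42 (um^2/s)
n_total: 800   # total copies on the reference sphere
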