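# Polarisome (Bni1 / actin cables / Spa2) module — reference parameter set,
# adapted from the 1-D mechanistic polarisome modelling literature and
# re-fitted on the base r = 2.0 um sphere (the original fits are 1-D).
# B_on is the recruitment of Bni1 by active Cdc42.
# Units: um, s, molecules.
D_cyt: 10.0   # cytoplasmic diffusion (um^2/s)
D_mem: 0.01   # membrane diffusion of Bni1m/Spa2m (um^2/s)
B_on: 0.005   # Bni1 recruitment by active Cdc42 (um^2/s)
B_spont: 0.005 # spontaneous Bni1 membrane attachment (1/s)
B_fb: 2.0     # Bni1 recruitment by membrane Spa2, positive feedback (um^2/s)
B_off: 0.3    # Bni1 release (1/s)
A_nuc: 1.0    # actin-cable nucleation per membrane Bni1 (1/s)
A_dec: 0.2    # actin-cable decay (1/s)
S_on: 3.0     # Spa2 delivery along cables (um^2/s)
S_off: 0.3    # Spa2 release (1/s)
V_on: 0.2     # vesicle delivery of Cdc42-GDP along cables (um^2/s; coupled)
n_bni1: 40    # total Bni1 copies
n_spa2: 60    # total Spa2 copies
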