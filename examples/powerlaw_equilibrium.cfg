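# Equilibrium weight of the power-law rule (original parameters).
analysis = equilibrium_powerlaw
model.preset = powerlaw_original
axis1.name = window_T
axis1.start = 5
axis1.stop = 200
axis1.num = 40
axis2.name = delay_d
axis2.start = -15
axis2.stop = 15
axis2.num = 31
seed = 1
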