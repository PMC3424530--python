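# Small Monte-Carlo sweep: NN doublet, nonoscillatory protocol.
analysis = monte_carlo
model.preset = visual_cortex_doublet
fixed.kind = nonoscillatory
fixed.rate_mean = 4
fixed.event_rate = 2
fixed.rate_bg = 1
fixed.duration = 20
fixed.repeats = 4
axis1.name = window_T
axis1.start = 1
axis1.stop = 20
axis1.num = 3
axis2.name = delay_d
axis2.start = -2
axis2.stop = 2
axis2.num = 3
seed = 1
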