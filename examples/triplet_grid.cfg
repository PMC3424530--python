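# Closed-form triplet weight change per cycle at 5 Hz, visual-cortex fit.
analysis = closed_form_triplet
model.preset = visual_cortex_triplet
fixed.freq_f = 5
axis1.name = window_T
axis1.start = 1
axis1.stop = 150
axis1.num = 40
axis2.name = delay_d
axis2.start = -40
axis2.stop = 40
axis2.num = 41
seed = 1
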