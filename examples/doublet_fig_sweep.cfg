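# Expected weight change per pairing for the realistic doublet rule,
# swept over synchronization window T and effective delay d.
analysis = closed_form_doublet
model.preset = visual_cortex_doublet
axis1.name = window_T
axis1.start = 1
axis1.stop = 100
axis1.num = 50
axis2.name = delay_d
axis2.start = -10
axis2.stop = 10
axis2.num = 41
seed = 1
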