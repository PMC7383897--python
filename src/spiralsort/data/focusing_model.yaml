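# Measured lateral equilibrium positions (µm from the outer wall) of the
# three end-product classes in the 170 x 30 µm spiral channel, as
# mean/SD per flow rate (ml/min).  Combinations absent here were not
# measured and are never interpolated.
channel_width_um: 170.0
classes:
  enucleated:
    0.2: {mean: 100.0, sd: 24.0}
    0.4: {mean: 123.0, sd: 22.0}
    0.6: {mean: 131.0, sd: 23.0}
    0.8: {mean: 103.0, sd: 33.0}
    1.0: {mean: 36.0, sd: 21.0}
  nucleated:
    0.2: {mean: 110.0, sd: 20.0}
    0.4: {mean: 125.0, sd: 15.0}
    0.6: {mean: 134.0, sd: 11.0}
    1.0: {mean: 103.0, sd: 32.0}
  nucleus:
    0.4: {mean: 151.0, sd: 23.0}
    0.6: {mean: 156.0, sd: 11.0}
    0.8: {mean: 158.0, sd: 11.0}
    1.0: {mean: 154.0, sd: 18.0}
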