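# Irradiance-series simulation: 6 tyrosine TRAST curves, 2.0-22.9 kW/cm2
scenario:
  name: fig2a_intensity_series
seed: 1
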