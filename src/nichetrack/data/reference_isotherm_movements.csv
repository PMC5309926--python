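isotherm_temp,movement_cooling_km,movement_warming_km
11,-136.53,377.40
12,-87.69,315.24
13,-38.85,260.85
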