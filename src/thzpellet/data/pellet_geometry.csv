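class,diameter,thickness,weight,printed_density,pressure_ton
diabetic,5,0.52,13.4,1.31,1.0
diabetic,5,0.76,15.8,1.06,0.5
diabetic,13,1.05,28.0,1.36,1.0
diabetic,5,1.12,25.9,1.17,0.5
diabetic,5,1.71,34.7,1.03,0.5
diabetic,5,1.81,37.0,1.00,0.5
non-diabetic,5,0.85,17.5,1.05,0.5
non-diabetic,5,1.25,25.5,1.04,0.5
non-diabetic,5,1.79,35.1,1.00,0.5
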