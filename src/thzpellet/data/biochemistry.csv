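analyte,non_diabetic,diabetic,units,reference_interval,method
Albumin,49.10,45.20,g/l,34 to 48,Immunonephelometric method
Glucose,4.34,6.51,mmol/l,3.30 to 6.10,Enzyme method
Triglycerides,0.82,1.69,mmol/l,<1.77,Enzyme method
Glycated hemoglobin,4.8,11.0,%,4 to 6,High-yield liquid chromatography
Bilirubin,0.027,0.007,mmol/l,0.003 to 0.020,Colorimetric method
Creatinine,0.08,0.06,mmol/l,0.06 to 0.10,Kinetic colorimetric method
Total cholesterol,4.49,3.43,mmol/l,3.50 to 5.00,Enzyme method
Uric acid,0.25,0.15,mmol/l,0.20 to 0.42,Colorimetric method
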