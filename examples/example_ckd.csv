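variable_code,variable_name,unit_label,rate_to_standard,standard_unit,normal_min,normal_max,extreme_min,extreme_max
57139A.B,Creatinine,Mg/dL,1,Mg/dL,0.6,1.3,0.1,5
57139A.B,,Mmol/L,11.312,,,,,
57139A.B,,Mg/L,0.1,,,,,
GLUC,Glucose,mg/dL,1,mg/dL,70,100,10,1000
GLUC,,mmol/L,18,,,,,
BP,Blood pressure,mmHg,1,mmHg,60,200,40,260
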