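# Reference ranges for the four Blood-Risk-Score markers.
# "abnormal_direction" is the departure that scores a point.
# Units: triglycerides/glucose/magnesium mmol/L, creatinine umol/L.

[triglycerides]
high = 1.5
abnormal_direction = "high"

[glucose]
low = 3.0
high = 7.8
abnormal_direction = "high"

[magnesium]
low = 0.7
high = 1.1
abnormal_direction = "low"

[creatinine]
low = 64.0
high = 108.0
abnormal_direction = "low"
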