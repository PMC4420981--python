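exposure,disease,rr_central,rr_low,rr_high,increment
fruit,coronary_heart_disease,0.93,0.89,0.96,80
fruit,stroke,0.89,0.85,0.93,80
fruit,oral_cancer,0.72,0.59,0.87,100
fruit,oesophageal_cancer,0.56,0.42,0.74,100
fruit,lung_cancer,0.94,0.90,0.97,80
fruit,stomach_cancer,0.67,0.59,0.76,100
vegetable,coronary_heart_disease,0.89,0.83,0.95,80
vegetable,stroke,0.97,0.92,1.02,80
vegetable,oral_cancer,0.72,0.63,0.82,50
vegetable,oesophageal_cancer,0.87,0.72,1.05,50
vegetable,stomach_cancer,0.70,0.62,0.79,100
red_meat,colorectal_cancer,1.29,1.04,1.60,100
red_meat,type2_diabetes,1.19,1.04,1.37,100
red_meat,stroke,1.21,1.10,1.33,100
processed_meat,colorectal_cancer,1.21,1.04,1.42,50
processed_meat,type2_diabetes,1.51,1.25,1.83,100
processed_meat,coronary_heart_disease,1.37,1.11,1.68,50
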