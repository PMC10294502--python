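consequent,antecedent,support_pct,confidence_pct,lift,exclusive
diabetes,cardiovascular_disease,2.31,35.51,2.06,0
diabetes,cardiovascular_disease;hypertension,1.73,40.12,2.33,1
diabetes,gonarthrosis;hypertension,3.72,31.60,1.84,0
diabetes,hypertension;obesity,1.94,34.60,2.01,0
diabetes,hypertension;spondylosis,3.24,31.52,1.83,0
diabetes,gonarthrosis;hypertension;spondylosis,1.83,36.51,2.12,1
diabetes,gonarthrosis;spondylosis,2.34,28.30,1.64,0
hypertension,cardiovascular_disease,4.31,66.12,1.62,0
hypertension,cardiovascular_disease;diabetes,1.73,74.71,1.84,1
hypertension,cardiovascular_disease;gonarthrosis,1.57,78.67,1.93,1
hypertension,cardiovascular_disease;spondylosis,1.52,72.15,1.77,1
hypertension,cerebrovascular_disease,3.03,69.09,1.70,0
hypertension,depression,1.89,63.39,1.56,1
hypertension,diabetes,11.83,68.78,1.69,0
hypertension,diabetes;gonarthrosis,3.72,79.10,1.94,0
hypertension,diabetes;gonarthrosis;spondylosis,1.83,78.41,1.93,1
hypertension,diabetes;spondylosis,3.24,71.76,1.76,0
hypertension,gonarthrosis,11.78,62.13,1.53,1
hypertension,diabetes;obesity,1.94,78.49,1.93,0
hypertension,gonarthrosis;obesity,1.86,72.16,1.77,0
gonarthrosis,arthritis,3.19,38.46,2.03,0
gonarthrosis,arthritis;hypertension,1.81,42.50,2.24,1
gonarthrosis,cardiovascular_disease,1.99,30.61,1.61,0
gonarthrosis,cardiovascular_disease;hypertension,1.57,36.42,1.92,1
gonarthrosis,diabetes;hypertension,3.72,31.46,1.66,0
gonarthrosis,diabetes;spondylosis,2.34,51.76,2.73,0
gonarthrosis,diabetes;hypertension;spondylosis,1.83,56.56,2.98,1
gonarthrosis,hypertension;obesity,1.86,33.18,1.75,0
gonarthrosis,hypertension;spondylosis,5.03,48.84,2.58,0
spondylosis,arthritis,2.82,33.97,1.72,0
spondylosis,arthritis;hypertension,1.54,36.25,1.84,1
spondylosis,cardiovascular_disease,2.10,32.24,1.64,0
spondylosis,cardiovascular_disease;hypertension,1.52,35.19,1.79,1
spondylosis,diabetes;gonarthrosis;hypertension,1.83,49.29,2.50,1
spondylosis,diabetes;gonarthrosis,2.34,49.72,2.52,0
spondylosis,gonarthrosis,8.27,43.62,2.21,0
spondylosis,gonarthrosis;hypertension,5.03,42.66,2.17,0
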