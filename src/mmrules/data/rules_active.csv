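consequent,antecedent,support_pct,confidence_pct,lift,exclusive
diabetes,cardiovascular_disease,2.04,32.99,1.83,0
diabetes,gonarthrosis;hypertension,2.78,30.68,1.70,0
diabetes,hypertension;obesity,1.55,38.22,2.12,0
diabetes,hypertension;spondylosis,2.59,28.71,1.59,0
hypertension,cardiovascular_disease,3.82,61.86,1.56,0
hypertension,cerebrovascular_disease,2.93,69.00,1.74,0
hypertension,diabetes,11.37,63.13,1.59,0
hypertension,diabetes;spondylosis,2.59,69.71,1.75,0
hypertension,diabetes;gonarthrosis,2.78,71.58,1.80,0
hypertension,diabetes;obesity,1.55,87.95,2.21,0
hypertension,gonarthrosis;obesity,1.51,71.72,1.80,0
gonarthrosis,arthritis,2.23,34.20,2.11,0
gonarthrosis,cardiovascular_disease,1.68,27.15,1.67,0
gonarthrosis,diabetes;hypertension,2.78,24.44,1.51,0
gonarthrosis,diabetes;spondylosis,1.57,42.29,2.61,0
gonarthrosis,obesity,2.10,30.84,1.90,1
gonarthrosis,hypertension;obesity,1.51,37.17,2.29,0
gonarthrosis,hypertension;spondylosis,3.75,41.65,2.57,0
spondylosis,arthritis,2.23,34.20,1.91,0
spondylosis,cardiovascular_disease,1.76,28.52,1.59,0
spondylosis,gonarthrosis,6.36,39.22,2.19,0
spondylosis,diabetes;gonarthrosis,1.57,40.44,2.26,0
spondylosis,gonarthrosis;hypertension,3.75,41.45,2.31,0
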