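disease,AG_consequent,AG_antecedent,AG_total,IG_consequent,IG_antecedent,IG_total,increase_pct
spondylosis,5,2,7,8,9,17,143
gonarthrosis,7,3,10,9,12,21,110
hypertension,7,7,14,13,15,28,100
diabetes,4,4,8,7,11,18,125
arthritis,0,2,2,0,4,4,100
cardiovascular_disease,0,4,4,0,10,10,150
cerebrovascular_disease,0,1,1,0,1,1,0
obesity,0,3,3,0,4,4,33
depression,0,0,0,0,1,1,
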