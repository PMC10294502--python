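# Mapping from the 30 raw KHPS chronic-condition codes to the 14 grouped
# disease codes used in the analysis. Every raw code maps to exactly one
# group; the map is surjective onto the 14 groups. Obesity is the 15th
# analysis condition and is derived from BMI, not from a raw code.
groups:
  - hypertension
  - diabetes
  - chronic_liver_disease
  - gonarthrosis
  - arthritis
  - spondylosis
  - cancer
  - cardiovascular_disease
  - cerebrovascular_disease
  - chronic_respiratory_disease
  - thyroid_disease
  - depression
  - alzheimers_disease
  - chronic_renal_failure
mapping:
  hypertension: hypertension
  diabetes: diabetes
  chronic_hepatitis: chronic_liver_disease
  alcoholic_hepatitis: chronic_liver_disease
  hepatic_cirrhosis: chronic_liver_disease
  gonarthrosis: gonarthrosis
  degenerative_arthritis: arthritis
  rheumatoid_arthritis: arthritis
  disc_disorder: spondylosis
  other_spondylopathy: spondylosis
  gastric_cancer: cancer
  colorectal_cancer: cancer
  lung_cancer: cancer
  breast_cancer: cancer
  cervical_cancer: cancer
  thyroid_cancer: cancer
  other_cancer: cancer
  angina: cardiovascular_disease
  myocardial_infarction: cardiovascular_disease
  cerebral_hemorrhage: cerebrovascular_disease
  cerebral_infarction: cerebrovascular_disease
  asthma: chronic_respiratory_disease
  pulmonary_emphysema: chronic_respiratory_disease
  copd: chronic_respiratory_disease
  bronchiectasis: chronic_respiratory_disease
  hypothyroidism: thyroid_disease
  hyperthyroidism: thyroid_disease
  depression: depression
  alzheimers_disease: alzheimers_disease
  chronic_renal_failure: chronic_renal_failure
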