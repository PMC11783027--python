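condition,group,body_system
gout,gout,musculoskeletal conditions
osteoarthritis,osteoarthritis,musculoskeletal conditions
rheumatoid arthritis,inflammatory arthritis,musculoskeletal conditions
osteoporosis,osteoporosis,musculoskeletal conditions
hypertension,hypertension,disease of the circulatory system
myocardial infarction,coronary heart disease,disease of the circulatory system
angina,coronary heart disease,disease of the circulatory system
atrial fibrillation,atrial fibrillation,disease of the circulatory system
heart failure,heart failure,disease of the circulatory system
peptic ulcer,ulcer and upper gastrointestinal acid conditions,diseases of the digestive system
gastro-oesophageal reflux,ulcer and upper gastrointestinal acid conditions,diseases of the digestive system
liver failure,liver disease,diseases of the digestive system
chronic obstructive pulmonary disease,chronic lung disease,diseases of the respiratory system
asthma,chronic lung disease,diseases of the respiratory system
chronic kidney disease,chronic kidney disease,diseases of the genitourinary system
end-stage renal disease,chronic kidney disease,diseases of the genitourinary system
urinary incontinence,urinary conditions,diseases of the genitourinary system
diabetes,diabetes,diseases of the endocrine system
hypothyroidism,thyroid disorders,diseases of the endocrine system
depression,depression,mental health conditions
alcohol misuse,alcohol problems,mental health conditions
Hodgkin lymphoma,hematological cancers,cancers
leukemia,hematological cancers,cancers
metastatic solid tumour,solid organ cancer (secondary),cancers
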