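deficit,condition
activity limitation,
anaemia and haematinic deficiency,
arthritis,gout
arthritis,osteoarthritis
arthritis,rheumatoid arthritis
atrial fibrillation,atrial fibrillation
cerebrovascular disease,
chronic kidney disease,chronic kidney disease
chronic kidney disease,end-stage renal disease
diabetes,diabetes
dizziness,
dyspnoea,
falls,
foot problems,
fragility fracture,
hearing impairment,
heart failure,heart failure
heart valve disease,
housebound,
hypertension,hypertension
hypotension or syncope,
ischaemic heart disease,myocardial infarction
ischaemic heart disease,angina
memory and cognitive problems,
mobility and transfer problems,
osteoporosis,osteoporosis
parkinsonism and tremor,
peptic ulcer,peptic ulcer
peptic ulcer,gastro-oesophageal reflux
peripheral vascular disease,
polypharmacy,
requirement for care,
respiratory disease,chronic obstructive pulmonary disease
respiratory disease,asthma
skin ulcer,
sleep disturbance,
social vulnerability,
thyroid disease,hypothyroidism
urinary incontinence,urinary incontinence
urinary system disease,
visual impairment,
weight loss and anorexia,
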