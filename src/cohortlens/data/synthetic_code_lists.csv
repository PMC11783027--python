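condition,source,code
gout,primary,R001G.1
gout,primary,R001G.2
gout,hospital,H001G
osteoarthritis,primary,R002O.1
osteoarthritis,primary,R002O.2
osteoarthritis,hospital,H002O
rheumatoid arthritis,primary,R003RA.1
rheumatoid arthritis,primary,R003RA.2
rheumatoid arthritis,hospital,H003RA
osteoporosis,primary,R004O.1
osteoporosis,primary,R004O.2
osteoporosis,hospital,H004O
hypertension,primary,R005H.1
hypertension,primary,R005H.2
hypertension,hospital,H005H
myocardial infarction,primary,R006MI.1
myocardial infarction,primary,R006MI.2
myocardial infarction,hospital,H006MI
angina,primary,R007A.1
angina,primary,R007A.2
angina,hospital,H007A
atrial fibrillation,primary,R008AF.1
atrial fibrillation,primary,R008AF.2
atrial fibrillation,hospital,H008AF
heart failure,primary,R009HF.1
heart failure,primary,R009HF.2
heart failure,hospital,H009HF
peptic ulcer,primary,R010PU.1
peptic ulcer,primary,R010PU.2
peptic ulcer,hospital,H010PU
gastro-oesophageal reflux,primary,R011GOR.1
gastro-oesophageal reflux,primary,R011GOR.2
gastro-oesophageal reflux,hospital,H011GOR
liver failure,primary,R012LF.1
liver failure,primary,R012LF.2
liver failure,hospital,H012LF
chronic obstructive pulmonary disease,primary,R013COPD.1
chronic obstructive pulmonary disease,primary,R013COPD.2
chronic obstructive pulmonary disease,hospital,H013COPD
asthma,primary,R014A.1
asthma,primary,R014A.2
asthma,hospital,H014A
chronic kidney disease,primary,R015CKD.1
chronic kidney disease,primary,R015CKD.2
chronic kidney disease,hospital,H015CKD
end-stage renal disease,primary,R016ESRD.1
end-stage renal disease,primary,R016ESRD.2
end-stage renal disease,hospital,H016ESRD
urinary incontinence,primary,R017UI.1
urinary incontinence,primary,R017UI.2
urinary incontinence,hospital,H017UI
diabetes,primary,R018D.1
diabetes,primary,R018D.2
diabetes,hospital,H018D
hypothyroidism,primary,R019H.1
hypothyroidism,primary,R019H.2
hypothyroidism,hospital,H019H
depression,primary,R020D.1
depression,primary,R020D.2
depression,hospital,H020D
alcohol misuse,primary,R021AM.1
alcohol misuse,primary,R021AM.2
alcohol misuse,hospital,H021AM
Hodgkin lymphoma,primary,R022HL.1
Hodgkin lymphoma,primary,R022HL.2
Hodgkin lymphoma,hospital,H022HL
leukemia,primary,R023L.1
leukemia,primary,R023L.2
leukemia,hospital,H023L
metastatic solid tumour,primary,R024MST.1
metastatic solid tumour,primary,R024MST.2
metastatic solid tumour,hospital,H024MST
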