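condition,weight
myocardial infarction,1
heart failure,1
chronic obstructive pulmonary disease,1
rheumatoid arthritis,1
peptic ulcer,1
diabetes,1
chronic kidney disease,2
end-stage renal disease,2
Hodgkin lymphoma,2
leukemia,2
liver failure,3
metastatic solid tumour,6
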