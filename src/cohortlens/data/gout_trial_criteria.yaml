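# Example trial criteria for a gout cohort, mirroring a published
# urate-lowering trial: adults of any gender and ethnicity, excluding
# patients with selected comorbidities or prescriptions that would
# contraindicate the trial drug.
name: example gout trial
inclusion:
  age:
    min: 18
  gender: any
  ethnicity: any
exclusion:
  conditions:
    - end-stage renal disease
    - alcohol misuse
    - liver failure
  drugs:
    - bendroflumethiazide
    - hydrochlorothiazide
    - cyclopenthiazide
    - indapamide
    - aspirin
    - mesalazine
    - sulfasalazine
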