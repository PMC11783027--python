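drug,class,chapter
bendroflumethiazide,thiazide diuretics,02 cardiovascular system
hydrochlorothiazide,thiazide diuretics,02 cardiovascular system
cyclopenthiazide,thiazide diuretics,02 cardiovascular system
indapamide,thiazide diuretics,02 cardiovascular system
aspirin,antiplatelet drugs,02 cardiovascular system
simvastatin,statins,02 cardiovascular system
atorvastatin,statins,02 cardiovascular system
losartan,angiotensin receptor blockers,02 cardiovascular system
candesartan,angiotensin receptor blockers,02 cardiovascular system
warfarin,oral anticoagulants,02 cardiovascular system
apixaban,oral anticoagulants,02 cardiovascular system
mesalazine,aminosalicylates,01 gastrointestinal system
sulfasalazine,aminosalicylates,01 gastrointestinal system
omeprazole,proton pump inhibitors,01 gastrointestinal system
paracetamol,non-opioid analgesics,04 central nervous system
amitriptyline,antidepressant drugs,04 central nervous system
metformin,antidiabetic drugs,06 endocrine system
levothyroxine,thyroid hormones,06 endocrine system
allopurinol,drugs for gout,10 musculoskeletal and joint disease
colchicine,drugs for gout,10 musculoskeletal and joint disease
naproxen,non-steroidal anti-inflammatory drugs,10 musculoskeletal and joint disease
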