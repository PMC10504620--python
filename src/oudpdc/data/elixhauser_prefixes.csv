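icd10_prefix,category
F10,Alcohol
E52,Alcohol
F11,Drugs
F12,Drugs
F13,Drugs
F14,Drugs
F15,Drugs
F16,Drugs
E66,Obesity
E86,FluidsLytes
E87,FluidsLytes
E222,FluidsLytes
G25,NeuroOther
G31,NeuroOther
G40,NeuroOther
G41,NeuroOther
R56,NeuroOther
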