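compound,coefficient,sorbent,field_L_kg,batch_L_kg
tetracycline,K_s,sand,1.4,
tetracycline,K_bc,CH,12.2,1859
tetracycline,K_bc,CHCHI,12.7,648
enrofloxacin,K_s,sand,<0.1,
enrofloxacin,K_bc,CH,7.0,1315
enrofloxacin,K_bc,CHCHI,8.4,1551
atrazine,K_s,sand,0.2,
atrazine,K_bc,CH,24.6,292
atrazine,K_bc,CHCHI,<0.1,279
diuron,K_s,sand,0.7,
diuron,K_bc,CH,19.2,2405
diuron,K_bc,CHCHI,1.7,866
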