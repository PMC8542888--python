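name,molecular_mass_g_mol,pka,logp
acetaminophen,151,9.5,0.51
atrazine,215,1.68,2.61
diclofenac,296,4.15,4.51
enrofloxacin,359,5.88-6.06;7.70-7.74,4.7
diuron,233,n/a,2.87
tetracycline,444,multiple,0.09
oxytetracycline,460,multiple,-0.9
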