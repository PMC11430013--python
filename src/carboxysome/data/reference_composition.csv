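category,protein,structure,monomers_per_unit,monomer_mw_kda,monomer_copies,monomer_copies_sd
structural,CcmK2,hexamer,6,10.9,11853,2191
structural,CcmK3,hexamer,6,10.8,12,2
structural,CcmK4,hexamer,6,11.9,127,27
structural,CcmL,pentamer,5,11.0,29,8
structural,CcmO,pseudohexamer,6,29.4,7,7
structural,CcmP,pseudohexamer,6,23.2,30,22
structural,CcmM35,monomer,1,35.2,730,331
structural,CcmM58,monomer,1,57.8,112,27
structural,CcmN,monomer,1,16.3,8,2
catalytic,RbcL,L8S8 hexadecamer,8,52.4,5112,0
catalytic,RbcS,L8S8 hexadecamer,8,13.3,6919,825
catalytic,RbcX,dimer,2,17.0,7,7
catalytic,CcaA,hexamer,6,30.2,169,151
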