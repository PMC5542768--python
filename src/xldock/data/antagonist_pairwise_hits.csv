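ligand,ligand_chain,ligand_seq,ligand_res,receptor_chain,receptor_seq,receptor_res,crosslinker
dFX-CRF(12-41),L,12,PHE,R,329,LEU,NTERM_CLAC_CYS
dFX-CRF(12-41),L,12,PHE,R,330,PHE,NTERM_CLAC_CYS
dFX-CRF(12-41),L,12,PHE,R,348,ASN,NTERM_CLAC_CYS
dFX-CRF(12-41),L,13,HIS,R,329,LEU,LYS_CLAC_CYS
dFX-CRF(12-41),L,13,HIS,R,330,PHE,LYS_CLAC_CYS
dFX-CRF(12-41),L,13,HIS,R,344,PHE,LYS_CLAC_CYS
dFX-CRF(12-41),L,14,LEU,R,123,ASN,LYS_CLAC_CYS
dFX-CRF(12-41),L,15,LEU,R,341,ARG,LYS_CLAC_CYS
dFX-CRF(12-41),L,15,LEU,R,345,ILE,LYS_CLAC_CYS
dFX-CRF(12-41),L,17,GLU,R,123,ASN,LYS_CLAC_CYS
dFX-CRF(12-41),L,17,GLU,R,173,GLN,LYS_CLAC_CYS
dFX-CRF(12-41),L,17,GLU,R,345,ILE,LYS_CLAC_CYS
dFX-CRF(12-41),L,18,VAL,R,120,VAL,LYS_CLAC_CYS
dFX-CRF(12-41),L,31,ALA,R,104,GLU,LYS_CLAC_CYS
dFX-CRF(12-41),L,33,SER,R,73,TYR,LYS_CLAC_CYS
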