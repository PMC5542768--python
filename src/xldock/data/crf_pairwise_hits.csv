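ligand,ligand_chain,ligand_seq,ligand_res,receptor_chain,receptor_seq,receptor_res,crosslinker
CRF,L,13,HIS,R,330,PHE,LYS_CLAC_CYS
CRF,L,13,HIS,R,344,PHE,LYS_CLAC_CYS
CRF,L,15,LEU,R,173,GLN,LYS_CLAC_CYS
CRF,L,17,GLU,R,345,ILE,LYS_CLAC_CYS
CRF,L,18,VAL,R,120,VAL,LYS_CLAC_CYS
CRF,L,31,ALA,R,104,GLU,LYS_CLAC_CYS
CRF,L,33,SER,R,73,TYR,LYS_CLAC_CYS
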