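ligand_chain,ligand_seq,ligand_anchor,receptor_chain,receptor_seq,receptor_anchor,d0,k
L,8,CB,R,273,CB,9.0,10.0
L,8,CB,R,330,CB,9.0,10.0
L,12,CB,R,329,CB,9.0,10.0
L,12,CB,R,330,CB,9.0,10.0
L,12,CB,R,333,CB,9.0,10.0
L,12,CB,R,345,CB,9.0,10.0
L,12,CB,R,348,CB,9.0,10.0
L,12,CB,R,349,CB,9.0,10.0
L,14,CB,R,349,CB,9.0,10.0
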