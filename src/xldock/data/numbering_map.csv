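chain,seq,generic,domain
R,73,ECD,ECD
R,104,hinge,hinge
R,119,1.39,helix I
R,120,1.40,helix I
R,123,1.43,helix I
R,124,1.44,helix I
R,169,2.64,helix II
R,173,2.68,helix II
R,176,2.71,helix II
R,195,3.36,helix III
R,199,3.40,helix III
R,260,ECL2,ECL2
R,261,ECL2,ECL2
R,262,ECL2,ECL2
R,263,ECL2,ECL2
R,264,ECL2,ECL2
R,265,ECL2,ECL2
R,267,ECL2,ECL2
R,269,5.36,helix V
R,270,5.37,helix V
R,272,5.39,helix V
R,273,5.40,helix V
R,277,5.44,helix V
R,324,6.50,helix VI
R,325,6.51,helix VI
R,326,6.52,helix VI
R,329,6.55,helix VI
R,330,6.56,helix VI
R,333,6.59,helix VI
R,336,ECL3,ECL3
R,341,7.35,helix VII
R,344,7.38,helix VII
R,345,7.39,helix VII
R,348,7.42,helix VII
R,349,7.43,helix VII
R,355,7.49,helix VII
R,356,7.50,helix VII
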