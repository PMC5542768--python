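ligand,chain,seq,generic,domain
CRF,R,119,,
CRF,R,195,,
CRF,R,262,,
CRF,R,264,,
CRF,R,265,,
CRF,R,267,,
CRF,R,269,,
CRF,R,270,,
CRF,R,329,,
CRF,R,330,,
CRF,R,336,,
Ucn1,R,119,,
Ucn1,R,195,,
Ucn1,R,262,,
Ucn1,R,264,,
Ucn1,R,265,,
Ucn1,R,267,,
Ucn1,R,269,,
Ucn1,R,270,,
Ucn1,R,329,,
Ucn1,R,330,,
Ucn1,R,336,,
CRF(9-41),R,119,,
CRF(9-41),R,195,,
CRF(9-41),R,260,,
CRF(9-41),R,261,,
CRF(9-41),R,262,,
CRF(9-41),R,263,,
CRF(9-41),R,272,,
CRF(9-41),R,273,,
CRF(9-41),R,277,,
CRF(9-41),R,325,,
CRF(9-41),R,326,,
CRF(9-41),R,329,,
CRF(9-41),R,330,,
Ucn1(8-40),R,119,,
Ucn1(8-40),R,195,,
Ucn1(8-40),R,260,,
Ucn1(8-40),R,261,,
Ucn1(8-40),R,262,,
Ucn1(8-40),R,263,,
Ucn1(8-40),R,272,,
Ucn1(8-40),R,273,,
Ucn1(8-40),R,277,,
Ucn1(8-40),R,325,,
Ucn1(8-40),R,326,,
Ucn1(8-40),R,329,,
Ucn1(8-40),R,330,,
dFX-CRF(12-41),R,119,,
dFX-CRF(12-41),R,195,,
dFX-CRF(12-41),R,260,,
dFX-CRF(12-41),R,261,,
dFX-CRF(12-41),R,262,,
dFX-CRF(12-41),R,263,,
dFX-CRF(12-41),R,325,,
dFX-CRF(12-41),R,326,,
dFX-CRF(12-41),R,329,,
dFX-CRF(12-41),R,330,,
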