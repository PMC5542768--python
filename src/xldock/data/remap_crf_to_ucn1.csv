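from_seq,to_seq
13,12
15,14
17,16
18,17
31,30
33,32
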