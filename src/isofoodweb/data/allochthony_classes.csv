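source,class
S1,autochthonous
S2,autochthonous
S3,autochthonous
S4,autochthonous
S5,autochthonous
S6,allochthonous
S7,allochthonous
S8,allochthonous
S9,autochthonous
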