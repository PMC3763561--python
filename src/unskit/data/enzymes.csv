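name,site,cut_top,cut_bottom
I-SceI,TAGGGATAACAGGGTAAT,9,5
XbaI,TCTAGA,1,5
XhoI,CTCGAG,1,5
FseI,GGCCGGCC,6,2
PacI,TTAATTAA,5,3
EcoRI,GAATTC,1,5
HindIII,AAGCTT,1,5
BamHI,GGATCC,1,5
NdeI,CATATG,2,4
PstI,CTGCAG,5,1
SpeI,ACTAGT,1,5
NotI,GCGGCCGC,2,6
EcoRV,GATATC,3,3
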