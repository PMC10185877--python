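lncRNA	in_original	in_expanded
C5orf66-AS1	1	1
CYTOR	0	1
SPRY4-IT1	0	1
FAM3D-AS1	0	1
HAND2-AS1	0	1
H19	0	1
LUCAT1	0	1
HEIH	0	1
HOTAIR	1	1
EPB41L4A-AS2	0	0
LNC-JPH1-7	0	0
LNC-LCE5A-1	0	0
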