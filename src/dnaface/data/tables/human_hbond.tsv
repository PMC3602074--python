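# Hydrogen bonds in the human TLR9 ECD - CpG ODN complex model.
# Chain A = protein, chain S = ODN; distance in Angstrom (H...acceptor),
# angle in degrees (donor-H...acceptor).
donor	acceptor	distance	angle
A:TYR224:HH	S:DG9:OP1	2.18	121.3
A:ARG337:HH22	S:DT5:O2	2.48	86.1
A:LYS338:HZ2	S:DC8:O2	2.06	126.2
A:LYS338:HZ2	S:DG9:N3	2.43	107.2
A:LYS367:HZ1	S:DT5:O4	1.67	129.8
S:DC3:H42	A:GLN335:OE1	2.11	130.1
S:DG6:H22	A:ARG311:O	2.21	165.8
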