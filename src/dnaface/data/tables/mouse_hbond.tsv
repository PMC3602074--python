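# Hydrogen bonds in the mouse TLR9 ECD - CpG ODN complex model.
# "*" spellings of primed sugar atoms are kept as published and
# normalized on parse.
donor	acceptor	distance	angle
A:TYR224:HH	S:DC13:OP1	2.41	133.1
A:TYR224:HH	S:DC13:O5*	1.84	149.3
A:SER311:HG	S:DG15:O6	2.11	111.5
A:LYS338:HZ2	S:DT14:O2	2.28	124.7
A:ASN370:HD22	S:DT10:OP1	2.15	130.5
A:LYS392:HZ1	S:C17:O3*	2.48	152.6
S:DG15:H22	A:ARG337:NE	2.44	105.8
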