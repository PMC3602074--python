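# Idealized B-form nucleotide template (helix axis = z).
# Local chemistry from CCD ideal coordinates; shared
# sugar-phosphate backbone posed so that Rz(36deg)+3.38A
# connects O3'->P and the 180-deg dyad about x generates
# Watson-Crick pairing.  columns: atom_name element x y z
P	P	5.8584	4.9030	0.0691
OP1	O	5.7908	6.2933	-0.4331
OP2	O	4.6476	4.0464	-0.5565
O5'	O	5.7413	4.9059	1.6743
C5'	C	4.4831	5.5000	1.9959
C4'	C	3.7554	5.8850	0.7065
O4'	O	3.0707	4.7425	0.1432
C3'	C	2.6104	6.8858	1.0034
O3'	O	2.8582	7.6013	2.2151
C2'	C	1.6605	6.6557	-0.1956
C1'	C	2.0421	5.2572	-0.7168
N9	N	0.8693	4.3718	-0.6788
C8	C	-0.4366	4.7646	-0.6485
N7	N	-1.2117	3.7194	-0.6191
C5	C	-0.4516	2.5972	-0.6289
C6	C	-0.7389	1.2123	-0.6092
O6	O	-1.8905	0.8143	-0.5758
N1	N	0.2944	0.3429	-0.6357
C2	C	1.5774	0.7988	-0.6670
N2	N	2.6067	-0.1078	-0.6854
N3	N	1.8575	2.0826	-0.6843
C4	C	0.8874	3.0038	-0.6684
H1	H	0.1214	-0.6118	-0.6224
H21	H	3.5254	0.2018	-0.7119
H22	H	2.4161	-1.0589	-0.6679
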