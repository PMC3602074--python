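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
N9	N	0.8693	4.3718	-0.6770
C8	C	-0.4352	4.7627	-0.6646
N7	N	-1.2115	3.7191	-0.6263
C5	C	-0.4562	2.5946	-0.6174
C6	C	-0.7328	1.2181	-0.5731
N6	N	-2.0380	0.7589	-0.5400
N1	N	0.2877	0.3666	-0.5693
C2	C	1.5349	0.7955	-0.5999
N3	N	1.8424	2.0745	-0.6362
C4	C	0.8889	3.0008	-0.6430
H61	H	-2.2165	-0.1940	-0.5142
H62	H	-2.7746	1.3909	-0.5398
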