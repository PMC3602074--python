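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
N1	N	1.0071	4.2219	-0.8502
C2	C	1.3095	2.8445	-0.9071
O2	O	2.4547	2.3912	-0.8624
N3	N	0.2011	1.9990	-1.0202
C4	C	-1.1324	2.3750	-1.0793
O4	O	-2.0599	1.5764	-1.1777
C5	C	-1.3714	3.8414	-1.0148
C7	C	-2.7840	4.3273	-1.0739
C6	C	-0.3119	4.6538	-0.9064
H3	H	0.3947	1.0027	-1.0624
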