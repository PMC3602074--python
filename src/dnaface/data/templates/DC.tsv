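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
N1	N	0.8692	4.3719	-0.6784
C2	C	1.0388	3.0382	-0.6675
O2	O	2.1680	2.5766	-0.6901
N3	N	-0.0060	2.2126	-0.6333
C4	C	-1.2439	2.6870	-0.6090
N4	N	-2.3156	1.8251	-0.5744
C5	C	-1.4552	4.0806	-0.6237
C6	C	-0.3836	4.9066	-0.6540
H41	H	-2.1663	0.8668	-0.5678
H42	H	-3.2196	2.1755	-0.5520
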