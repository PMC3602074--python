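# Hydrophobic contacts in the mouse TLR9 ECD - CpG ODN complex model.
amino_acid	protein_atoms	nucleotide	nucleotide_atoms
Tyr224	CE1,CZ	C13	C3'
Val248	CG1	T14	C7
Glu287	CB,CG,CD	T14	C4,C5,C7
Ser311	CB	T14	C4
Ser311	CB	G15	C6
Val312	CG2	C12	C5
Val312	CB,CG1,CG2	C13	C5, C6
Val312	CB,CG1	T14	C4
Thr334	CB,CG2	G18	C4',C1'
Thr334	CB,CG2	T19	C5',C4'
Arg335	CA,CB,CG,CD	A16	C2,C6
Arg335	CB,CG,CD,CZ	C17	C2,C4
Arg335	CD,CZ	G18	C2
Arg337	CB,CG,CD,CZ	G15	C2,C6
Arg337	CZ	C17	C4',C5'
Lys338	CB,CG	C13	C4
Lys338	CG	T14	C2
Phe343	CE1	T10	C5'
Val364	CG2	G18	C5'
His397	CG,CD2,CE1	T10	C7
His397	CE1	G9	C2',C3'
Gln399	CD	G9	C5'
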