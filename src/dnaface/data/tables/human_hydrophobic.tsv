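# Hydrophobic contacts in the human TLR9 ECD - CpG ODN complex model.
# Comma-separated atom cells list every contacting atom of the residue pair.
amino_acid	protein_atoms	nucleotide	nucleotide_atoms
TYR224	CZ	C8	C3'
VAL248	CG1	C8	C5'
VAL290	CG2	G9	C5'
VAL312	CB	G6	C2
VAL312	CG1	C8	C5'
VAL312	CG2	A7	C2
ASP314	CB	G9	C5'
ARG337	CD,CZ	A4	C2,C5,C6
ARG337	CZ	T5	C2
ARG337	CB,CZ	G6	C2,C4,C5,C6
LYS338	CD	A7	C2
LYS338	CD,CE	C8	C2
LYS338	CE	G9	C2
ASN340	CG	T10	C5'
VAL364	CG1	C3	C5
ALA365	CB	A4	C6
LYS367	CE	T5	C4,C5
MET392	CE	C3	C2',C3'
ARG397	CZ	T11	C5'
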