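# Packaged data

## `tables/`

TSV transcriptions of published interaction tables for the modelled human
and mouse TLR9 ECD – CpG ODN 1826 complexes (chain `A` = protein, chain
`S` = ODN). Two schemas:

- hydrophobic tables: `amino_acid`, `protein_atoms`, `nucleotide`,
  `nucleotide_atoms`. Multi-atom cells are comma-separated and are kept
  as lists on parse (no pair expansion — how multi-atom rows map onto
  per-pair counts is not defined by the source lists, so only
  distinct-residue aggregation is unambiguous).
- H-bond tables: `donor`, `acceptor` (`CHAIN:RESNAMESEQ:ATOM` notation),
  `distance` (Å, H⋯acceptor), `angle` (degrees, donor–H⋯acceptor).

Primed sugar atoms are written with an ASCII apostrophe (`C3'`); the
`*` spelling (`O5*`) occurring in the mouse H-bond table is kept verbatim
and normalized on parse. Bare one-letter nucleotide codes (`C17`) are
normalized to `DC17` on parse.

## `templates/`

Idealized B-form deoxynucleotide templates, one TSV per residue
(`atom_name element x y z`, Å, helix axis = z). All four share one
sugar–phosphate backbone. Local bond geometry comes from the chemical
component dictionary's ideal coordinates; the rigid pose and internal
torsions were fitted once, offline, so that the canonical helical
operator (36.0° twist, 3.38 Å rise) produces a connected O3′(k)–P(k+1)
backbone and the 180° dyad about x generates Watson–Crick pairing.
These are convention-grade fiber-style templates, not refined
experimental geometry.
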