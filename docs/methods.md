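# Methods

## Molecular data model

Structures are Chain → Residue → Atom hierarchies with coordinates in Å.
Residue kind (protein / nucleic / other) is derived from the residue name
via embedded dictionaries; residue numbering is taken verbatim from the
input, since published contact lists use author numbering. Atoms are
referenced as `CHAIN:RESNAMESEQ:ATOMNAME` (`A:ARG337:CZ`) throughout.
PDB parsing is delegated to gemmi; alternate locations are resolved to
the highest-occupancy conformer (ties: first seen) and waters are dropped
by default because the solvent is represented by the SASA probe. Writing
emits fixed-column ATOM records (3-decimal coordinates, TER per chain).

## Group radii

The default radius set (`chothia_group`) uses united-atom class radii:
tetrahedral C 1.87 Å, trigonal/aromatic C 1.76 Å, N 1.65 Å, O 1.40 Å,
S 1.85 Å, P 1.80 Å. Hydrogens carry a nominal 1.0 Å but are excluded
from surface computations — the heavy-atom group radii subsume them.
A per-element fallback (with warning) covers non-standard residues. The
set name is echoed in every report so results are traceable to their
parameterization. The exact historical radius tables used by legacy
surface programs vary; this one is pinned and printed, which is what
reproducibility actually requires.

## Polar hydrogens

Idealized placement on donor heavy atoms: N–H 1.01 Å, O–H 0.96 Å.
Ring/backbone N–H along the in-plane bisector of the two heavy
neighbours; sp² amino groups (Arg NH1/2, Asn/Gln amides, base N2/N4/N6)
in the plane of the parent's substituents at ±120°; hydroxyls and the
Lys ammonium staggered anti to the grandparent atom. Existing hydrogens
are preserved (idempotent). Donors/acceptors follow standard
protein/DNA chemistry; His is modelled as the neutral tautomer with both
ring nitrogens listed as donor and acceptor, and Arg NE additionally as
an acceptor (neutral-Arg tautomer), which appears in published
protein–DNA contact lists.

## B-form DNA construction

Residue *k* of a strand is one packaged nucleotide template transformed
by *k*·(36.0° about z) + *k*·(3.38 Å along z) — the canonical B-DNA
fiber values, exposed as `HelixParameters`. The templates share a single
sugar–phosphate backbone; local bond geometry comes from the chemical
component dictionary's ideal coordinates, and the rigid pose plus a few
internal torsions (glycosidic χ per base, three backbone torsions) were
fitted once, offline, subject to: O3′(k)–P(k+1) = 1.60 Å under the
helical operator, Watson–Crick pairing (N1–N3 ≈ 2.85/2.87 Å) generated
by a 180° dyad about x, bases roughly perpendicular to the axis and
pointing inward (C1′ radius 5.6 Å < P radius 7.6 Å), and no non-bonded
heavy-atom pair of stacked or paired residues closer than 1.9 Å. These
are convention-grade fiber-style templates — adequate for contact and
surface analysis, not refined experimental geometry; sugar pucker and
sequence-dependent step parameters are not modelled. The 5′ residue is
built without a phosphate (5′-OH), so an *n*-mer carries *n − 1*
phosphates. ODN 1826 is modelled with a natural phosphodiester backbone;
the synthetic reagent is commonly a phosphorothioate, but no sulfur
substitution is introduced. Duplexes place the complement of residue
*k* through the dyad then the same helical operator, yielding an
antiparallel chain emitted 5′→3′.

## SASA

`lr_sasa` implements Lee & Richards z-slicing: per atom, the expanded
sphere (r + probe) is cut into slabs (default 0.1 Å); in each slab the
exposed arc of the atom's circle is found by exact interval union
(half-open arcs, wrap-around split at the origin, tangent circles cover
nothing), and by the hat-box theorem the slab contributes
exposed-fraction × 2πR × dz. Neighbour search uses a k-d tree; an
all-pairs mode exists and is tested to give identical results. The 0.1 Å
default is justified by a convergence test (halving the spacing moves
totals by < 0.2%). `sampled_sasa` is an independent estimator: a
Fibonacci point lattice on each expanded sphere, rotated by a seeded
random rotation, with points kept if outside all neighbouring expanded
spheres. The two routes agree within 2% on the test fixtures; single
atoms match 4π(r+p)² essentially exactly, and two intersecting spheres
match the closed-form spherical-cap area to 0.5%.

## Interface analysis

Interface area follows the component-subtraction convention
ASA(A) + ASA(B) − ASA(AB), counting both buried faces; per-residue
burial is the residue's isolated-component area minus its in-complex
area, floored at zero below 1e-6 to suppress numerical noise. Interface
residues are those burying more than a threshold, default 0.1 Å² —
"lost accessible surface" in principle means any positive burial, but a
small floor keeps slicing noise out; the threshold is echoed in every
output. Side contributions sum exactly to the interface area, and the
protein share is reported as a percentage to one decimal (840/1790 Å²
→ 46.9%). Composition reports the protein-side burial fractions of
Lys/Arg, His (kept separate so both the strict and the inclusive
positively-charged groupings can be read), Asp/Glu, and the rest.

## Contacts and hydrogen bonds

A hydrophobic contact is a cross-side C–C pair with d < 4.5 Å, strict
inequality; intra-side pairs are never reported. H-bonds are
donor–H⋯acceptor triples with H⋯A ≤ 2.6 Å and D–H⋯A ≥ 80°; geometry is
reported to 2 decimals (Å) and 1 decimal (degrees). The criteria are
deliberately permissive — published complex models list bonds from
1.67–2.48 Å with angles down to 86.1°, and both cutoffs are
configuration. Donor side is the chain kind of the donor heavy atom.
Enumeration uses a k-d tree and is tested for exact set equality against
a brute-force all-pairs census generated independently with the fixture.

Parsers for published interaction-table transcriptions accept two TSV
schemas (see `src/dnaface/data/README.md`); multi-atom cells are kept as
atom-name lists without Cartesian-product expansion, because how such
rows map onto per-pair counts is not defined by the source lists —
distinct-residue aggregation is the unambiguous statistic and is what
the package reports.

## Docking

A Cartesian Katchalski-Katzir correlation replaces spherical-polar
machinery: the receptor grid scores +1 in a surface shell (occupied
cells within `surface_thickness`, default 1.5 Å, of the envelope,
measured by Euclidean distance transform) and `interior_penalty`
(default −15) deeper in; the ligand grid is +1 on all occupied cells.
Electrostatics use simplified unit charges (Arg CZ / Lys NZ +1, Asp CG /
Glu CD −1, DNA phosphate P −1); the receptor charge is smeared as a
capped Coulomb potential (cap 2 Å, range 8 Å) and correlated against
ligand point charges, weighted 0.5 and sign-flipped so opposite charges
score positively. For each rotation of a deterministic ZYZ Euler grid
(default step 15°), the translational search is an FFT cross-correlation
over the full lattice; FFT equality with the naive sum is an explicit
test oracle. Poses are deduplicated at 2 Å / 10° and ranked by total
score. Grid spacing defaults to 0.6 Å and the translation extent to
40 Å, mirroring the grid-dimension and distance-range settings of the
published spherical-polar protocol; scoring grids use float32, whose
rounding is negligible against grid discretization. Scores are
grid-dependent overlap-cell counts, not energies: only rankings at fixed
parameters are meaningful, and joint rotation of both molecules changes
top scores by a few percent (grid-discretization noise, damped by a
thicker shell).

## Synthetic data

The toy complex poses an ideal α-helical peptide (φ = −57°, ψ = −47°,
ideal bond geometry, side chains grafted from chemical-component ideal
coordinates on the local N/CA/C frame, polar hydrogens added) against a
built ssDNA, axis-parallel, slid in along +x by bisection until the
closest heavy-atom cross distance equals the requested approach
(default peptide SYVRKNAQVRKY mixes the donor/acceptor-rich residue
types seen at protein–DNA interfaces; default ODN TCCATGACGTT).
Its contact manifest is computed by brute-force double loops at
generation time, independent of the k-d-tree detection code it tests.
The generator is deterministic per seed (byte-identical PDB output).
What it does not emulate: real side-chain rotamer diversity, backbone
flexibility, water-mediated contacts, or the leucine-rich-repeat
geometry of an actual receptor — so passing tests certify the geometry
engine, not biological realism of any particular complex.

The pocket fixture is a 9 Å pseudo-atom ball (1.0 Å lattice, carbon
radii) with a spherical pocket carved around a seed-dependent direction
(wall gap 1.8 Å, verified at generation), plus a complementary ball
half-buried at the recorded embedding translation. Shape correlation
genuinely peaks at the embedding: identity-rotation scans recover it
within one 0.6 Å grid spacing across seeds, and it ranks first under
full 15° rotational sampling.

## Problem sizes and determinism

Tests run fixtures of tens to a few thousand pseudo-atoms; the full
rotational docking check samples ~6 400 rotations on a ~56³ grid
(about 1.5 minutes), chosen as the smallest sizes at which the
properties are non-trivial. All randomness is seeded; reruns are
bit-reproducible on a fixed software stack.

## Known limitations

- Counts of published hydrophobic-contact totals (e.g. per-pair tallies
  of multi-atom rows) are not reconstructable from the printed lists;
  only distinct-residue statistics are reported from fixtures.
- The SASA engine handles group radii only; per-atom force-field radii
  sets can be added as `RadiusSet` instances.
- Docking treats both molecules as rigid and scores are not comparable
  across grid parameters.
- DNA templates are fiber-style idealizations; no sequence-dependent
  geometry, no sugar-pucker refinement, no energy minimization.
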