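# Methods

This note records the models behind each computation, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the places where a genuinely open design choice was settled.

## Coordinate model and structure reading

Structures are parsed with gemmi into a plain chain → residue → atom
hierarchy. Only the first model of multi-model files is used. Alternate
locations are resolved to the highest-occupancy conformer, ties broken by
alphabetical alt-loc id — deterministic and standard practice. Hydrogens
are dropped on read: the crystal structures this package targets are X-ray
entries without hydrogens, and every cutoff below is defined on heavy
atoms. Waters and non-polymer hetero groups (SAM/SAH cofactors, ions) stay
in the model but are flagged and excluded from all area, volume and
contact computations.

Biological assemblies are built from the deposited transforms (REMARK 350
or the mmCIF assembly categories), x′ = R·x + t with R required to be a
proper orthonormal rotation (|det R − 1| < 1e-6). When a file deposits
several assemblies, the first tetramer-producing one is preferred,
otherwise the first; an explicit transform list can always be passed to
`build_assembly` to override. Crystallographic symmetry expansion from
space-group operators is deliberately out of scope — only deposited
assembly instructions are trusted.

## Superposition and correspondence

RMSD between chains uses the Kabsch least-squares superposition (SVD of
the cross-covariance with the usual determinant correction, so reflections
are never returned; collinear point sets are rejected). Correspondence
between chains is built automatically: if the two chains carry the same
residue type at every shared author seq-id, residues are matched by
number, restricted to residues resolved in both — the deterministic
reading of "equivalent Cα atoms" when constructs are identical but
different residues are disordered. Otherwise a global sequence alignment
is used (match +1, mismatch 0, affine gaps: −5 to open, −1 to extend,
terminal gaps penalised; Biopython's PairwiseAligner provides the DP). The
alignment score is verified optimal against exhaustive enumeration for
short sequences in the test suite.

Fixed-radius neighbor search is exact: a k-d tree provides candidates, and
every returned pair satisfies the strict inequality d < cutoff. When the
query and target are the same point set the search is unordered with
self-pairs removed.

## Surface areas

Shrake–Rupley: each atom's sphere (van der Waals radius + probe) is
sampled at n deterministic points from a golden-section spiral; a point is
buried if it falls inside any neighbor's inflated sphere; the atom's
accessible area is the exposed fraction times 4π(r+p)². Defaults: probe
1.4 Å (water), 960 points per atom. At 960 points the discretisation error
on protein-sized atoms is below 1% (checked against a 10,000-point run and
against biotite's independent implementation in the tests). Radii are
element-based Bondi values — C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.20, default 1.70 Å — because the radius table of the original surface
program is not published; element-based radii are reproducible and
configurable.

Buried surface area of two disjoint groups is BSA = ASA(A) + ASA(B) −
ASA(A∪B) (non-negative by construction with a shared point set), and the
"interface area" is BSA/2, the per-side convention used by interface
servers, so a buried area of ~4760 Å² corresponds to an interface of
~2380 Å².

## Grid volumes, contraction deltas and cavities

The molecular volume counts lattice cells whose centers lie within
(radius + probe) of any atom, at 1 Å spacing and 0 Å probe by default. The
lattice is anchored at absolute multiples of the spacing, so translating a
body by lattice vectors changes nothing and disjoint unions are exactly
additive — which is what makes the contraction deltas meaningful:
Δ2 = b − 2a and Δ4 = c − 4a are exact arithmetic on the monomer (*a*,
mean over the assembly's chains, which differ by well under 1 Å RMSD),
tight-dimer (*b*) and tetramer (*c*) volumes. The magnitudes of these
deltas on ~10⁵ Å³ bodies (tens to hundreds of Å³) sit below what different
grid implementations reproduce; the sign — densification or not — is the
robust claim, and the only one the package asserts on real data.

Cavity detection marks cells within (radius + 1.4 Å probe) of any atom as
solid, flood-fills the empty cells from the bounding-box boundary, and
reports the remaining empty connected components. Connectivity is
6-neighbor — conservative, never merging cavities through diagonal leaks.
Components smaller than 3 cells are discarded as grid noise. The exact
cavity definition of the original program (probe-occupiable vs
center-accessible) is not published; this package documents and tests its
own definition, and the hollow-shell fixtures confirm convergence of the
cavity volume to the probe-eroded interior as the grid is refined.

The surface/volume ratio reported per entry uses the tetramer SASA over
the tetramer grid volume; the basis is recorded with the report because
the convention is otherwise ambiguous.

## Contact inventories

All cutoffs are strict upper bounds on heavy-atom distances; with no
hydrogens in the data there are no angular criteria, and His counts as
basic regardless of protonation.

* Disulfides: Cys SG–SG < 2.5 Å.
* Salt bridges: acidic (Asp OD1/OD2, Glu OE1/OE2, any OXT) vs basic
  (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2, N-terminal backbone N) < 3.5 Å,
  counted once per residue pair; ≥ 2 simultaneous atom pairs set the
  bidentate flag. Residue-pair counting matches the way bidentate ionic
  interactions are described in the comparative literature; it is an
  interpretation, and the TSV export lists the underlying atom pairs so a
  different convention can be audited.
* Hydrogen bonds: N/O/S heavy-atom pairs < 3.5 Å between distinct
  residues, counted per atom pair (the per-monomer totals of ~200 only
  make sense on atom pairs). Pairs already claimed as salt bridges or
  disulfides are excluded, as is the covalent peptide neighborhood:
  residues consecutive both positionally and in author numbering
  contribute no backbone C–N or O(i)···N(i+1) "bonds" — the latter sits
  near 2.25 Å in every polypeptide and is bookkeeping, not an interaction.
* van der Waals contacts: apolar (C, S) atom pairs < 4.0 Å between
  non-adjacent residues, counted per residue pair, using only atoms not
  already assigned to a specific interaction. The original analysis was
  done "graphically"; a fixed documented rule replaces visual inspection,
  so absolute vdW counts are convention-dependent and best compared within
  a single convention.

Precedence is disulfide > salt bridge > H-bond > vdW; an atom pair
contributes to at most one kind (property-tested).

## Interfaces and the hydrophobic P-value

Interfacing residues are those losing more than 0.1 Å² of accessible area
upon complexation — the threshold filters sampling noise at 960 points and
is configurable. In a four-chain assembly, the two largest disjoint
interfaces are labeled tight dimers, remaining pairs above a 10 Å²
negligibility floor are tetramer interfaces; labels follow geometry, not
chain ids. The assembly-level buried area is Σ chain ASA − assembly ASA.

The hydrophobic P-value asks whether the interface is more apolar than a
random patch of the same size. Observed statistic: the fraction of the
buried area contributed by C and S atoms. Null: patches grown from a
uniformly chosen exposed seed atom by nearest-neighbor accretion (atoms
ranked by distance from the seed on the seed's own isolated chain) until
the patch's accessible area reaches that chain's one-side buried area;
P = Pr(patch apolar fraction ≥ observed), ties counting as ≥, so a
uniformly apolar surface gives exactly 1. The estimator is seeded and
reproducible; 2000 samples by default. This is a re-interpretation of the
published interface statistic, whose exact configuration is not public:
absolute values are not comparable across implementations, but the
calibration (uniform under its own null) and the qualitative ordering of
interfaces are, and both are tested.

## Synthetic ground truth

The generators produce geometry the detectors can be scored against, not
protein chemistry:

* Sphere bodies use carbon pseudo-atoms. The solid cluster's 1.5 Å lattice
  pitch keeps every interior point within one carbon vdW radius of an
  atom, so zero cavities is guaranteed; the hollow shell's inner atom
  surface sits exactly at the requested interior radius, its layers are
  dense enough that a 1.4 Å probe cannot leak, and shells thinner than two
  probe radii are rejected.
* The ideal helix is built from textbook internal coordinates (φ = −57°,
  ψ = −47°, ω = 180°, standard backbone bonds/angles) by NeRF chaining;
  the resulting O(i)···N(i+4) distance is 3.09 Å, giving the canonical
  11-rung ladder on 15 residues.
* Planted complexes place each requested interaction at its own station
  along the interface with functional-atom distances mid-interval below
  the cutoffs (3.0 / 2.9 / 2.05 / 3.8 Å) and anchor atoms pulled back so
  no unplanned cross-chain pair enters any cutoff; recovery is exact by
  construction and tested across 50 seeds. The optional apolar filler
  channel adds pure vdW contact pairs without touching the specific
  counts.
* The patchy dimer plants an all-apolar contact cap on spheres of mixed
  50/50 polar/apolar composition; the cap is narrow and deeply buried so
  an equal-area random patch rarely fits inside it, making the planted
  interface genuinely anomalous under the patch null.

What these fixtures do **not** emulate: real side-chain rotamers, packing
densities, missing atoms/disorder, or the residue-type correlations of
actual interfaces. Passing the synthetic suites therefore demonstrates the
correctness of the computations and detectors, not the biological
calibration of any threshold; the deposited-entry checks exist precisely
to anchor the pipeline to real crystal structures and require those
coordinate files locally.

## Numerical and degenerate-input choices

* All distance cutoffs strict (<); boundary distances excluded.
* Superposition requires ≥ 3 non-collinear points; correspondence with
  fewer than 3 matched atoms is an error.
* Grid computations require positive spacing; empty atom lists are errors
  for volumes/surfaces and yield an empty cavity list.
* Cavities are sorted by volume (descending), ties broken by centroid.
* Alignment tie-breaks follow the DP engine's deterministic first
  traceback; scores are provably optimal, pairings on tied optima may
  differ between engines.
* Reports serialise with sorted keys; identical inputs and configuration
  give byte-identical JSON.

## Problem sizes used in the demonstration script

`scripts/acceptance.py` runs single-atom closed-form references, a
~1,500-atom hollow shell and ~600-atom solid cluster at 1 Å spacing
(0.25 Å refinement is exercised in the test suite), 20 planted complexes,
a 200-residue noisy superposition, the 448-atom toy tetramer through the
full comparative pipeline at 960 surface points, and the 2,000-atom patchy
dimer at 240 surface points with 2,000 null patches — sizes chosen so the
whole script completes in well under a minute on one core while every
quantity is computed, not asserted.

## Known limitations

* Interface P-values and vdW counts are convention-bound (see above);
  compare them within this package's definitions only.
* Contraction deltas on real structures inherit missing side-chain atoms
  from the deposited coordinates; entries with unmodelled interface
  residues shift by a few tens of Å³.
* No crystallographic symmetry expansion beyond deposited assembly
  transforms; entries whose biological unit is not deposited need explicit
  transforms.
* Sequence-based correspondence assumes a single global alignment;
  domain-swapped or circularly permuted homologs would need an external
  correspondence.
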