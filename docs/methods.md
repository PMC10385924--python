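# Methods

## Scope and data model

`lmp3d` computes conformation-dependent 3D molecular descriptors from the
two files a LAMMPS simulation of a non-reactive force field produces: the
input data file (atom style `full`: id, molecule id, type, charge, x, y, z,
optional image flags) and a text dump trajectory with per-frame box bounds.
"Real" units are assumed throughout (g/mol, Å, e); density is the only
absolute system property reported, in g/cm³ via the factor
1.66054 = 10²⁴/N_A.

Parsing is header-driven on both sides: data-file sections (Masses, Atoms,
Bonds, Angles, Dihedrals, Impropers, Coeff sections) are located by name in
any order, and dump columns are bound by the names on the `ITEM: ATOMS`
line, never by position. Angles/Dihedrals are read when present but not
required — only bonds enter any descriptor here. Scaled dump coordinates
(`xs`-style) are rejected rather than silently converted, as are dumps
mixing `x` and `xu` columns. Only orthogonal boxes are supported for
wrapped input; unwrapped input works for any box.

## Element and property assignment

Elements are inferred from the Masses section: the nearest entry within
0.5 g/mol across the built-in table wins. The table holds H, C, N, O, F, P,
S, Cl, Br, I plus the united-atom carbons CH, CH₂, CH₃, CH₄
(13.019–16.043 g/mol), which take carbon's radius, volume and electronic
properties but keep their own mass. Nearest-match (rather than
elements-first) is required because the UA masses CH₂ (14.027) and CH₄
(16.043) lie within 0.5 g/mol of N and O; the closest entry is always the
intended one for both AA and UA force fields. A mass matching nothing is a
hard error — descriptor values from a misassigned element would be silently
wrong.

Property values are fixed constants: Bondi van der Waals radii
(volume = 4/3·πr³), Pauling electronegativities, static dipole
polarizabilities (Å³), NIST first ionization potentials and electron
affinities (eV). Descriptor weightings use these scaled relative to carbon
(w = p/p_C, so any carbon atom weighs 1); partial charge is used raw in e
since it has no carbon reference. The full table can be rendered with
`lmp3d.properties.property_table_csv()`.

## Unwrapping

Wrapped coordinates are unwrapped per molecule by breadth-first traversal
of the bond graph from the lowest atom id. Each newly reached atom is
assigned an integer image vector so that its displacement from the
already-placed neighbour is the minimum image (each component in
[−L/2, L/2]); its unwrapped position is the wrapped position plus image ×
box length — one exact multiply-add per atom, no accumulation of rounding.
A bond whose minimum-image length still exceeds half the shortest box side
makes unwrapping ambiguous and raises an error instead of guessing, since a
silent misplacement would corrupt every descriptor downstream. Unwrapped
input passes through untouched.

Before descriptors are computed, each molecule snapshot is re-anchored so
its first atom sits at the origin. All descriptors are
translation-invariant, so this changes nothing mathematically; it makes the
computed values bitwise independent of whole-box lattice translations,
which is what lets wrapped and unwrapped variants of the same trajectory
produce byte-identical CSVs.

## Descriptor definitions and numerical choices

**Set 1 (22).** Classic topological indices evaluated on the geometric
distance matrix: W3D = Σ_{i<j} r_ij, H3D = Σ 1/r_ij, average geometric
distance, eccentricity radius/diameter/mean and the Petitjean index, a
Balaban-type J3D = B/(C+1)·Σ_bonds (S_i S_j)^{−1/2} with S the distance-row
sums and C the cyclomatic number, and Randić-type χ⁰/χ¹/χ² over graph
degrees, each scaled by the mean bond length to carry geometric units. The
same eleven are repeated on the hydrogen-suppressed graph (`_hs` suffix);
molecules without hydrogens repeat their plain values, and a molecule that
is all hydrogen reports zeros. Degenerate cases: one atom gives an all-zero
block; coincident-atom radius 0 defines Petitjean = 0.

**Set 2 (37).** Dipole magnitude about the mass-weighted centre (the value
is origin-dependent for net-charged species; the mass centre makes it
well defined), converted at 4.8032 D per e·Å. Inertia eigenvalues sorted
ascending with ratio and shape-factor combinations; gyration-tensor shape
measures (R_g, asphericity b = λc − (λa+λb)/2, acylindricity c = λb − λa,
relative shape anisotropy κ² = (b² + ¾c²)/R_g⁴). Gravitation indices
Σ m_i m_j/r_ij² over all and over bonded pairs. Molecular volume as the
union of vdW spheres on a 0.2 Å voxel grid (a voxel counts when its centre
is inside any sphere); shadow areas on 0.1 Å 2D grids after rotation into
the gyration principal frame, normalised variants dividing by the tight
enclosing rectangle of the projected disks. Plane-of-best-fit score = mean
|distance| to the least-squares plane (smallest right singular vector),
0 for N < 3. Chain measures follow the backbone — one shortest path
realising the graph diameter, ties broken by the lexicographically smallest
atom-id sequence: end-to-end distance R_ee, contour length L, Kuhn length
l_k = R_ee²/L, and folding profiles φ_k = mean over windows of
(direct distance)/(path length) for k = 1..10 (0 when the backbone is
shorter than k). Grid spacings are declared constants; grid-based values
are reproducible exactly and rotation-invariant to within ~2 %.

**Set 3 (311).** The molecular influence matrix H = M(MᵀM)⁺Mᵀ of the
centred coordinates M uses the Moore–Penrose pseudo-inverse so planar and
linear molecules (rank < 3) are handled; its diagonal h_i are the
leverages. Scalars: ITH/ISH from leverage-equality classes (tolerance
1e-6), HIC as Shannon entropy of normalised leverages, HGM = 100 ×
geometric mean of positive leverages, and RARS/RCON/REIG from the
influence/distance matrix R_ij = √(h_i h_j)/r_ij. Vectors over topological
lags 0..8 (H, HATS) and 1..8 (R, Rmax) under 8 weighting schemes (unit +
7 carbon-scaled properties): H_k keeps only positive H_ij terms per the
original definition; HATS_k and R_k use all pairs at the lag; Rmax_k is the
largest single term; totals sum over lags. Molecules with topological
diameter < 8 report exact zeros at the unreachable lags.

**Set 4 (30).** SASA by a deterministic Shrake–Rupley variant: 960
golden-spiral points per atom on the probe-expanded sphere (probe 1.4 Å,
both configurable), a point accessible unless strictly inside another
expanded sphere (with a 1e-12 relative epsilon so points exactly on a
boundary stay accessible — two coincident atoms each keep their full
area). The 30 CPSA descriptors follow the Stanton–Jurs partial-sum pattern;
"polar" atoms are those with |q| ≥ 0.2 e, a charge-based generalisation
that works for arbitrary force-field typing where heteroatom rules do not
apply. Empty charge classes yield zeros, never division errors.

**Set 5 (112).** Weighted covariance of the coordinates per scheme;
eigenvalues λ1 ≥ λ2 ≥ λ3 give directional size, θ_m = λ_m/T shape,
ε_m = λ_m²N/Σt⁴ inverse kurtosis of the scores, and γ_m symmetry — the
fraction of atoms with a mirror counterpart of the same element across the
score plane (counterpart window 0.5 Å, self-window 0.25 Å). Global T, A, V,
K (acentricity, 1 for a line, 0 for a sphere), G. Seven schemes (unit,
mass, |charge|, vdW volume, electronegativity, polarizability, ionization
potential) give 16×7 = 112; electron affinity is excluded here (it remains
in the autocorrelations) as the minimal scheme set consistent with that
count. A molecule with all-zero charges falls back to unit weights for the
charge scheme; a zero-sum non-charge scheme is an error. Eigenvector signs
are fixed by making each vector's largest-magnitude component positive, so
score-dependent values are deterministic under eigen-solver sign ambiguity.

**Set 6 (1110).** RDF sampled at r = 0.5..15 Å in 0.5 Å steps with
β = 100 Å⁻²; MoRSE at s = 0..29 Å⁻¹ with sinc(0) = 1; Moreau-Broto, Moran
and Geary autocorrelations over 1 Å bins [k, k+1), k = 0..29. RDF/MoRSE use
pair weights under the 8 schemes (240 each); autocorrelations use the 7
properties only (210 each), with Moran/Geary defined 0 when a bin is empty
or the property variance is zero. These grids are the established
conventions for the families and are what fixes the family sizes at
240/240/210/210/210.

## Engine and determinism

Work is partitioned into (molecule, frame) units. Results are assembled in
a fixed (frame, molecule-id) order independent of scheduling, numbers are
written as shortest-round-trip decimal reprs, and files are written to a
temp name then atomically renamed — so repeated runs and any worker count
give byte-identical `molecule_<molID>.csv` files. A `manifest.json` records
input SHA-256 hashes, configuration, and a hash of the descriptor
catalogue. Density is written per frame because box volume varies over an
NPT trajectory. Frame selection (e.g. using only the equilibrated second
half of a run) is left to the user; a `stride` option subsamples frames.

## Synthetic fixtures

The fixture generator emulates the file structure of real LAMMPS output
with exactly known ground truth: methane, ideal zig-zag alkanes,
planar rings and seeded freely jointed random-walk chains (fixed bond
length, uniform directions, self-overlap allowed — descriptors do not
require physical validity), replicated into a periodic box with seeded
rigid motion per frame, optional wrapping, and neutral / alternating ±q /
per-atom charge patterns covering the CPSA edge cases. Stored coordinates
are snapped to a 2⁻²⁰ Å (≈1e-6 Å) grid so that a coordinate and any
whole-box translation of it are both exactly representable in double
precision; this is what makes the wrapped/unwrapped byte-identity contract
exactly testable. What these fixtures do *not* emulate: force-field
energetics, equilibrated conformer ensembles, excluded volume, or realistic
charge distributions — passing tests demonstrate correctness of the
descriptor mathematics and the I/O/unwrapping pipeline, not chemical
realism of the inputs.

## Problem sizes

The test suite and the acceptance script run on 2–25-atom molecules, 1–3
molecules per box, and 1–5 frames, with 960–1920 SASA points — sizes at
which every descriptor can be cross-checked against explicit-loop oracles
and analytic closed forms. The engine itself is size-agnostic; cost grows
as O(N²) per molecule for the pair families and O(N²·points) for SASA.

## Known limitations

- Triclinic boxes are rejected for wrapped input (unwrapped input works).
- Reactive force fields (no Bonds section, time-varying connectivity) are
  out of scope.
- Implicit-hydrogen reconstruction for united-atom models is not
  attempted; hydrogen handling is limited to the hydrogen-suppressed
  variants of set 1.
- The set-1 and GETAWAY enumerations are this package's declared catalogues
  (22 and 311 columns); other implementations of the same families may
  enumerate more or fewer variants.
- Binary dump files are not read; text dumps only.
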