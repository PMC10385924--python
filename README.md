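# lmp3d

3D molecular descriptors computed directly from LAMMPS simulations, for
QSPR feature construction.

Most descriptor packages take a single static structure (a SMILES string or
an SDF file) and return one feature vector. Molecular-dynamics trajectories
instead carry many molecules across many time frames, and their
conformation-dependent 3D descriptors are exactly what is needed to model
condensed-phase properties such as density and viscosity of hydrocarbons.
`lmp3d` closes that gap: it reads a LAMMPS input data file (atom style
`full`) and a text dump trajectory, reconstructs each molecule's unwrapped
geometry frame by frame, and writes one descriptor table per molecule.

## What it computes

For every molecule at every frame, six descriptor families:

| Set | Family | Columns |
|-----|--------|---------|
| 1 | 3D topology / connectivity (3D Wiener `W3D`, Harary `H3D`, Balaban-type `J3D`, eccentricity family, χ⁰–χ² with a geometric scale, plus hydrogen-suppressed variants) | 22 |
| 2 | Geometric shape/size: dipole μ, inertia `I1..I3`, gyration (R_g, asphericity, acylindricity, κ²), gravitation indices, grid vdW volume, shadow indices `S1..S6`, plane-of-best-fit score, chain measures (R_ee, L_contour, Kuhn length l_k, folding profiles φ₁..φ₁₀) | 37 |
| 3 | GETAWAY, from the molecular influence matrix H = M(MᵀM)⁺Mᵀ: ITH, ISH, HIC, HGM, RARS, RCON, REIG and lag-0..8 H/HATS/R/Rmax vectors under 8 atomic weightings | 311 |
| 4 | CPSA (charged partial surface area) over a deterministic Shrake–Rupley solvent-accessible surface: PPSA/PNSA/DPSA/FPSA/WPSA families, charge ratios, polar-surface terms | 30 |
| 5 | WHIM: eigenvalue/score statistics of weighted coordinate covariances (size λ, shape θ, symmetry γ, density ε; global T, A, V, K, G) under 7 weightings | 112 |
| 6 | 3D-RDF (Gaussian-smoothed, Σ wᵢwⱼ e^{−β(r−r_ij)²}), 3D-MoRSE (Σ wᵢwⱼ sin(s·r)/(s·r)), and Moreau-Broto / Moran / Geary 3D autocorrelations over 1 Å lag bins | 240 + 240 + 3×210 |

plus the system density ρ = M_total · 1.66054 / V_box (g/cm³) in every row.

Atomic weights come from a fixed property table (Bondi radii, Pauling
electronegativities, polarizabilities, ionization potentials, electron
affinities), scaled relative to carbon; partial charges are taken raw from
the data file. Elements are inferred from the Masses section, including
united-atom CH/CH₂/CH₃/CH₄ pseudo-atoms, so both all-atom and united-atom
force fields work.

## Worked example

```sh
python examples/02_single_molecule_descriptors.py
```

builds a 16-carbon random-walk chain in a periodic 25 Å box, wraps it,
re-unwraps it and prints:

```
HGM       = 16.8057   (higher -> more even atom influence)
lk        = 0.7775 A (Kuhn length: Ree^2 / contour length)
molvolume = 127.19 A^3 (union of vdW spheres)
phi4      = 0.3424   (4-bond backbone straightness, 1 = straight)
Rg        = 1.9795 A
```

`HGM` is 100× the geometric mean of the influence-matrix leverages — a
compact measure of how evenly atoms determine the molecular geometry. The
Kuhn length and φ₄ quantify chain stiffness and local folding: a perfectly
straight chain has φ₄ = 1, this coiled random walk only 0.34. These four
quantities are the kind of conformation-sensitive features that static,
SMILES-derived descriptors cannot provide.

For a full run (one CSV per molecule):

```sh
lmp3d compute --data box.data --traj box.lammpstrj --sets 4,5 --workers 4 --out results/
```

writes `molecule_<molID>.csv` (header + one row per frame) for every
molecule id in the trajectory, and a `manifest.json` with input hashes and
the configuration. Output bytes are identical for any worker count.
Synthetic test inputs can be produced with `lmp3d fixture`.

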