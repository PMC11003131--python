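# cgstack

Coarse-grained (CG) force-field parametrization by bonded-distribution
matching, a minimal Langevin engine to close the refinement loop, and
structural analyses of stacked planar-molecule aggregates.

Planar photosensitizers like protoporphyrin IX (PpIX) stack face-to-face
into rod-like, near-crystalline aggregates in which neighbouring molecules
are rotated by quarter turns (90 or 270 degrees — never 0 or 180).
Amphiphilic additives can adsorb on the aggregate surface, form a
co-existing cluster, or intercalate between the stacked planes and split
the aggregate into small pieces.  `cgstack` is for modellers who want to
(a) parametrize CG models of such molecules from atomistic trajectories
and (b) quantify stacking order, cluster shape and additive placement in
multi-molecule configurations — all testable end to end against synthetic
data with known ground truth.

## The model

For a bonded coordinate x (bond length in nm, angle in degrees) whose
equilibrium marginal is Gaussian, Boltzmann inversion gives a harmonic
potential of mean force

    U(x) = 1/2 k (x - x0)^2,   x0 = <x>,   k = kB T / Var(x),

with kB = 0.0083144621 kJ mol^-1 K^-1 and T defaulting to 310.15 K.
Because the CG model's own thermodynamics shift its sampled marginals,
the parameters are refined iteratively: simulate the CG molecule (BAOAB
Langevin dynamics; velocity Verlet when friction is 0), measure its
bond/angle marginals, compare to the atomistic targets with a base-2
Jensen-Shannon divergence, and apply a damped moment-matching update
until every term agrees within a stated threshold (default JSD 0.02).

Aggregates are analysed with single-linkage contact clustering, gyration-
tensor shape metrics (asphericity; relative shape anisotropy kappa^2 = 1
for a rod, 0 for a sphere), per-molecule plane normals with neighbour
rotation angles about the stack axis, and a four-way additive placement
classifier (intercalated / surface / co-cluster / free).  Conventions and
defaults are documented in `docs/methods.md`; file formats in
`docs/formats.md`.

## Worked example

Build a four-molecule stack with the quarter-turn rotation pattern and
analyse it:

```sh
$ cgstack synth stack --n 4 --spacing 0.4 --rotations 90,270,90 --seed 1 -o scene.pdb
$ cgstack stacks scene.pdb
pair 0-1: separation=0.400 nm angle=90.0 deg bin=90 permitted=True
pair 1-2: separation=0.400 nm angle=270.0 deg bin=270 permitted=True
pair 2-3: separation=0.400 nm angle=90.0 deg bin=90 permitted=True
```

Each line is one stacked neighbour pair: the inter-plane separation
recovers the constructed 0.4 nm spacing, the rotation angle the
constructed sequence, and all pairs are flagged permitted because quarter
turns are the allowed crystalline arrangement (a 0 or 180 rotation would
report `permitted=False`).

Fit harmonic parameters from a trajectory whose bond marginal is Gaussian
(mean 0.47 nm, sigma 0.02 nm):

```sh
$ cat scheme.yaml
molecule: TOY
atoms: [C1, C2]
beads:
  - name: B1
    atoms: [C1]
  - name: B2
    atoms: [C2]
bonds:
  - [B1, B2]
$ cgstack synth bonded --bond 0-1:0.47:0.02 --n-frames 20000 --seed 3 -o traj.xyz
$ cgstack fit --traj traj.xyz --mapping scheme.yaml --temp 310.15 -o params.itp
bond (0, 1): r0=0.4701 nm k=6412.7 kJ/mol/nm^2
```

The closed form is k = kB T / sigma^2 = 6446.8 kJ mol^-1 nm^-2; the fit
lands within the sampling error of 20 000 frames (~1%).  The exported
`params.itp` contains the GROMACS-style line `1 2 1 0.470 6412.7`.

The full loop — map an atomistic trajectory, invert, resimulate, refine —
is `cgstack refine --traj target.xyz --mapping scheme.yaml -o final.itp`;
see `cgstack <subcommand> --help` for every stage (`map`, `stats`, `fit`,
`simulate`, `refine`, `clusters`, `stacks`, `synth`).  Every run prints a
`# key=value` header with all effective parameters and seeds, so results
are reproducible from the log alone.

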