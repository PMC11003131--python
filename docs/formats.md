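# File formats and schemas

All coordinates are nanometres internally.  PDB and XYZ files store
Angstrom (converted on read/write); GRO stores nanometres natively.  Only
orthorhombic boxes are supported — triclinic input raises an
unsupported-feature error.

## Mapping-scheme configuration (YAML)

Declares the atoms of one molecule, the bead memberships, and the CG
bonded terms.  Field names are fixed; unknown keys are rejected.  The only
silent default is `weighting: mass`.

```yaml
molecule: C14E          # label (free text)
atoms: [C1, C2, C3, N1, N2, N3]   # ordered atom names of the molecule
beads:
  - name: B1            # required, unique
    type: P1            # optional nonbonded type; defaults to the name
    atoms: [C1, C2, C3] # required, names from `atoms`
    weighting: mass     # optional: mass | geometric
  - name: B2
    atoms: [N1, N2, N3]
bonds:                  # optional list of bead-name pairs
  - [B1, B2]
angles: []              # optional list of bead-name triples
```

Errors name the offending object: a bead referencing an unknown atom, a
duplicate bead name, or a bond/angle term using an undefined bead.

## Structured force-field serialization (JSON, lossless)

`export_parameters(ff, topology, "structured")` emits, and
`import_parameters` reads:

```json
{
  "format": "cgstack-forcefield",
  "version": 1,
  "cutoff_nm": 1.1,
  "bonds":  [{"beads": [0, 1], "equilibrium_nm": 0.47,
              "force_constant_kj_mol_nm2": 1250.0}],
  "angles": [{"beads": [0, 1, 2], "equilibrium_deg": 120.0,
              "force_constant_kj_mol_rad2": 25.0}],
  "pairs":  [{"types": ["P1", "P2"], "epsilon_kj_mol": 2.0,
              "sigma_nm": 0.43}]
}
```

Bead indices are 0-based.  Floats round-trip exactly (JSON `repr`
precision).

## ITP-like bonded export

`export_parameters(ff, topology, "itp")` writes GROMACS-style sections
with 1-based bead indices:

```
[ bonds ]
;  i   j  funct   b0(nm)   kb(kJ/mol/nm2)
1 2 1 0.470 1250.0
[ angles ]
;  i   j   k  funct  th0(deg)  cth(kJ/mol/rad2)
1 2 3 2 120.00 25.00
```

funct 1 = harmonic bond, funct 2 = harmonic angle; b0 in nm (3 decimals,
the usual ITP precision), th0 in degrees, force constants in
kJ mol^-1 nm^-2 / kJ mol^-1 rad^-2.  This dialect is for interchange and
display; the structured JSON is the lossless serialization.

## Scene PDB conventions

Scenes (multi-molecule snapshots) are written as PDB with one residue per
molecule.  Residue name `STK` marks a stacker; any other residue name
marks an additive, whose species label becomes `additive:<resname>`.  On
read, stacker topologies are annotated with `core_atoms = all atoms` and
`reference_axis = (0, 1)` (the first two atoms), which matches the
orientation convention of the built-in square-planar stacker template.
Scene PDB files carry no box.

## XYZ trajectories

Multi-frame XYZ with the standard `count / comment / atom-lines` blocks;
coordinates in Angstrom with 6 decimals.  The comment line carries
`t=<ps>` and optionally `box=<a>,<b>,<c>` (nm), which the reader parses
back.  Bead names may appear in the element column for CG trajectories;
such files are meant for `read_trajectory` (coordinates only), not
`read_structure` (which needs real elements for masses).
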