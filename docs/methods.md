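# Methods

## Scope and assumptions

`bdascan` treats boronation-site identification as a purely geometric
screening problem layered on externally produced physics: docking
affinities come from a Vina-compatible engine (or the builtin
deterministic stand-in), and fold stability comes from MD trajectories the
user supplies. The package itself never minimizes, samples or scores with
a force field. Its assumptions are therefore structural:

- the input structure's coordinates and author residue numbering are
  authoritative (no renumbering, no rebuilding);
- a vacated side-chain volume is an adequate proxy for "room for a
  boronated side chain" — no repacking of the neighbors is attempted
  after truncation, so the cavities are exactly the crystallographic
  side-chain volumes;
- a fragment probe that re-occupies the cavity with its boron pointing
  the way the native side-chain terminus pointed is evidence that the
  full boronated residue will fit;
- hydrogen placement and partial charges are the responsibility of
  external preparation tools; shipped charge tables are editable
  placeholders for a neutral-pH state.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| interface cutoff | 8.0 | Å | heavy-atom antibody–receptor distance below which a residue is protected from mutation. 8 Å covers first- and most second-shell contacts; overridable by explicit residue lists. |
| `r_cavity` | 5.0 | Å | max distance from pose heavy-atom centroid to the vacated side-chain centroid for a pose to count as "inside" a cavity; ~the radius of an aromatic side-chain envelope. |
| `d_max` | 2.0 | Å | reference-carbon distance (native CZ vs probe C1 for Tyr/Phe) — demands near-superposition of the B-bearing carbon. |
| `theta_max` | 60.0 | deg | directionality angle between CB→CZ (native) and C_para→B (probe); 60° separates "points outward like the native terminus" from sideways/backwards poses. |
| `overlap_factor` | 0.6 | – | clash when interatomic distance < 0.6 × (r_vdW,i + r_vdW,j); 0.6 is a common soft-clash criterion that tolerates contact but not interpenetration. |
| H-bond `d_max` / `angle_min` | 3.0 Å / 135° | | standard geometric donor–acceptor criteria in MD analysis; a heavy-atom-only mode (distance criterion alone) serves H-free trajectories. |
| cluster cutoff | 1.5 | Å | CA-RMSD neighborhood for GROMOS leader clustering; between typical intra-basin (<1 Å) and inter-basin (>3 Å) backbone RMSD at this system size. |
| boron geometry | B–C 1.56, B–O 1.36, O–H 0.96 Å; 120° sp², planar | | standard experimental arylboronic-acid values; every number is a `BoronGeometry` field so users can substitute their own measurements. The boronic acid is assumed neutral trigonal (not anionic tetrahedral). |
| builtin engine | step 2.0 Å, 8 rotations, shells [3.0, 4.5] / <2.5 Å, −1 / +10 | | see below. |

Residue-vector tails: the Tyr/Phe residue vector is CB→CZ by default (CG
selectable via `VectorMapping`); Trp uses CB→CZ2 and His CB→(NE2,CE1
midpoint), in each case approximating the outward direction of the
side-chain terminus that the boron should inherit.

## The builtin docking engine

The builtin engine exists so the full pipeline runs deterministically at
desk scale; it is deliberately *not* a physical scoring function. A rigid
probe is placed at every lattice point (spacing `step`) inside the box
crossed with a fixed rotation set (identity plus Fibonacci-sphere
axis/golden-angle rotations — a pure function of the set size), and each
placement is scored −1 per receptor heavy atom within [3.0, 4.5] Å of a
probe heavy atom and +10 per receptor heavy atom closer than 2.5 Å. Ties
break by enumeration order, making output bitwise reproducible and
checkable against brute-force enumeration (the test suite does exactly
that). Affinities from this engine are contact counts, not kcal/mol;
real affinity screening requires the external-engine adapter.

## Trajectory analytics

- **Superposition** is weighted Kabsch via SVD with the determinant
  correction, so reflections are never returned; degenerate (collinear)
  references are rejected.
- **RMSF** superposes all frames onto the mean structure, recomputes the
  mean, and iterates (twice by default) — the standard fix for the
  mean-structure circularity.
- **Clustering** is GROMOS leader clustering on the pairwise Kabsch-RMSD
  matrix: repeatedly take the frame with the most unassigned neighbors
  within the cutoff (ties → lowest frame index) as a cluster medoid.
  Chosen over k-means/hierarchical because it is deterministic, needs no
  cluster count, and admits an exact brute-force oracle.
- **H-bond conservation** at a site is |WT ∩ mutant partner sets| / |WT
  set| over partners present in ≥10% of frames; an empty WT set gives 1.0
  by convention (nothing to conserve — a mutant that *gains* bonds is not
  penalized).

## Synthetic fixtures: what they do and do not show

The generators build ideal-geometry peptides (standard backbone internal
coordinates at helix −57/−47 or extended −139/135 φ/ψ; template side
chains at χ₁ = 180°), i.i.d. Gaussian coordinate noise, rigid two-state
mixtures, and planted donor–H···acceptor triads (2.8 Å / 170°) among
apolar decoys. They are geometric, not physical: no excluded volume in
the noise, no solvent, no correlated motions, no real rotamer
distributions. Passing tests therefore demonstrate that the *measurement
machinery* is correct (closed-form recoveries: Gaussian σ per coordinate
gives RMSD and RMSF of σ√3; a 70/30 two-state mixture yields a 0.70 top
cluster population; planted H-bond sets are recovered exactly), not that
any particular protein tolerates boronation. Real-antibody conclusions
require real structures and real MD.

Problem sizes in the default test and acceptance runs — peptides of 4–45
residues, 200-frame clustering, 600-frame RMSF, 20-mode grid docking —
were chosen as the smallest sizes at which the closed-form and
ground-truth recoveries are statistically stable.

## Numerical and design choices

- PDB altlocs collapse to the highest-occupancy conformer (ties by
  altloc letter), because the downstream geometry needs one conformer.
- Waters are recognized by resname (HOH/WAT) and ions as monoatomic
  residues; anything else parses generically, so non-standard residues
  such as BPA round-trip untouched.
- Coordinates are written at the PDB format's 0.001 Å precision; all
  round-trip guarantees are stated at that precision.
- Probe torsion trees are derived, not hard-coded: a bond is rotatable
  iff it is non-ring and both sides carry a further heavy atom, which
  yields exactly the C–B torsion for all three probes (hydroxyl torsions
  move only hydrogens and are frozen).
- BPA construction is strictly local: B continues the CZ→OH direction,
  the two oxygens lie in the aromatic-ring plane, and every retained atom
  keeps its coordinates bit-for-bit.
- Mutations within one scan structure are simultaneous per residue type
  (one structure per restype × target, eight in total when all four
  types are present); one-at-a-time scanning is available by passing a
  single-site exclusion complement.
- The interface-exclusion region is distance-defined rather than
  box-defined by default because a distance rule generalizes to any
  antibody–receptor pair; explicit residue lists and boxes are accepted
  as overrides.

## Known limitations

- The builtin engine's contact score has no orientational preference, so
  on small systems its top poses usually fail the directionality filter;
  it validates plumbing and determinism, not binding poses.
- Charge tables are placeholders; quantitative PDBQT charge output is
  only as good as the user-supplied table.
- The frcmod-like export provides bond/angle *stubs* (equilibrium values
  from the configured geometry, generic force constants); it is a
  starting point for parametrization, not validated force-field content.
- Trp and His boronation geometry reuses the Tyr-style vector logic with
  per-type reference atoms; building full boronated Trp/His residues
  (beyond the Tyr-derived BPA) is not implemented.
- mmCIF, protonation, and biological-assembly expansion are out of scope.
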