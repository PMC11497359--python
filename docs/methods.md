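# Methods

## Scope and model

`mdcontact` analyzes existing MD trajectories of a multidomain protein
surrounded by multiple copies of one or more small-molecule species, and
planar single-cell migration tracks. It does not run MD, docking, or image
tracking; those are upstream tools whose outputs it consumes.

The protein is partitioned into named domains given as chain-scoped
inclusive residue-id intervals (1-based author numbering as read from the
PDB residue-id column). Within one chain a residue may belong to at most
one domain; overlapping specifications are rejected with the colliding
residue ids. Insertion codes are not supported and raise an error;
alternate locations are reduced to the highest-occupancy conformer. Atom
masses come from a standard element table; unknown element symbols fall
back to carbon with a warning, which leaves center-of-mass positions
essentially unaffected for the rare cases where it can happen.

## Stability metrics

**RMSD.** For each domain separately, every post-equilibration frame is
superposed onto the reference using only that domain's selected atoms
(Kabsch superposition via SVD, proper rotation enforced; collinear
reference geometries are rejected as degenerate). The reference defaults to
the first post-equilibration frame; an explicit coordinate array may be
given instead, and superposition can be switched off to obtain raw
displacement RMSD. Per-domain (rather than whole-protein) alignment is the
default because domains are judged on their internal stability; a
whole-protein alignment can be had by defining one domain spanning the
protein.

**RMSF.** Two-pass procedure: frames are aligned to a running-mean
structure (two passes), and RMSF of residue *i* is the square root of the
atom-averaged mean squared deviation of its selected atoms from the mean
structure. Alignment can be disabled (`align=False`); that is the correct
analysis for inputs known to carry no global rigid-body motion, because
fitting a rigid transform to pure internal fluctuations absorbs ~6 degrees
of freedom of variance and biases the N-atom isotropic case by a factor
≈ √(1 − 2/N). The closed-form recoveries (harmonic amplitude A → RMSF
A/√2; isotropic Gaussian σ → σ√3) are therefore verified in unaligned
mode, while aligned mode is verified to remove imposed rigid-body drift
exactly.

**Atom selection** defaults to Cα per residue; `backbone`, `heavy` and
`all` are available. Cα is the common convention and matches the magnitude
of typical reported per-domain values.

**Box statistics.** Per-domain RMSF distributions are summarized with
Tukey's hinges (halves include the median for odd n) and whiskers at
1.5×IQR; values outside the fences are reported as outliers with their
residue ids.

**Equilibration.** All statistics discard frames before the equilibration
time (default 3000 ps). The sampling grid and frame mapping use only
post-equilibration frames, so results are identical whether the discarded
segment is present in the input or pre-trimmed — a property tested exactly.

## Contact statistic

The transient contact number C_i(t) counts the copies of a species whose
mass-weighted center of mass lies **strictly** within the cutoff (default
0.7 nm, stored internally as 7 Å) of the mass-weighted center of mass of
amino acid *i*. Distances use the minimum-image convention in orthorhombic
boxes; non-periodic mode is available for fixtures. Counts are evaluated on
a fixed grid t = t_eq + k·Δt (Δt default 100 ps), each grid time mapped to
the nearest stored post-equilibration frame with ties resolved to the
earlier frame, and averaged over the grid to give ⟨C_i⟩. The implementation
uses a k-d tree over ligand centers of mass with an exact strict-inequality
re-check; tests require exact agreement with an all-pairs brute-force scan.

C_domain sums ⟨C_i⟩ over the domain's residues — exactly additive over any
partition, and free to exceed the copy count when one copy touches several
residues simultaneously. In mixtures each species is counted independently:
a focal species' C_i never includes co-compound copies.

The competition matrix holds C_domain of the focal compound (rows) in the
presence of a co-compound (columns); diagonal cells are single-compound
systems and off-diagonal cells are annotated `increase`/`decrease` against
the focal compound's diagonal value. Missing diagonals suppress the row's
annotations with a warning.

Hotspots are residues with ⟨C_i⟩ > mean + k·sd (population sd, default
k = 1); the threshold is a package convention, exposed as a parameter,
since hotspot visualization is otherwise a visual judgement. Writing ⟨C_i⟩
into the PDB B-factor column (6.2F format, clipped at 999.99 with a
warning, missing residues set to 0) lets any viewer color the most visited
surface spots; a round-trip re-parse recovers the averages to the column
precision of 0.01.

## Migration kinematics

Tracks are strictly time-ordered planar samples per cell. Velocity is
accumulated path length divided by elapsed time (the convention of common
chemotaxis-analysis tools), not a mean of instantaneous speeds. Directional
persistence is the directionality ratio Euclidean/accumulated distance — 1
for straight motion, 0 for a net return to the origin, undefined (flagged,
not 0) for a stationary track. Statistics are computed over the track as
given; windowing to a fixed observation span is the caller's choice, not an
implicit truncation. All statistics are invariant under rigid transforms of
the coordinate system.

The Mann–Whitney U statistic counts pairwise wins with ½ per tie. The
two-sided p-value is exact — full enumeration of all C(n, n_a) label
assignments — when n_a + n_b ≤ 12 and the pooled sample is tie-free, and
otherwise uses the normal approximation with tie correction and continuity
correction. Both branches agree with an independent implementation
(scipy's) to machine precision in the tests, which also verify the
conservation law U_a + U_b = n_a·n_b.

## Synthetic data

The generators produce the study's conditions in miniature, with analytic
ground truth:

- **Lattice protein**: one Cα pseudo-atom per residue on a cubic grid
  (non-collinear by construction), with assignable residue types and a
  domain map; a multi-atom glycine exists for center-of-mass tests.
- **Ligand diffusion**: single-atom copies, i.i.d. uniform per frame
  (occupancy law E[⟨C_i⟩] = M·(4/3)πr³/V) or tethered — one copy held
  within a bind radius of a chosen residue on a deterministic Bresenham
  schedule hitting an exact bound fraction, kept outside the cutoff when
  unbound so the bound fraction equals the contact occupancy exactly.
  Optional per-frame Gaussian wobble of the protein produces non-trivial
  RMSD/RMSF. Defaults mirror the target study scale where it matters for
  the statistics: 10 copies per species, a ~13.7 nm box, 100 ps sampling.
- **Harmonic fluctuations**: per-residue sinusoids with random direction
  and phase; with full oscillation periods sampled, RMSF is A/√2 exactly.
- **Rigid motion**: translated/rotated copies of the reference; superposed
  RMSD 0, unsuperposed RMSD equal to the translation magnitude.
- **Persistent random walks**: constant-speed 2-D steps with turning
  angles uniform on [−π(1−p), π(1−p)], so p = 0 is exactly the unbiased
  walk, p = 1 exactly straight, and mean persistence increases with p.
  Sampling defaults (25-min intervals, 19 steps ≈ 8 h, 40–200 cells)
  match typical live-cell tracking experiments.

No solvent or ions are generated: the contact statistic depends only on
ligand and residue centers of mass, so explicit water is irrelevant to it.
This is the main respect in which passing tests do not certify behaviour on
real MD output — real trajectories add correlated protein motion, solvent-
mediated kinetics and multi-atom ligands (the code paths for multi-atom
copies and periodic wrap are exercised, but at fixture scale). Likewise the
persistent-random-walk tracks have no measurement noise, drift, or cell
division/loss events.

## Numerical conventions

- Internal length unit Å throughout; the cutoff parameter is given in nm
  (0.7 nm = 7 Å) to match the field's convention.
- Strict inequality at the contact cutoff; a copy at exactly the cutoff
  does not count.
- Grid anchoring at the equilibration boundary; nearest-frame mapping with
  ties to the earlier frame.
- Kabsch degenerate geometry: the reference's second singular value must
  exceed 1e-10 of the first.
- Quartiles by Tukey hinges, whiskers at 1.5×IQR.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical generator output, and the report pipeline is
  byte-identical across reruns (checksummed manifest, no timestamps).

## Problem sizes

Test and verification runs use deliberately small systems — 4–50 residue
lattice proteins, 10 ligand copies, 10²–10⁴ frames, 200–400 tracks — chosen
so each statistical check has enough power for its stated tolerance (1–2%
for closed forms, 3 standard errors for stochastic recoveries, exact for
oracle and invariance checks) while the whole suite stays fast.

## Known limitations

- Orthorhombic boxes only; triclinic minimum image is not implemented.
- PDB only (no mmCIF); insertion codes rejected; one model per file.
- Per-domain RMSD uses a single reference frame; no windowed or
  block-averaged error estimates.
- The competition matrix annotates direction of change but attaches no
  significance test — single trajectories per cell, as in the target
  workflow, give no replicate variance to test against.
- Tracks are two-dimensional, matching planar phase-contrast imaging.
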