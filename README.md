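# mdcontact

Domain-resolved stability and ligand-contact analysis of protein MD
trajectories, with single-cell migration kinematics.

`mdcontact` is built for studies that ask how small ligands — for example
endocrine-disruptive chemicals such as bisphenol A, genistein, alternariol or
α-zearalenol — interact with a multidomain receptor such as an integrin
fragment, and how those interactions change in chemical mixtures. It covers
the in-silico side of such a study end to end:

- **Domain model.** PDB structures parsed into a flat atom table; named
  domains defined as chain-scoped inclusive residue ranges (e.g. an integrin
  fragment's N-domain = chain A 1:126 ∪ 328:597, α1 = 127:327, Hyb =
  chain B 58:101 ∪ 343:423, β1 = 102:342, available as a built-in map).
- **Stability metrics.** Per-domain RMSD time series (each frame optimally
  superposed with the Kabsch algorithm onto a reference, using only that
  domain's atoms), per-residue RMSF about the aligned mean structure, and
  Tukey box statistics of RMSF per domain. The first 3 ns of each trajectory
  are treated as equilibration and discarded.
- **Contact occupancy.** The transient contact number C_i(t) counts ligand
  copies whose center of mass lies strictly within 0.7 nm of the center of
  mass of amino acid *i* (minimum-image convention in periodic boxes),
  evaluated every 100 ps and averaged into ⟨C_i⟩. The domain contact number

      C_domain = Σ_{i ∈ domain} ⟨C_i⟩

  may exceed the number of ligand copies, because one copy can contact
  several residues simultaneously. Comparing C_domain for a compound alone
  versus in a binary mixture gives a per-domain **competition matrix** with
  increase/decrease annotations, revealing displacement or relocation
  between compounds. ⟨C_i⟩ can be written into the B-factor column of a PDB
  file to visualize contact hotspots in any molecular viewer.
- **Migration kinematics.** Per-cell velocity (accumulated path length over
  elapsed time, μm/min), accumulated and Euclidean distance, and directional
  persistence (Euclidean/accumulated ∈ [0, 1]); two-group comparisons by the
  Mann–Whitney U test (exact enumeration for small tie-free samples).
- **Synthetic data.** Generators for every fixture the pipeline needs —
  lattice pseudo-proteins, ligand diffusion with controlled occupancy,
  harmonic fluctuations with RMSF ground truth A/√2, rigid-body motion with
  known RMSD, and persistent random walks with tunable persistence — so the
  whole chain is testable without an MD engine.

## Worked example

Generate a synthetic study (four ligand systems around a two-domain toy
protein, plus two migration conditions) and run the full report:

```sh
mdcontact simulate demo --seed 1 --n-frames 101
mdcontact report demo/config.yaml
```

which prints, among other tables:

```
== competition_D1 ==
        cmpA with cmpA       C_domain = 1.789 [diagonal]
        cmpA with cmpB       C_domain = 1.704 [decrease]
        cmpB with cmpA       C_domain = 0.493 [increase]
        cmpB with cmpB       C_domain = 0.451 [diagonal]
...
== Migration summary ==
       control n=40 median v = 0.600 um/min, mean persistence = 0.678
       treated n=40 median v = 0.300 um/min, mean persistence = 0.300
```

Reading the competition matrix: species `cmpA` is tethered near domain D1,
so its diagonal C_domain there (1.789 — the compound alone) is high; adding
`cmpB` lowers it slightly (1.704, annotated *decrease*), while `cmpB`'s own
D1 contacts rise in the mixture (*increase*). The migration summary shows
the generated "treated" condition's slower (0.3 vs 0.6 μm/min median
velocity) and less persistent (0.30 vs 0.68) motion; `track_tests.csv`
holds the Mann–Whitney p-values. All tables land as tidy CSV in
`demo/report/` together with B-factor-annotated PDBs and a checksummed
manifest; reruns are byte-identical.

The same stages are available as library functions
(`mdcontact.contact_series`, `domain_contact_number`, `competition_matrix`,
`domain_rmsd_series`, `residue_rmsf`, `read_tracks`, `mann_whitney_u`, …)
and as separate CLI stages (`stability`, `contacts`, `tracks`).

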