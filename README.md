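# hydrashell

Analysis of protein hydration from solvated trajectories and its
solution-side correlates. Highly stable designed proteins — e.g.
inverse-folding redesigns of the ubiquitin β-grasp fold — appear to owe
part of their resilience to an ordered, long-lived shell of surface
water. Testing that idea needs the same bookkeeping on every system:
how many waters sit in the primary (≤ 3.5 Å of solute heavy atoms) and
secondary (3.5–10 Å) hydration shells, how long they stay, how many
protein–water and water–water hydrogen bonds they form (3.5 Å / 30°
geometric criterion), how strong the protein–water nonbonded
interaction is (12-6 Lennard-Jones + Coulomb within 12 Å), and whether
the NMR observables that report on hydration — amide temperature
coefficients Δδ_NH/ΔT, HDX intensity-retention ratios I(t)/I(0), the
rotational correlation time τ_c from R₂/R₁ — and the sequence's charged
surface composition move the same way.

`hydrashell` implements that pipeline as a library with a thin CLI, for
structural-bioinformatics users who have coordinate files (multi-model
PDB as the trajectory container), per-residue NMR tables, and FASTA
sequences. Full solvated MD is out of scope; instead a synthetic-data
generator builds toy solvated systems, scripted-occupancy trajectories,
NMR tables and design sets with exact known ground truth, so every
stage is verifiable — and verified — against brute-force oracles at
desk scale.

## Core quantities

* shell assignment: water oxygen → primary / secondary / bulk by
  minimum distance to solute heavy atoms (ties to the inner shell);
  residence runs with an optional frame-gap tolerance; Monte-Carlo
  shell volumes and densities; cumulative averages after burn-in
* hydrogen bonds: donor–acceptor ≤ 3.5 Å and D–H···A within 30° of
  linear; classified protein–water / water–water (per shell) /
  protein–protein; per-residue attribution
* energetics: E = Σ 4ε[(σ/r)¹² − (σ/r)⁶] + 332.0637·q_iq_j/(ε_r r)
  over cross pairs within 12 Å, Lorentz–Berthelot mixing; radius of
  gyration and a baseline-factor unfolding detector
* NMR: per-residue OLS slopes in ppb/K with the empirical HB rule
  (slope > −5.0 ppb/K), profile correlations, HDX protection counts at
  inclusive/strict thresholds, τ_c = √(6R₂/R₁ − 7)/(4πν_N)
* sequences: K/R vs D/E composition (His optional), net charge and the
  counterion count that neutralises it, substitution maps, and
  charged-residue enrichment statistics over design sets

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Build the toy study pair and compare it (scripts live under
`analysis/`, each a thin driver over the library; tables land in
`results/`):

```console
$ python analysis/01_build_synthetic_systems.py
wildtype_like: 51 atoms, 13 waters, 40 frames -> results/synthetic/wildtype_like.pdb
nonbonded parameters -> results/synthetic/parameters.csv
enhanced_hydration: 81 atoms, 23 waters, 40 frames -> results/synthetic/enhanced_hydration.pdb

$ python analysis/07_comparative_study.py
                 metric  wildtype_mean  enhanced_mean  diff_of_means
              n_primary       6.000000      16.000000     -10.000000
        n_protein_water       3.000000       8.000000      -5.000000
           energy_total     -23.086345     -51.679188      28.592842
```

The enhanced-hydration system was built with ten extra primary-shell
waters, five extra donated hydrogen bonds, and correspondingly stronger
(more negative) protein–water interaction energy — and the pipeline
recovers exactly those differences from the written PDB trajectories.
The sequence side of the story:

```console
$ python analysis/06_sequence_charges.py
ubiquitin: 11 positive / 11 negative, net +0 e -> counterions (0, 0)
12/15 composition: net -3 e -> 3 cations, 0 anions
500 variants: mean enrichment 5.26% positive, 6.58% negative (sd 0.000 / 0.000)
```

The same stages are exposed as a CLI for user data:

```bash
hydrashell shells results/synthetic/enhanced_hydration.pdb --out-dir out/
hydrashell energy results/synthetic/enhanced_hydration.pdb \
    --parameters results/synthetic/parameters.csv --out-dir out/
hydrashell seqcharge my_designs.fasta --out-dir out/
hydrashell demo --seed 0 --out-dir demo_out/   # self-checking toy study
```

`hydrashell demo` exits nonzero naming the first stage whose
ground-truth check fails; its `manifest.json` records the config
snapshot, seed, per-stage substream seeds and file digests needed to
replay the run.

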