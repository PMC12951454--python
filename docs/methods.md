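# Methods

`hydrashell` quantifies how a protein organises the water around it, and
the solution-NMR and sequence-level observables that co-report on that
organisation. It is built for the comparison that motivates it: a
wild-type-like solute versus a variant whose surface recruits more
ordered, longer-lived hydration water. Because full solvated MD
trajectories are far beyond desk scale, every stage is exercised against
a synthetic-data generator whose ground truth is known by construction;
the generator is first-class, tested code, not a fixture.

## Hydration shells

A water is represented by its oxygen. Per frame, the minimum Euclidean
distance d from each water oxygen to any solute non-hydrogen atom bins
the water into the **primary shell** (d ≤ 3.5 Å), the **secondary
shell** (3.5 < d ≤ 10 Å) or bulk. The boundary convention is closed on
the inner side — a water at exactly the cutoff belongs to the inner
shell — so the partition is deterministic and exhaustive (the three
counts always sum to the number of waters). Both cutoffs live in
`AnalysisConfig` (`primary_cutoff`, `secondary_cutoff`).

Distances are computed with a k-d tree (`scipy.spatial.cKDTree`); an
exhaustive all-pairs oracle is kept in the test suite and the two must
agree exactly. With orthorhombic box lengths present, minimum-image
distances are used; toy systems are non-periodic by default.

**Residence runs.** A run is a maximal stretch of frames in which a
water occupies a shell, optionally tolerating interior excursions of at
most `gap_tolerance` consecutive frames (default 0; gap frames count
toward the run length, so intervals 10–20 and 22–30 merge into one
21-frame run at tolerance 1). "Residence time" has no unique definition
in the trajectory-analysis literature (continuous vs intermittent
survival correlators); the run-length definition here is declared, not
inferred, and the tolerance is exposed. Frame-based gap merging requires
uniform frame spacing and errors otherwise.

**Shell density.** The shell volume has no closed form for a general
solute, so it is estimated by Monte-Carlo rejection sampling: uniform
points in the solute bounding box padded by the secondary cutoff, the
in-band fraction times the box volume, with the binomial standard error
reported. Density is the shell water count over that volume. For a
single atom the primary-shell volume must converge to (4/3)π(3.5)³ =
179.59 ų, tested at three MC standard errors. Any density figure
produced this way carries the MC volume definition with it.

**Cumulative averages.** Every per-frame series can be smoothed by a
running mean after discarding frames with time < `burn_in_time`
(default 40 000 ps, i.e. the first 40 ns of a 500 ns run; with frames
every 100 ps that leaves exactly 4600 analysis frames). When a
trajectory carries no time stamps the reader stamps frames at the
requested spacing starting from 0.

## Hydrogen bonds

Geometric criterion: donor–acceptor (heavy–heavy) distance ≤ 3.5 Å and
deviation of the D–H···A angle from linearity ≤ 30° (D–H···A ≥ 150°).
Donors are N/O atoms with at least one covalently bound hydrogen
(hydrogens without bond records attach to the nearest heavy atom within
1.2 Å; an orphan hydrogen is an error); acceptors are all N/O atoms;
sulfur is excluded by default (`include_sulfur`). A 30° "angle
criterion" is also sometimes read as an H–D···A cone or applied to the
H···A distance; those are conventions, not facts, so the distance mode
is configurable (`hb_distance_mode`: donor–acceptor or
hydrogen–acceptor) and the angle convention is documented rather than
silently assumed.

Intramolecular water pairs are excluded. When both hydrogens of one
donor reach the same acceptor, the pair counts once and the hydrogen
with the smaller angular deviation is kept — one physical bond, one
record. Bonds are classified protein–water, water–water or
protein–protein by the molecule types of donor and acceptor, and tagged
with the hydration shell of the participating water (donor water for
water–water bonds), which is how water–water counts are split by shell.
Counts are provably monotone in both cutoffs, and the generator
round-trip holds: waters placed with a linear donated bond at d ≤
cutoff are all detected, waters bent beyond the angle cutoff are all
rejected.

Per-residue attribution: a protein–water bond belongs to its protein
residue; a water–water bond is credited to every residue with a heavy
atom within the primary cutoff of either water oxygen (a "water bridge
near this residue" notion). Means are taken over post-burn-in frames.

## Nonbonded energetics

Protein–water interaction energy is the pairwise sum over cross pairs
with r ≤ 12 Å of

    4ε[(σ/r)¹² − (σ/r)⁶] + k_C q_i q_j / (ε_r r)

with Lorentz–Berthelot mixing (arithmetic σ, geometric ε) and
k_C = 332.0637 kcal·Å·mol⁻¹·e⁻². Plain truncation, no switching
function, no long-range correction: this mirrors a cutoff-based
post-hoc energy analysis of saved frames, not the simulation engine's
PME electrostatics — running MD is out of scope entirely. The LJ and
Coulomb parts are reported separately and must sum to the total to
1e-9 relative. PDB files carry no charges or LJ parameters, so they are
supplied by the synthetic generator or a side-car table keyed by
(atom name, residue name) (`parameter_table` / `apply_parameters`);
force-field file parsing is deliberately not implemented.

Compactness is the mass-weighted radius of gyration (unit masses when
none are given). The unfolding detector flags the first frame where Rg
exceeds `factor` (default 1.5) times the mean over an early baseline
window (default 5% of the trajectory). Heat-denaturation trajectories
cannot be regenerated at desk scale, so the detector is validated on
synthetic step series with a constructed onset, and those thresholds
are declared artifact parameters, not inferred ones.

## NMR observables

**Temperature coefficients.** Per residue, the OLS slope of the amide
shift (ppm) against temperature (K), reported in ppb/K; the synthetic
grid follows common amide-tracking practice, 281–320 K in 5 K steps.
The empirical hydrogen-bond rule classifies a residue as hydrogen
bonded iff its slope is strictly above a threshold (−5.0 ppb/K default,
−2.72 ppb/K for GB3-calibrated work — both exposed). A constant-shift
series gets slope 0 with r² defined as 1 (a perfect flat fit; Pearson r
is undefined at zero variance). Residues with fewer than three points
are skipped with a warning. Profile comparison uses Pearson correlation
over the intersection of residue keys, no imputation; Spearman is an
option since the published correlation flavour for such profiles is
often unstated.

**HDX protection.** The retention ratio I(t)/I(0) of amide cross-peak
intensities after exchange into D₂O, default t = 48 h. Protection at a
threshold is inclusive at the canonical 0.2 ("retaining ≥ 20%") and
strict for cuts quoted as strict (">60%"), matching how such thresholds
are printed; counts are non-increasing in the threshold by
construction. No intrinsic-exchange (sequence/pH) correction is
applied: ratios are reported raw, so cross-condition comparisons at
different pH fold in the intrinsic-rate change.

**Rotational correlation time.** τ_c = sqrt(6·R₂/R₁ − 7) / (4π·ν_N),
with ν_N the ¹⁵N Larmor frequency implied by the ¹H field
(|γ_N/γ_H| = 0.10136767). This is the standard isotropic single-field
estimator — closed-form, invertible (the inverse is shipped and the
round trip is tested to 1e-6 ns) — not a spectral-density or
anisotropic-diffusion fit, which would need more data than an R₂/R₁
ratio. It is valid only for R₂/R₁ > 7/6 (domain error otherwise) and is
accurate in the slow-tumbling limit, a few ns upward at typical fields.

## Sequence charges

Side-chain counting only: K and R positive, D and E negative, histidine
neutral by default (`KRH_DE` optional), termini excluded, full sequence
length as the percentage denominator, no pKa model. This scheme
reproduces the 11/11, net-zero profile of the canonical 76-residue
ubiquitin sequence (embedded as `UBIQUITIN_SEQUENCE`) and gives the
counterion rule its simple form: cations = max(0, −net),
anions = max(0, net), which restores exact neutrality — a 12/15
composition needs three monovalent cations. Design-set enrichment is
the per-variant delta in percent positive/negative versus the template,
summarised by mean and population (ddof = 0) standard deviation.
Composition conventions are not innocuous: published per-protein
positive/negative counts and percentage enrichments can disagree with
any single counting scheme (His treatment, termini, length
normalisation), which is exactly why the scheme here is explicit and
validated against two self-consistent reference numbers rather than
all printed ones.

## The synthetic generator

What it emulates, and what it does not:

* **Toy solvated systems** — a compact cubic-lattice cluster of charged
  pseudo-atoms (alternating N/O elements, ±0.5 e, σ = 3.3 Å,
  ε = 0.1 kcal/mol) stands in for a protein; rigid 3-site waters
  (0.9572 Å / 104.52°, O −0.834 e, H +0.417 e, LJ on oxygen only — the
  TIP3P-class parameterisation) are placed so their oxygen sits at an
  exact prescribed distance from its nearest solute atom, optionally
  donating a perfectly linear or deliberately bent hydrogen bond to a
  named acceptor. Placement is by bounded rejection sampling (error
  after 500 retries), waters kept ≥ 2 Å apart.
* **Trajectories** — shell occupancy is scripted per water as frame
  intervals; inside its intervals a water sits in the primary shell (at
  its constructed position when already primary, else at 0.7× the
  cutoff), outside — and for unscripted waters — it is parked 4 Å
  beyond the secondary cutoff. Gaussian jitter is truncated at 3 sd and
  refused outright whenever the worst-case relative displacement
  (2·3·sd·√3) could cross a shell boundary, so scripted occupancy is
  exact, not approximate. Times are uniform (default 100 ps).
* **NMR tables** — shifts linear in temperature with known ppb/K
  slopes plus optional Gaussian noise; HDX intensities exp(−k t) with a
  designated protected subset (k_slow) against k_fast; ground truth
  stored in table metadata.
* **Design sets** — each variant substitutes exact numbers of
  non-charged template positions to K/R and D/E, so the enrichment
  deltas are known arithmetic.

Not emulated: water dynamics (no diffusion, no exchange kinetics),
periodic boundary conditions, force-field-accurate geometry, spectral
noise structure, conformational change. Passing tests therefore certify
the *bookkeeping and the mathematics* of every stage — distances,
angles, energies, regressions, counts — under controlled truth; they do
not certify that a real trajectory would show any particular hydration
difference. Every generator is a deterministic function of (spec, seed),
and each analysis applied to noise-free generator output must recover
the stored truth exactly.

## Numerical choices and degenerate inputs

* Shell ties go to the inner shell (closed inner boundary).
* One (donor, acceptor) pair → one HB record (best-deviation hydrogen).
* Energy: coincident cross-group atoms are an error (r = 0); pairs with
  ε = 0 contribute no LJ term; cutoff is inclusive (r ≤ 12 Å).
* Burn-in discarding every frame, zero solute heavy atoms, zero total
  mass, empty design sets, all-residues-skipped tables: all errors,
  never silent zeros. Missing table cells parse as missing, not 0.
* MC shell volume requires ≥ 10⁴ samples and errors on a zero estimate.
* Study sizes: the shipped toy study uses 40-frame, ≤ 81-atom systems
  and the test suite's oracle batch tops out at 300 waters — sizes
  chosen so exhaustive brute-force verification of every operation
  stays comfortable on one CPU.

## Known limitations

* The comparative study's secondary-shell counts are degenerate on
  scripted trajectories (unscripted waters are parked in bulk); the
  secondary shell is exercised via static placements instead.
* τ_c ignores anisotropy and fast internal motion; it is a size/
  friction proxy, not a model-free analysis.
* Per-residue water-water attribution double-counts a bridge shared by
  two residues by design (it answers "how busy is this residue's
  surface", not "how many bonds exist").
* The PDB dialect is the fixed-column subset (no mmCIF, no compressed
  trajectory formats); element inference from atom names follows the
  column-13 convention and can be fooled by nonstandard ion naming.
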