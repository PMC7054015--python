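# Methods

## Polymer model

Chromosomes are Kremer–Grest-type bead-spring chains. One bead represents
~3.2 kb of chromatin as a 30-nm sphere (σ), consistent with yeast
chromatin compaction. Three intra-chain terms act:

- **Excluded volume.** WCA potential (repulsive Lennard-Jones truncated
  and shifted at 2^(1/6) σ), ε = 1 kT, between all bead pairs. Together
  with the bonds this prevents chain crossing.
- **Connectivity.** FENE bonds between consecutive beads,
  R₀ = 45 nm (1.5 σ), K = 30 kT/σ² (the standard Kremer–Grest value; the
  spring constant is not critical as long as bonds cannot reach R₀).
- **Bending.** Kratky–Porod energy κ(1 − cos θ) per joint. The discrete
  worm-like-chain mapping κ = Lp/b (kT) is used with Lp = 61.7 nm for
  internal chromatin and 195.0 nm for the compact, rigid 20-kb regions at
  free chromosome ends; the stiff value applies to joints whose three
  beads all lie in a telomeric region.

Measured persistence lengths of free chains slightly exceed the input Lp
(by ~5–10%) because next-neighbour excluded volume adds local stiffness;
the tangent-correlation estimator therefore fits only short contour lags
(≤3 bonds, through the origin), where the decay is exponential — at longer
lags self-avoidance makes the decay slower than exponential and would
bias Lp upward.

## Nuclear landmarks

The nucleus is a rigid sphere, R = 1000 nm. Landmark regions:

- **SPB**: a 150-nm sphere internally tangent to the NE at (−850, 0, 0);
  centromere beads are confined inside it (microtubule tethering).
- **Nucleolus**: the lens-shaped intersection of the nucleus with a
  sphere centred at (1000, 0, 0); its radius (640.92 nm) is solved by
  Brent root-finding on the closed-form two-sphere lens volume so the
  lens holds 10% of the nuclear volume (solver tolerance ≤ 0.005 nm,
  verified against Monte-Carlo integration). rDNA beads are kept inside,
  all other beads outside.
- **Peripheral shell**: the nucleus is divided into three concentric
  equal-volume shells, r₁ = (1/3)^(1/3) R ≈ 693.4 nm,
  r₂ = (2/3)^(1/3) R ≈ 873.6 nm; the outermost layer is 126 nm deep.
  Boundary points are assigned to the inner shell (a zero-measure,
  determinism-only choice).

All confinements act through the one-sided quadratic "indent" force
F = K(r − R)², K = 10 (reduced units), applied only to beads violating
their condition. A bead exactly at a keep-outside sphere's centre has no
defined direction; a fixed +x unit vector is used.

**Telomere–NE attraction.** Terminal beads feel a truncated-shifted
Lennard-Jones well in the wall distance s = R_nuc − r, cutoff 126 nm (the
peripheral-shell depth). The well depth is the one free parameter of the
model; it was calibrated once, by sweeping 1–5 kT on the 1/10-scale
wild-type system, to the published behaviour that telomeres are *not*
strictly peripheral — they should sit outside the peripheral shell in
roughly 40% of conformations. The equilibrated sweep gave 45% at 4 kT,
39.8% at 4.5 kT and 35.8% at 5 kT; the shipped default is **4.5 kT**.

## Dynamics and sampling

BAOAB Langevin integration at kT = 1, friction γ = 1/τ_LJ, dt = 0.01
τ_LJ, mass 1 per bead (τ_LJ = σ√(m/ε)). Chains are initialised as
solenoidal rods (radius ≤ 150 nm, ~34.5-nm bonds, 32-nm rise per turn —
compact, unentangled, no self-overlap), placed longest-first at uniform
random positions/orientations with clash rejection (inter-chain minimum
distance σ), then relaxed with all restraints active (60 τ_LJ preliminary
at full scale) and sampled during production (30,000 τ_LJ, one
conformation per 3000 τ_LJ, 1000 replicates → 10,000 conformations).

Two numerical safeguards: per-bead speeds are clamped at 10 σ/τ_LJ
(0.05 σ per half-step), which leaves thermal motion (~1.7 σ/τ_LJ)
untouched but keeps the integrator stable while a fresh placement still
grossly violates the quadratic restraints; and the FENE denominator is
floored to avoid singularities that equilibrium dynamics never reach.
Pair forces use a direct O(N²) cutoff loop: the systems integrated at
desk scale are a few hundred beads, where all-pairs is faster than
neighbour-list bookkeeping and bitwise-identical in the forces.

Per-replicate seeds derive from the master seed via a counter-based seed
sequence and are recorded in the ensemble manifest; runs are bit
reproducible.

## Problem sizes used in the shipped analyses

Full-scale ensembles (4062 beads × 1000 replicates × 30,000 τ_LJ × 11
strains) are a cluster-scale computation. The shipped tests and examples
run the same code on reduced systems chosen to preserve the relevant
physics: a 1/10-length-scaled 16-chromosome wild type (413 beads, 10
replicates × 10 samples = 100 conformations, 420 τ_LJ equilibration +
600 τ_LJ production) for the telomere shell statistic, and a
three-chromosome mini karyotype with one fusion for the
envelope-displacement contrast. Equilibration was verified by per-sample
stationarity of the statistics and by KS comparison of radial
distributions between production halves.

## Karyotypes and fusions

Chromosome lengths and centromere midpoints follow the R64-1-1 assembly.
The rDNA array on chromosome XII is modelled as 101 tandem 9.1-kb repeats
(within the organism's 100–200 range), chosen so the wild-type genome
discretises to exactly 4062 beads; per-chromosome overrides are possible.
Bead tiling is per source segment with a ceiling rule (the last bead
carries the remainder bp), so fusing chromosomes conserves beads exactly:
a fusion adds a connectivity bond between the junction beads, which lose
their terminal/telomeric character (no NE attraction, internal bending
stiffness), while donor centromeres lose their SPB restraint. Junction
sequence deletion defaults to 0 bp and is configurable per event. The ten
canonical fusion strains join the growing composite's right end
(chromosome IV first — its right telomere is consumed in every strain) to
the next donor's left end; with junction ends not otherwise documented,
this orientation convention is the package's choice and affects only
which subtelomeres are flagged as former junctions.

## Structural statistics

- **Shell occupancy**: per-bead fractions over the ensemble; beads caught
  marginally outside the nucleus count as peripheral. Per-gene
  % peripheral is the unweighted mean over beads overlapping the gene
  (any-overlap mapping), ×100.
- **10-kb loci**: non-overlapping groups of three consecutive beads from
  the chain start (trailing remainder = one short locus); NE distance is
  R_nuc − |x| from bead centres, averaged within the locus, then over
  conformations.
- **Contact maps**: bead pairs within 120 nm are contacts; bins are 10
  beads (32 kb); the bin-pair value is the fraction of conformations with
  ≥1 contacting bead pair (bounded in [0,1] like a contact probability; a
  raw-count mode exists behind a flag). Model/experiment comparison uses
  Spearman correlation per intra-chromosomal genomic-distance stratum;
  the experimental matrix is an externally preprocessed input.
- **2D density maps**: beads projected to (a, ρ) = (x, √(y²+z²)),
  histogrammed on a 2 × 2 µm grid with 10-nm pixels, blurred with a 30-nm
  Gaussian and normalised to a unit maximum. Kernel mass is conserved
  away from grid edges; mass within ~3 blur widths of the ρ = 0 axis is
  clipped, an inherent property of the half-plane projection.

## Expression analyses

Fold changes are log2((strain median + c)/(baseline + c)) with pseudocount
c = 0.1 TPM (configurable; the pseudocount tames low-count noise at the
price of slightly attenuating fold changes of weakly expressed genes).
The baseline for each gene is the median, across strains in which the
gene is predicted to move < 1 pp, of the per-strain replicate medians;
when no strain qualifies the wild-type median is used. Per-gene
significance uses the Welch two-sample t-test on log2(TPM + c) between
the strain's replicates and the pooled replicates of baseline-eligible
strains (unequal-variance form used uniformly; pooled-variance is a
flag). Group contrasts use one-way ANOVA with Tukey HSD against the
non-displaced (|Δ%P| ≤ 1 pp) group; mover counts use raw p < 0.05 with no
multiplicity correction, deliberately mirroring the simple counting
analysis they feed. Distance to telomere is measured from the gene
midpoint to the nearest wild-type chromosome end; log-space distances use
ln(kb + 1). The sequential (type-I) ANOVA enters terms in the order Δ%P,
WT expression, CEN distance, CEN lost, CEN distance × CEN lost, so each F
tests the increment over the preceding terms, on all genes and on subsets
within 200/100/75/15 kb of the centromere.

## Synthetic data generator

The generator emulates the statistical structure of a real RNA-seq
TPM table: per-gene log2 baselines ~ N(5, 2²); a subtelomeric repression
term −δ·exp(−d_tel/λ) with δ = 2 log2 units and λ = 10 kb (genes at
chromosome ends ~4-fold repressed); a periphery coupling
log2(1 + g·(P_WT − P_s)) with g = 0.01 per percentage point (so a 25-pp
decrease in peripheral residency yields exactly ×1.25 expression — the
effect size the analyses are designed to detect); replicate noise
~ N(0, 0.25²) in log2 (a placeholder magnitude for typical RNA-seq
replicate scatter, flagged as such); optional Poisson counting noise at a
configurable library size. An alternative log-linear coupling
(g directly in log2 units per pp) is available behind a flag and is used
where an exactly linear response is required (e.g. testing the sequential
ANOVA's null behaviour, since the default coupling is mildly nonlinear in
Δ%P).

What the generator does *not* emulate: gene-length and GC biases,
correlated expression programmes (stress regulons), mapping artefacts,
and strain-specific copy-number effects. Passing the recovery tests
therefore shows the estimators are unbiased and calibrated under the
generator's assumptions, not that real data meet those assumptions.

Position stubs (wild-type residency decaying from chromosome ends;
configurable displacement on fused arms, strongest near former
telomeres) let every expression analysis run without the simulator.

## Known limitations

- The acceptance-grade telomere shell statistic is calibrated at 1/10
  scale; the attraction depth that yields 40% non-peripheral telomeres at
  full scale could differ somewhat with full crowding.
- Fusion junction orientations and deleted junction bp are conventions
  (documented above), not measured values.
- Hydrodynamics, strand passage by topoisomerases, cell-cycle geometry
  changes and non-spherical nuclei are out of scope.
- The O(N²) force loop makes full-genome (4062-bead) production runs
  slow; they are supported but intended for cluster-scale use.
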