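# yeastnuc

Restraint-based polymer modelling of the budding-yeast (*Saccharomyces
cerevisiae*) interphase nucleus, and the statistics that connect predicted
gene position to gene expression — for the wild-type karyotype and for
strains in which chromosomes have been fused end-to-end.

## The scientific problem

In interphase yeast nuclei, chromosome organisation is stereotyped: the 16
centromeres cluster near the spindle pole body (SPB), the 32 telomeres
anchor at the nuclear envelope (NE), and the rDNA array on chromosome XII
organises the nucleolus opposite the SPB. Fusing chromosomes end-to-end
deletes centromeres and telomeres and therefore rewires this organisation.
`yeastnuc` models each karyotype as an ensemble of bead-and-spring polymer
conformations under minimal landmark restraints, quantifies where every
locus sits relative to the NE, and asks whether genes predicted to move
away from the periphery change their expression.

The package is aimed at computational biologists who want to (a) generate
conformational ensembles for arbitrary (including fused) yeast karyotypes,
(b) derive positional statistics — radial shell occupancy, contact maps,
NE/SPB displacement — and (c) run the position-vs-expression regression
and resampling analyses on real or synthetic expression tables.

## The model

Each chromosome is a chain of 30-nm beads (~3.2 kb of chromatin per bead;
4062 beads genome-wide, including a 101-repeat rDNA array) with three
energy terms:

- **excluded volume** — purely repulsive (WCA) Lennard-Jones, σ = 30 nm;
- **connectivity** — FENE bonds, maximum extension 45 nm;
- **bending** — Kratky–Porod stiffness κ = Lp/b with Lp = 61.7 nm
  internally and 195.0 nm over the 20-kb telomeric regions.

Nuclear organisation enters through one-sided quadratic restraints
F = K(r−R)², K = 10: all beads inside the 1-µm-radius nucleus, centromere
beads inside a 150-nm sphere tangent to the NE at (−850, 0, 0) (the SPB),
rDNA beads inside — and all others outside — a nucleolar sphere of radius
640.92 nm centred at (1000, 0, 0) whose lens with the nucleus holds 10% of
the nuclear volume. Terminal (telomere) beads additionally feel a
short-range Lennard-Jones attraction to the NE (depth 4.5 kT, range
126 nm — the thickness of the outermost of three equal-volume shells).
Chains start as solenoidal rods placed at random without clashes (longest
first), restraints are satisfied in a short preliminary Langevin run, and
conformations are sampled from a production run (at full scale: 1000
replicates × 10 samples = 10,000 conformations per strain).

A gene's **% peripheral** is the fraction of conformations in which its
beads lie in the outermost equal-volume shell; **Δ%P** is the
fusion-strain-minus-wild-type change in percentage points. The expression
analyses regress per-gene log2 fold changes (against a robust cross-strain
baseline) on Δ%P, with LOESS trends, Tukey-corrected group contrasts,
sequential ANOVA for centromere covariates and moving-window r²
comparisons against distance-to-telomere.

## Worked example

Run the synthetic end-to-end pipeline (mini karyotype, position stubs, a
generated expression table with the default periphery–expression coupling
of 1% expression change per percentage point of Δ%P):

```python
from yeastnuc.pipeline import RunConfig, run_pipeline
root = run_pipeline(RunConfig({"out_dir": "runs/demo", "seed": 7}))
print((root / "analysis" / "summary.json").read_text())
```

which prints

```json
{
 "n_genes": 124,
 "anova_F": 20.374502212682287,
 "anova_p": 9.717652574034493e-11,
 "n_movers": 30,
 "n_significant_movers": 3
}
```

and writes `analysis/binned_groups.tsv`:

```
        group  n      mean       se
     < -15 pp  9  0.267550 0.047612
 -15 to -5 pp 21  0.113032 0.040020
  -5 to -1 pp  1 -0.220760      NaN
non-displaced 93  0.000034 0.009183
```

Genes predicted to move more than 15 pp away from the periphery show a
mean log2 fold change of ≈ 0.27 (×1.2, consistent with the injected 1%/pp
coupling at their mean displacement of ~20 pp), genes that do not move
show none, and the one-way ANOVA across displacement groups is highly
significant. `n_significant_movers` counts movers (>5 pp) whose per-gene
Welch t-test reaches p < 0.05 — low here because the demo uses only 124
genes and 4 replicates.

The nuclear geometry itself is available directly:

```python
from yeastnuc import NuclearGeometry
NuclearGeometry().describe()
# {'R_nuc_nm': 1000.0, 'c_spb_nm': [-850.0, 0.0, 0.0], 'R_spb_nm': 150.0,
#  'c_nucl_nm': [1000.0, 0.0, 0.0], 'R_nucl_nm': 640.92,
#  'nucleolar_volume_fraction': 0.1, 'shell_r1_nm': 693.36,
#  'shell_r2_nm': 873.58, 'R_per_nm': 126.42}
```

A command-line interface wraps the same functionality:

```sh
yeastnuc simulate --strain "FC(IV:XII)CEN4" --scale 0.1 --replicates 5 --seed 1 --out runs/fc
yeastnuc analyze-structure --ensemble runs/fc --strain "FC(IV:XII)CEN4" --out runs/fc-structure
yeastnuc synth expression --out runs/synth --seed 1
yeastnuc run --config myrun.yaml
```

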