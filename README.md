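# cortiquant

Quantification of cellular patterning and density in organ-of-Corti cell
mosaics — for developmental biologists measuring how hair-cell and
supporting-cell lattices break down in mutants (e.g. *Etv4/5/1* triple
knockouts), from digitized confocal surface images or from the package's
own synthetic epithelium generator.

## What it computes

**Six-arm sector-occupancy ("star") statistic.** For each focal cell in a
chosen row (second-row OHCs by default), arms are drawn to its six closest
same-type cells; each arm's direction, measured counter-clockwise from the
longitudinal axis, falls into one of 16 radial sectors of 22.5°
(sector s covers [(s−1)·22.5°, s·22.5°)). Per sample this yields a
16-vector of arm frequencies f with Σf_s = 1 and counts summing to
6·n_focal. A perfect offset-row lattice (row spacing d_c·√3/2) occupies
exactly sectors {1, 3, 6, 9, 11, 14} at 1/6 each; disorder spreads the
mass, summarized by the Shannon entropy H = −Σ f_s log₂ f_s
(log₂6 ≈ 2.585 bits for the lattice, 4 bits at uniformity).

**Per-sector group tests.** Per-cochlea sector frequencies are compared
between genotypes with two-sided two-sample t-tests (Student default,
Welch optional); stars follow * p < 0.05, ** p < 0.01 on raw p, with
Benjamini–Hochberg adjusted p always reported alongside.

**Cell density.** Cells per 100 µm of sensory epithelium,
(n_cells / L) × 100, per sample × region, compared by two-way fixed-effects
ANOVA (genotype × region, type-II SS) with Tukey HSD for genotype within
each region.

**Synthetic epithelium generator.** Seeded, bit-reproducible offset-row
mosaics with positional jitter, missing cells and ectopic hair cells in
the pillar region; presets `control` and `etv_tko` emulate the control and
knockout phenotypes so the whole pipeline is testable without imaging
data. See `docs/methods.md` for model details and limitations.

## Worked example

The numbered scripts under `analysis/` run the full simulated study
(3 cochleae per genotype for base/mid/apex) and write their tables to
`results/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_sector_profiles.py
python analysis/03_sector_tests.py
python analysis/04_density_anova.py
python analysis/05_calibration.py
```

`02_sector_profiles.py` prints the disorder summary — knockout mosaics
carry ~0.7 bits more sector entropy than controls:

```
mean sector-profile entropy (bits) by genotype and region:
genotype  region
control   apex      3.168
          base      3.188
          mid       3.226
etv_tko   apex      3.910
          base      3.937
          mid       3.918
```

`03_sector_tests.py` flags the sectors whose occupancy differs between
genotypes (the asterisks of a radar plot):

```
base: 12/16 sectors differ (raw p < 0.05): [2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14, 15]
mid: 11/16 sectors differ (raw p < 0.05): [3, 4, 5, 6, 7, 9, 10, 11, 13, 14, 15]
apex: 10/16 sectors differ (raw p < 0.05): [2, 3, 4, 6, 10, 11, 12, 13, 14, 15]
```

`04_density_anova.py` shows the flip side: the knockout preset disrupts
*arrangement*, not cell number, so hair-cell density (~37 cells/100 µm)
shows no genotype effect (two-way ANOVA genotype p = 0.95), while the
patterning statistic separates the genotypes decisively.

`05_calibration.py` checks the statistics themselves: per-sector type-I
error 0.0497 over 400 null experiments at α = 0.05, and power 1.000 for
detecting ≥ 1 significant sector in control-vs-knockout runs with n = 3.

The same pipeline is scriptable from the shell:

```sh
cortiquant simulate-experiment --preset control-vs-tko --n-samples 3 --seed 7 --out results/exp
cortiquant profile --in results/exp/mosaics.csv --axis-angle 0 --out results/exp
cortiquant density --in results/exp/mosaics.csv --out results/exp
```

Identical config + seed reproduce byte-identical tables; every output
directory gets the resolved config and a run log.

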