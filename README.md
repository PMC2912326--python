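# popflow

Marker filtering and population-structure analysis for genome-wide SNP
gene-flow studies, of the kind used to reconstruct human migration
"genome maps" from chip genotypes of many regional population groups.

Chip-scale population comparisons are sensitive to three biases that
popflow measures and removes before any clustering is trusted:

* **Recombination hotspots / LD.** Two-locus haplotype frequencies are
  estimated from unphased genotypes by EM (only the double heterozygote
  is phase-ambiguous; the E-step splits it between the *AB/ab* and
  *Ab/aB* configurations in proportion to `f_AB·f_ab` vs `f_Ab·f_aB`),
  giving `R² = D²/(p_A(1−p_A)p_B(1−p_B))`.  A marker position whose
  windowed mean R² drops below 0.7 in at least one reference population
  is flagged as a possible recombination hotspot (RH) and removed.
* **Genotype call rate (GCR).** Per sample, `GCR_i = N_gt/(N_gt + N_ng +
  N_ig)` with `N_gt` successful genotypes, `N_ng` natural no-calls, and
  `N_ig` no-calls inserted at random to build degraded dataset variants
  (data1–data3 at 95/90/85%), each passed through a marker call-rate
  cutoff (95% for the original data0, 80% for degraded sets).
* **Regional specific markers (RSM).** Per marker, each population's
  frequency-deviation variance `var_i = (p_i − p̄)²` is standardised
  across the K populations, `z_i = (var_i − μ)/σ`; markers with any
  |z| > 4 are regionally informative, and selected markers within 500 kb
  of each other are thinned to the first of each run.

On the cleaned data popflow computes identity-by-state / allele-sharing
distances (het–het sharing counted as 2, pairwise deletion), classical
(Torgerson) MDS, Patterson-standardised SNP PCA, Saitou–Nei
neighbor-joining trees (Studier–Keppler criterion, exact on additive
matrices), Weir–Cockerham Fst (per marker and ratio-of-sums mean,
group-versus-rest), and a per-population monomorphic-marker fraction as
a genetic-drift score.

Because cohorts of this kind are rarely deposited, the package ships a
synthetic-data generator with known ground truth: Balding–Nichols drift
(`p_i ~ Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i)`, so `Var(p_i) =
F_i·p(1−p)`), founder-pool haplotype blocks (high within-block R², low
cross-block R², block boundaries as planted hotspot surrogates), planted
frequency outliers, admixed individuals and random no-calls.  Every
downstream statistic is tested against this ground truth.

## Worked example

The `analysis/` scripts run the full study on a synthetic worldwide
cohort (24 regional groups × 16 samples, 2 000 SNPs at 55 kb spacing,
drift graded from F = 0.30 to 0.02, 40 planted regional markers, 98.7%
call rate):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_flag_hotspots.py
python analysis/03_callrate_grid.py
python analysis/04_select_regional_markers.py
python analysis/05_genome_map.py
python analysis/06_fst_and_drift.py
```

Selected output:

```
cohort: 384 samples in 24 groups, 2000 markers
overall genotype call rate: 0.9870
flagged 994 of 2000 panel positions as possible hotspots
planted block boundaries detected: 39/39
data3: target GCR 0.85, achieved 0.8500 after the 80% marker cutoff (1004 markers, dropped 2)
selected 320 of 1006 markers at |z| > 4
retained 61 after 500 kb thinning
data0: 1006 markers; MDS separation (between-centroid / within-spread) = 4.70 -> 4.11 at data3
highest group-vs-rest mean Fst (world level): POP2: 0.1293 ...
strongest monomorphic-marker drift (rarefied): POP1: fraction 0.212
```

Reading this: every planted hotspot boundary in the reference panel is
recovered by the R² < 0.7 rule; degradation to 85% call rate hits its
target exactly after `N_ig` insertion; the variance scan selects markers
dominated by the strongest-drift groups (planted shifts in low-drift
groups are masked by genuine drift outliers — expected on a
heterogeneous world panel); the MDS genome map keeps its 24 groups
separated across the whole call-rate grid; and the monomorphic-marker
drift ranking puts the most-drifted group (planted F = 0.30) first.

A `popflow` CLI exposes each stage (`popflow simulate|hotspots|filter|
degrade|qc|rsm|dist|embed|njtree|fst|drift|export-structure|pipeline`);
`popflow pipeline --config run.yaml` runs the configured end-to-end flow
and writes a JSON manifest with per-stage parameter, seed and
marker-count bookkeeping.

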