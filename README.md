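# rohsim

Gene-dropping breeding simulation and runs-of-homozygosity (ROH) based
inbreeding estimation.

## What this is for

Pedigree inbreeding coefficients, genomic-relationship-matrix (GRM)
inbreeding and ROH-based inbreeding all try to measure the same thing —
autozygosity, the fraction of an individual's genome where both homologous
copies descend from one ancestral copy — but they disagree in selected
populations, and with real data there is no truth to compare against.
`rohsim` creates that truth: founders carry uniquely numbered alleles at
every locus, alleles are dropped through a simulated breeding program by
Mendelian inheritance with recombination, and autozygosity is read off
exactly per animal.  On top of the simulator sit the estimators used in
practice and a panel-analysis layer for real-format SNP data:

* forward simulation of an overlapping-generation breeding program
  (50 sires / 500 dams, 60 cycles, four selection criteria: random,
  phenotypic, pedigree BLUP, genomic BLUP);
* inbreeding estimators: true autozygosity `F_TRUE`, Wright's pedigree
  `F_PED` (Meuwissen–Luo recursion), VanRaden GRM diagonal `F_GRM`
  (G = ZZ′/2Σp(1−p), fixed-0.5 or known base frequencies), and ROH-based
  `F_ROH`;
* two ROH detectors: a longest-first scan with a genotyping-error
  heterozygote allowance, and a PLINK-style fixed sliding window;
* a replicate runner producing estimator-vs-truth tables, correlations,
  ROH length distributions and significance letter groupings;
* PLINK `.ped/.map` and `.bed/.bim/.fam` I/O, plus a synthetic
  Holstein-like panel generator with birth years and a two-slope
  inbreeding trend around a changepoint year, with per-year trend fitting.

The intended audience is quantitative geneticists and breeding-program
analysts who want to benchmark inbreeding estimators or ROH detection
rules under a known truth.

## Worked example

```python
import numpy as np
from rohsim import SimConfig, run_simulation, ROHParams, detect_roh_shrink
from rohsim import inbreeding as ib

cfg = SimConfig(n_sires=20, n_dams=100, n_cycles=12, n_chrom=10,
                total_cm=1000.0, n_snp=20_000, n_qtl=200,
                selection="random", snapshot_cycles=(12,))
res = run_simulation(cfg, rng=np.random.default_rng(7))
snap = res.snapshots[12]
idx = snap.animal_index

seg = detect_roh_shrink(snap.dose, res.genome.snp_chrom, res.genome.snp_bp,
                        ROHParams(min_window_snp=20), animal_ids=idx)
f_roh = ib.f_roh(seg, idx, res.genome.n_snp)
print(f"F_TRUE {res.f_true[idx].mean():.4f}  F_PED {res.f_ped[idx].mean():.4f}  "
      f"F_ROH {f_roh.mean():.4f}")
print(f"corr(F_PED, F_TRUE) = {np.corrcoef(res.f_ped[idx], res.f_true[idx])[0,1]:.3f}")
```

prints (seed 7):

```
F_TRUE 0.0464  F_PED 0.0468  F_ROH 0.0466
corr(F_PED, F_TRUE) = 0.772
```

After 12 cycles of random mating in this small population, mean true
autozygosity is ~4.6%.  All three measures agree on the cohort mean, but
pedigree F correlates only ~0.77 with individual truth — it is an
expectation that cannot see Mendelian sampling — while the 20-SNP ROH rule
recovers the realized autozygosity almost exactly at this density.  `examples/` contains five
runnable scripts covering gene dropping, the estimator suite, ROH
detection, selection-regime comparison and the synthetic Holstein-like
panel.

A thin command line mirrors the library:

```sh
rohsim simulate --selection blup --cycles 60 --replicates 1 --seed 1 --out out/
rohsim roh --panel out/rep0_gen60 --min-snp 20 --out segments.tsv
rohsim kinship --panel out/rep0_gen60 --out inbreeding.csv
rohsim report --selection random --replicates 5 --seed 1 --out tables/
```

## Layout

```
src/rohsim/
  genome_sim.py   genome map, QTL effects, founder alleles, recoding
  gene_drop.py    meiosis and Mendelian transmission of allele labels
  breeding.py     breeding program, BLUP / GBLUP solvers
  inbreeding.py   F_TRUE, F_PED, F_GRM, F_ROH
  roh_detect.py   ROH detectors and summaries
  experiment.py   replicate runner, tables, correlations, letter groups
  panel_io.py     PLINK I/O, synthetic panel fixture, trend reports
  cli.py          thin command line over the above
docs/methods.md   model, assumptions, parameter choices, limitations
examples/         one narrative script per capability
```
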