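# Methods

## The problem

Inbreeding is the probability (pedigree view) or realized fraction (genomic
view) of an individual's genome at which the two homologous copies descend
from a single ancestral copy — autozygosity.  In practice autozygosity is
estimated: from pedigrees (Wright's F), from a genomic relationship matrix
(GRM diagonal), or from runs of homozygosity (ROH).  `rohsim` simulates
closed breeding populations in which *true* autozygosity is known exactly,
so estimators can be benchmarked against truth, and applies the same ROH
machinery to real-format SNP panels to measure inbreeding trends over time.

## Gene dropping and the truth layer

Every founder carries two uniquely numbered alleles at every locus
(`genome_sim.assign_founder_alleles`).  Meiosis transmits these labels under
a Haldane model: per chromosome the crossover count is Poisson(L/100) for
map length L in cM, crossover positions are uniform, the starting haplotype
is Bernoulli(0.5), there is no interference and no mutation.  A descendant
locus where both labels coincide is autozygous by construction; `f_true` is
the fraction of panel SNPs at which this holds.  Observed genotypes are
produced by a recode map that assigns each founder allele code "1" or "2"
per locus — once, so recoding is a pure function of (locus, id):

* `fixed_half` — each allele coded 1 with probability 0.5 (base allele
  frequencies ≈ 0.5);
* `uniform_0_to_half` — a per-locus target p ~ U(0, 0.5) first, then each
  allele coded 1 with probability p (uniform base frequencies; some loci
  monomorphic; no MAF filter is applied).

The realized founder frequency of code 1 is recorded as the locus's "known
base frequency" for the GRM.

### Genome defaults

29 autosomes, 2496 cM total, 54,000 SNPs and 750 QTL placed uniformly at
random, 1 cM ≡ 1 Mb everywhere.  Chromosome lengths follow the real cattle
autosome size spectrum (ARS-UCD physical sizes rescaled to the configured
total); pass `chrom_length_cm` for any other layout.  QTL effects are
Gamma(0.4) magnitudes with random sign, one effect per founder QTL allele
(`max_alleles` caps the allelic diversity if desired), jointly rescaled so
founder breeding-value variance equals h²·Vp = 0.3.

## Breeding program

Defaults reproduce a closed nucleus: 50 sires, 500 dams, 60 overlapping
cycles; each dam produces two progeny per cycle (sex Bernoulli(0.5)) by an
independently drawn random sire (`mating="balanced"` assigns each sire an
equal number of randomly chosen dams instead).  All
animals are phenotyped at birth (y = TBV + N(0, 0.7); the trait is not
sex-limited).  Each cycle 25 sires and 150 dams are culled **oldest-first**
(ties by selection score) and replaced by the top-ranked offspring of the
matching sex under the configured criterion:

* `random` — iid uniform scores;
* `phenotype` — own record;
* `blup_ebv` — animal-model BLUP via Henderson's MME with a sparse,
  inbreeding-adjusted A-inverse, re-estimated each cycle on all records
  (preconditioned CG, relative residual 1e-8, warm-started);
* `gblup_gebv` — GBLUP with a VanRaden GRM built from the observed allele
  frequencies of a rolling reference (cohorts of the last 3 cycles), solved
  in marker space, which is algebraically identical to the G-space solve
  and much cheaper when markers < reference animals.

Oldest-first culling is the default because it makes parental tenure
deterministic (sires two cycles, dams ~3.3), giving a generation interval
of ≈1.8 cycles; rank-based and fresh-random culling are available
(`culling="rank" | "random"`) but produce materially slower inbreeding
accumulation than the default at these population sizes.

## Inbreeding measures

* `f_true` — autozygous fraction of SNP loci, from the truth layer (QTL
  excluded; the panel is the measuring device).
* `f_ped` — Wright's coefficient by the Meuwissen–Luo recursion; exact,
  incremental (only new animals are processed as a pedigree grows), and
  equal to the tabular-method A diagonal minus one.
* `f_grm` — G = ZZ′/2Σp(1−p) with Z the dose matrix centered by 2p;
  F = G_ii − 1.  Under `fixed_0.5` every locus contributes 0.5 to the
  denominator, monomorphic or not; under `known_base` the realized founder
  frequencies are used and base-monomorphic loci drop out of numerator and
  denominator.  F_GRM may be negative or exceed 1.
* `f_roh` — summed SNP counts of detected segments divided by panel size.

## ROH detection

**Longest-first scan** (`detect_roh_shrink`): enumerate every maximal
homozygote-bounded stretch tolerating at most ⌊n_snp·e⌋ embedded
heterozygous calls (e = assumed genotyping error rate, default 0.001 —
so no heterozygote is tolerated below 1000 called SNPs), accept candidates
longest-first so segments never overlap, then filter by minimum SNP count
(5/20/35/50) and minimum span (window × 50 kb: 0.25/1/1.75/2.5 Mb).  The
implementation is verified against an exhaustive O(L²) enumeration oracle
on hundreds of random instances.

Two deliberate interpretation choices, made because the reference tool's
internals are unpublished:

1. *Error allowance* is ⌊n·e⌋ per segment (`error_allowance="floor"`); a
   `"ceil"` variant (≥1 heterozygote tolerated at any length) exists but
   triples short-window chance detections and is not the default.
2. *The marker-density requirement* (1 SNP per 50 kb) is treated as a
   property the panel must satisfy globally, not a per-segment filter: at
   the default panel's own mean spacing (46 kb/SNP) a binding per-segment
   average-density rule discards half of the genuine long segments and
   depresses F_ROH by ~13%.  A per-segment filter is available via
   `density_kb_per_snp`.

With these defaults, window-20 F_ROH reproduces true inbreeding at
generation 60 (0.091 vs 0.093 in a full-density replicate) and window-5
F_ROH shows the expected chance-homozygosity inflation at generation 10
(0.052 vs truth 0.014).

**Fixed sliding window** (`detect_roh_sliding`): per-SNP hit fractions over
all windows containing the SNP (window passes with ≤1 heterozygote and ≤5
missing calls), eligibility at hit fraction ≥ 0.05, maximal eligible runs
split at gaps >1000 kb and reported at ≥window SNPs, ≥1000 kb and ≤50
kb/SNP (the published defaults of that tool family).  As published, this
variant runs slightly below truth (0.082 vs 0.091 at generation 60).

Known limitation: the reference shrinking-window tool reports fewer,
longer segments than this formulation (30.4 × 163.2 SNP vs ~51 × ~96 SNP
per animal at generation 60 under random selection) at identical total
coverage.  No allowance rule consistent with e = 0.001 merges segments
across heterozygote-rich non-autozygous gaps, so segment-count and
mean-length statistics from this package are finer-grained than that
tool's; coverage-level quantities (F_ROH, length classes by Mb, trends)
are unaffected.

## Replicates and statistics

`experiment.run_replicates` runs the full pipeline per replicate (seed =
base + index), summarizes every cohort (truth and pedigree measures each
cycle; genomic and ROH measures at snapshot cycles), and aggregates
mean ± SE across replicates.  Estimator correlations are computed within
the snapshot cohort (the 1000 offspring born that cycle) per replicate and
averaged; pooled-across-replicate correlations can be formed from the
per-animal tables.  Significance letters for group comparisons use
all-pairs Welch t-tests with Holm correction (Tukey HSD by flag) and an
insert-absorb compact letter display.

## Synthetic genotype panel with a trend changepoint

`panel_io.generate_panel_fixture` emulates a medium-density cattle panel
(default 44,369 SNPs, 29 autosomes, uniform base frequencies) with yearly
cohorts whose mean inbreeding follows a two-slope line around a
changepoint year.  The trend is created through the mating design: for
each offspring a set of candidate sire/dam pairs from the recent parent
pool is screened, and the mating is randomized between the pairs whose
pedigree kinship brackets the year's target so the cohort mean matches it
in expectation.  Founder alleles are then gene-dropped through this
pedigree and ROH-based inbreeding is measured per animal.

What the fixture does and does not emulate: it reproduces cohort structure,
panel density, a realistic right-skewed ROH length distribution and a
controllable trend; it does not model genotyping error, missingness,
imputation, selection on a trait, or real linkage-disequilibrium structure.
Passing trend-recovery tests therefore demonstrates the estimator pipeline,
not field performance on noisy data.  Two further limits: kinship is
quantized (0, 1/8, 1/4...), so very shallow targets are met only in cohort
expectation; and background drift in the finite parent pool puts a floor
under the achievable slope (a flat trend needs a pool large enough that
drift per year stays below the trend resolution).

## Problem sizes used in the test and acceptance runs

Autozygosity fractions and pedigree/truth correlations are locus-sampling
quantities, insensitive to panel density, so those runs use 5,400 SNPs
(truth-only regimes) or 2,000 SNPs (genomic-selection regimes, where the
panel also feeds the GRM predictor).  SNP-denominated ROH statistics are
density-dependent and run at the full 54,000-SNP panel (one replicate).
Replicates: 5 (random), 2–3 (selective regimes), 1 (full density); the
full-scale study design corresponds to 20 replicates at 54k throughout.

## Numerical notes

* RNG: a single `numpy` Generator per replicate; replicate seeds are
  base + index; all simulation stages consume from the same stream in a
  fixed order, so runs are bit-reproducible.
* Selection and culling ties break deterministically (lowest id).
* MME solves use Jacobi-preconditioned CG on the symmetric positive
  definite system; the GRM-space GBLUP route adds a 1e-6 ridge only if the
  phenotypic covariance factorization fails (it cannot at σe² > 0).
* Positions are forced strictly increasing within chromosomes at bp
  resolution by redrawing collisions; bp = round(cM × 1e6).
* Segment spans are 1-based inclusive; f_roh validates that segments per
  animal/chromosome are disjoint before summing.
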