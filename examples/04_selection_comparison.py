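"""Effect of the selection criterion on inbreeding accumulation.

Runs the breeding program at reduced scale under random, phenotypic and
BLUP selection (2 replicates each) and prints the per-generation mean true
inbreeding.  Family-information-based selection (BLUP) inbreeds fastest;
random selection slowest — the ordering reported for full-scale runs.
"""

import numpy as np

from rohsim.breeding import SimConfig, run_simulation

GENS = (4, 8, 12)
print(f"{'selection':12s}" + "".join(f"  gen{g:>2d}" for g in GENS))
for sel in ("random", "phenotype", "blup_ebv"):
    means = np.zeros(len(GENS))
    for rep in range(2):
        cfg = SimConfig(
            n_sires=15, n_dams=75, n_cycles=12, n_chrom=10, total_cm=1000.0,
            n_snp=5000, n_qtl=200, selection=sel, snapshot_cycles=(),
        )
        res = run_simulation(cfg, rng=np.random.default_rng(10 + rep))
        means += [res.f_true[res.cohort(g)].mean() for g in GENS]
    means /= 2
    print(f"{sel:12s}" + "".join(f"  {m:.3f}" for m in means))
print("\nMean F_TRUE per cohort (2 replicates). BLUP co-selects relatives and")
print("accumulates autozygosity fastest; random mating sets the drift baseline.")
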