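"""Shared fixtures.

The expensive session fixtures run the full-size breeding program once per
selection regime and are shared by the acceptance tests; unit tests use the
small toy objects.  Problem sizes: truth-layer runs use a 5,400-SNP panel
(autozygosity fractions are insensitive to panel density), genomic-selection
runs a 2,000-SNP panel, and the ROH-statistics run the full 54,000-SNP panel
where SNP-length statistics depend on marker density.
"""

from __future__ import annotations

import numpy as np
import pytest

from rohsim import genome_sim
from rohsim.breeding import SimConfig, run_simulation


@pytest.fixture(scope="session")
def toy_genome():
    return genome_sim.build_genome(3, 300.0, 400, 20, rng=7)


@pytest.fixture(scope="session")
def toy_layer(toy_genome):
    layer = genome_sim.assign_founder_alleles(12, toy_genome.n_loci, rng=8)
    genome_sim.recode_alleles(layer, "fixed_half", rng=9, snp_locus_idx=toy_genome.snp_locus_idx)
    return layer


def _run(selection, n_snp, seed, snapshots=(), scenario="fixed_half"):
    cfg = SimConfig(
        selection=selection, scenario=scenario, n_snp=n_snp, n_qtl=750,
        snapshot_cycles=snapshots,
    )
    return run_simulation(cfg, rng=np.random.default_rng(seed))


@pytest.fixture(scope="session")
def random_runs():
    """Five random-selection replicates at 5,400 SNPs (truth measures only)."""
    return [_run("random", 5400, 100 + r) for r in range(5)]


@pytest.fixture(scope="session")
def random_full_density_run():
    """One random-selection replicate at the full 54,000-SNP density.

    Snapshots at generations 10 and 60 provide genotypes for ROH detection
    at the short (5-SNP) and standard (20-SNP) window sizes.
    """
    return _run("random", 54_000, 150, snapshots=(10, 60))


@pytest.fixture(scope="session")
def phenotype_runs():
    """Two phenotypic-selection replicates at 5,400 SNPs."""
    return [_run("phenotype", 5400, 200 + r) for r in range(2)]


@pytest.fixture(scope="session")
def gblup_runs():
    """Two GBLUP-selection replicates at 2,000 SNPs."""
    return [_run("gblup_gebv", 2000, 300 + r) for r in range(2)]


@pytest.fixture(scope="session")
def blup_run():
    """One BLUP-selection replicate at 2,000 SNPs."""
    return _run("blup_ebv", 2000, 400)


@pytest.fixture(scope="session")
def uniform_phenotype_run():
    """Phenotypic selection under the uniform base-allele-frequency scenario."""
    return _run("phenotype", 5400, 500, snapshots=(60,), scenario="uniform_0_to_half")
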