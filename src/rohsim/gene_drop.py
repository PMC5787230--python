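"""Gene dropping: Mendelian transmission of founder allele ids with recombination.

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson(length_cm / 100), crossover positions are uniform on the cM map and
the starting haplotype is Bernoulli(0.5); there is no interference and no
mutation.  Because founder alleles are uniquely numbered, the dropped ids are
an exact record of identity by descent in every descendant.

The batch routines are vectorized over offspring; `meiosis` and
`drop_generation` provide the single-animal / explicit-mating API on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_sim import GenomeMap

__all__ = ["HaplotypeSet", "meiosis", "drop_generation", "gamete_batch", "drop_offspring"]


@dataclass
class HaplotypeSet:
    """Founder-allele-id haplotypes for a set of animals.

    ``ids`` has shape (n_animals, 2, n_loci) over the genome's merged locus
    order; ``animal_ids`` are the pedigree ids of the rows.
    """

    animal_ids: np.ndarray
    ids: np.ndarray

    @property
    def n_animals(self) -> int:
        return self.ids.shape[0]

    def row_of(self, animal_id: int) -> int:
        idx = np.flatnonzero(self.animal_ids == animal_id)
        if len(idx) == 0:
            raise KeyError(f"animal {animal_id} not in haplotype set")
        return int(idx[0])


def gamete_batch(
    parent_hap: np.ndarray,
    pos_cm: np.ndarray,
    length_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row of ``parent_hap`` for a single chromosome.

    Parameters
    ----------
    parent_hap : (n, 2, L) parent haplotypes (already gathered per offspring).
    pos_cm : (L,) locus positions on this chromosome.
    length_cm : chromosome map length in cM.

    Returns
    -------
    (n, L) array of transmitted allele ids.
    """
    n, _, L = parent_hap.shape
    n_x = rng.poisson(length_cm / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    kmax = int(n_x.max()) if n else 0
    if kmax == 0:
        return parent_hap[np.arange(n), start]
    xpos = rng.uniform(0.0, length_cm, size=(n, kmax))
    # pad unused crossover slots beyond each gamete's count to +inf
    xpos[np.arange(kmax)[None, :] >= n_x[:, None]] = np.inf
    # crossovers strictly before a locus flip the active haplotype there
    n_before = (xpos[:, :, None] < pos_cm[None, None, :]).sum(axis=1)
    hap = (start[:, None] + n_before) % 2
    return np.take_along_axis(parent_hap, hap[:, None, :], axis=1)[:, 0, :]


def drop_offspring(
    parent_ids: np.ndarray,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    genome: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce offspring haplotypes from a parent haplotype store.

    ``parent_ids`` is the (n_parents, 2, n_loci) store; ``sire_rows`` /
    ``dam_rows`` give, per offspring, the store row of its sire and dam.
    Offspring haplotype 0 is the paternal gamete, haplotype 1 the maternal.
    Only the parent store and one offspring cohort are resident at a time.
    """
    n = len(sire_rows)
    out = np.empty((n, 2, genome.n_loci), dtype=parent_ids.dtype)
    P_s = parent_ids[sire_rows]  # one gather per parent role, sliced per chromosome
    P_d = parent_ids[dam_rows]
    for c in range(1, genome.n_chrom + 1):
        sl = genome.chrom_locus_slice(c)
        pos = genome.loci_cm[sl]
        length = float(genome.chrom_length_cm[c - 1])
        out[:, 0, sl] = gamete_batch(P_s[:, :, sl], pos, length, rng)
        out[:, 1, sl] = gamete_batch(P_d[:, :, sl], pos, length, rng)
    return out


def meiosis(
    parent: np.ndarray, genome: GenomeMap, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Single meiosis: one gamete (id vector over all loci) from a (2, L) parent."""
    rng = np.random.default_rng(rng)
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2 or parent.shape[1] != genome.n_loci:
        raise ValueError("parent must have shape (2, n_loci)")
    out = np.empty(genome.n_loci, dtype=parent.dtype)
    for c in range(1, genome.n_chrom + 1):
        sl = genome.chrom_locus_slice(c)
        out[sl] = gamete_batch(
            parent[None, :, sl], genome.loci_cm[sl],
            float(genome.chrom_length_cm[c - 1]), rng,
        )[0]
    return out


def drop_generation(
    parents: HaplotypeSet,
    matings: list[tuple[int, int, int]],
    genome: GenomeMap,
    rng: np.random.Generator | int | None = None,
) -> HaplotypeSet:
    """Drop alleles from ``parents`` to offspring of the requested matings.

    ``matings`` is a list of ``(sire_id, dam_id, n_offspring)``.  Offspring
    animal ids are assigned sequentially after the largest parent id.  Raises
    ``KeyError`` if a mating references an animal absent from ``parents``.
    """
    rng = np.random.default_rng(rng)
    sire_rows, dam_rows = [], []
    for sire, dam, k in matings:
        s, d = parents.row_of(sire), parents.row_of(dam)
        sire_rows.extend([s] * k)
        dam_rows.extend([d] * k)
    sire_rows = np.asarray(sire_rows, np.int64)
    dam_rows = np.asarray(dam_rows, np.int64)
    ids = drop_offspring(parents.ids, sire_rows, dam_rows, genome, rng)
    next_id = int(parents.animal_ids.max()) + 1
    return HaplotypeSet(
        animal_ids=np.arange(next_id, next_id + len(sire_rows)), ids=ids
    )
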