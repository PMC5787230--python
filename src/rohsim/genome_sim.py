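"""Simulated genome construction.

Builds the genetic map (SNP and QTL placement on a multi-chromosome cM map),
samples additive QTL effects, and sets up the founder allele layer used for
gene dropping: every founder carries two uniquely numbered alleles at every
locus, so identity by descent can be read off directly in any descendant.
A recode map collapses the unique founder alleles to bi-allelic SNP codes
("1"/"2") under one of two base-frequency scenarios.

Conventions
-----------
* 1 cM == 1 Mb throughout; base-pair positions are ``round(pos_cm * 1e6)``.
* Loci are stored genome-wide in (chromosome, position) order.  SNPs and QTL
  are independent sets; positions may coincide.
* Allele ids are 1-based integers ``1..2*n_founders``; id 0 is never used.
* SNP codes are 1 and 2; genotype dose counts copies of allele "1".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "QTLEffectTable",
    "FounderAlleleLayer",
    "build_genome",
    "sample_qtl_effects",
    "assign_founder_alleles",
    "recode_alleles",
    "genotype_codes",
    "true_breeding_values",
]

SCENARIOS = ("fixed_half", "uniform_0_to_half")

#: Relative lengths of the 29 cattle autosomes (approximate physical sizes in
#: Mb, ARS-UCD assembly order BTA1..BTA29).  Under the 1 cM == 1 Mb convention
#: these are rescaled to the configured total map length, so the simulated
#: genome has a realistic chromosome-size spectrum instead of 29 equal pieces.
CATTLE_CHROM_MB = np.array(
    [158, 136, 121, 120, 120, 118, 110, 113, 105, 104, 107, 91, 84, 84, 85,
     81, 75, 66, 64, 72, 70, 61, 52, 62, 43, 52, 45, 46, 51], float
)


@dataclass
class GenomeMap:
    """Genetic map holding chromosome lengths and ordered SNP/QTL positions.

    All positional arrays are genome-wide and sorted by (chromosome, cM).
    ``snp_of_locus`` / ``qtl_of_locus`` map the merged locus order used by the
    gene dropper back to SNP / QTL indices.
    """

    n_chrom: int
    chrom_length_cm: np.ndarray  # (n_chrom,)
    snp_chrom: np.ndarray        # (n_snp,) 1-based chromosome codes
    snp_cm: np.ndarray           # (n_snp,) position within chromosome, cM
    snp_bp: np.ndarray           # (n_snp,) int64, 1 cM == 1 Mb
    qtl_chrom: np.ndarray
    qtl_cm: np.ndarray
    # merged locus order (SNP + QTL interleaved by position), built in __post_init__
    loci_chrom: np.ndarray = field(init=False)
    loci_cm: np.ndarray = field(init=False)
    snp_locus_idx: np.ndarray = field(init=False)  # locus index of each SNP
    qtl_locus_idx: np.ndarray = field(init=False)  # locus index of each QTL

    def __post_init__(self) -> None:
        is_snp = np.concatenate(
            [np.ones(len(self.snp_cm), bool), np.zeros(len(self.qtl_cm), bool)]
        )
        chrom = np.concatenate([self.snp_chrom, self.qtl_chrom])
        cm = np.concatenate([self.snp_cm, self.qtl_cm])
        # stable sort keeps SNP before QTL at identical positions
        order = np.lexsort((~is_snp, cm, chrom))
        self.loci_chrom = chrom[order]
        self.loci_cm = cm[order]
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        self.snp_locus_idx = inv[: len(self.snp_cm)]
        self.qtl_locus_idx = inv[len(self.snp_cm):]

    @property
    def n_snp(self) -> int:
        return len(self.snp_cm)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_cm)

    @property
    def n_loci(self) -> int:
        return len(self.loci_cm)

    @property
    def total_cm(self) -> float:
        return float(self.chrom_length_cm.sum())

    def chrom_locus_slice(self, c: int) -> slice:
        """Slice of the merged locus arrays belonging to chromosome ``c`` (1-based)."""
        lo, hi = np.searchsorted(self.loci_chrom, [c, c + 1])
        return slice(int(lo), int(hi))

    def chrom_snp_slice(self, c: int) -> slice:
        lo, hi = np.searchsorted(self.snp_chrom, [c, c + 1])
        return slice(int(lo), int(hi))

    def to_map_table(self) -> pd.DataFrame:
        """SNP map as the standard PLINK .map/.bim column layout."""
        return pd.DataFrame(
            {
                "chrom": self.snp_chrom,
                "snp_id": [f"snp{i + 1}" for i in range(self.n_snp)],
                "cm": self.snp_cm,
                "bp": self.snp_bp,
            }
        )


@dataclass
class QTLEffectTable:
    """Signed additive effect for every (QTL locus, founder allele id).

    ``effect[q, a]`` is the effect of founder allele id ``a`` (1-based; column 0
    unused) at QTL ``q``.  Magnitudes are gamma draws with ``gamma_shape``,
    signs are Bernoulli(0.5), and all effects share one ``scale_factor`` chosen
    so the founder-population variance of true breeding values hits the target
    additive variance.
    """

    effect: np.ndarray       # (n_qtl, 2*n_founders + 1) float64
    gamma_shape: float
    scale_factor: float


@dataclass
class FounderAlleleLayer:
    """Unique founder allele ids per locus plus the SNP recode map.

    ``allele_ids`` has shape (n_founders, 2, n_loci) over the merged locus
    order of the genome map.  ``recode_map`` has shape (n_snp, 2N+1) with
    values 1/2 (column 0 unused); ``base_freq`` is the realized founder
    frequency of allele "1" at each SNP, which is the "known base frequency"
    used by the genomic relationship matrix.
    """

    allele_ids: np.ndarray
    n_founders: int
    recode_map: np.ndarray | None = None
    scenario: str | None = None
    target_freq: np.ndarray | None = None
    base_freq: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return self.allele_ids.shape[2]


def _place_loci(n: int, chrom_length_cm: np.ndarray, rng: np.random.Generator):
    """Place ``n`` loci uniformly over the concatenated map, sorted per chromosome.

    Positions are forced to be strictly increasing within a chromosome by
    redrawing any collisions at bp resolution.
    """
    n_chrom = len(chrom_length_cm)
    cum = np.concatenate([[0.0], np.cumsum(chrom_length_cm)])
    total = cum[-1]
    pos = rng.uniform(0.0, total, n)
    chrom = np.searchsorted(cum, pos, side="right").astype(np.int32)
    chrom = np.clip(chrom, 1, n_chrom)
    cm = pos - cum[chrom - 1]
    order = np.lexsort((cm, chrom))
    chrom, cm = chrom[order], cm[order]
    # enforce strict increase at bp resolution (duplicates possible after rounding)
    for _ in range(100):
        bp = np.round(cm * 1e6).astype(np.int64)
        dup = np.zeros(n, bool)
        if n > 1:
            dup[1:] = (chrom[1:] == chrom[:-1]) & (bp[1:] <= bp[:-1])
        if not dup.any():
            break
        cm[dup] = rng.uniform(0.0, chrom_length_cm[chrom[dup] - 1])
        order = np.lexsort((cm, chrom))
        chrom, cm = chrom[order], cm[order]
    else:  # pragma: no cover - essentially impossible at sane densities
        raise RuntimeError("could not place loci at distinct bp positions")
    return chrom, cm, bp


def build_genome(
    n_chrom: int = 29,
    total_cm: float = 2496.0,
    n_snp: int = 54_000,
    n_qtl: int = 750,
    rng: np.random.Generator | int | None = None,
    chrom_length_cm: np.ndarray | None = None,
) -> GenomeMap:
    """Build a genome map with uniformly placed SNPs and QTL.

    Parameters
    ----------
    n_chrom, total_cm
        Number of autosomes and total map length.  Chromosomes are equal
        length unless ``chrom_length_cm`` is given explicitly.
    n_snp, n_qtl
        Panel sizes; SNP and QTL positions are drawn independently.
    rng
        ``numpy.random.Generator`` or seed.
    """
    if n_chrom < 1 or total_cm <= 0 or n_snp < 2 or n_qtl < 0:
        raise ValueError("invalid genome configuration")
    rng = np.random.default_rng(rng)
    if chrom_length_cm is None:
        if n_chrom == len(CATTLE_CHROM_MB):
            rel = CATTLE_CHROM_MB
        else:
            rel = np.ones(n_chrom)
        chrom_length_cm = rel * (total_cm / rel.sum())
    else:
        chrom_length_cm = np.asarray(chrom_length_cm, float)
        if len(chrom_length_cm) != n_chrom:
            raise ValueError("chrom_length_cm length mismatch")
        if not np.isclose(chrom_length_cm.sum(), total_cm):
            raise ValueError("chromosome lengths must sum to total_cm")
    snp_chrom, snp_cm, snp_bp = _place_loci(n_snp, chrom_length_cm, rng)
    if n_qtl > 0:
        qtl_chrom, qtl_cm, _ = _place_loci(n_qtl, chrom_length_cm, rng)
    else:
        qtl_chrom = np.empty(0, np.int32)
        qtl_cm = np.empty(0, float)
    return GenomeMap(
        n_chrom=n_chrom,
        chrom_length_cm=chrom_length_cm,
        snp_chrom=snp_chrom,
        snp_cm=snp_cm,
        snp_bp=snp_bp,
        qtl_chrom=qtl_chrom,
        qtl_cm=qtl_cm,
    )


def assign_founder_alleles(
    n_founders: int, n_loci: int, rng: np.random.Generator | int | None = None
) -> FounderAlleleLayer:
    """Assign ids ``1..2*n_founders`` at every locus, two per founder.

    Per locus the ids are a random permutation, so every id occurs exactly
    once across founder haplotypes and every founder is heterozygous (ids
    differ) at every locus: founders have zero autozygosity by construction.
    """
    if n_founders < 1 or n_loci < 1:
        raise ValueError("n_founders and n_loci must be positive")
    rng = np.random.default_rng(rng)
    n_alleles = 2 * n_founders
    dtype = np.int16 if n_alleles < 2**15 else np.int32
    ids = np.empty((n_loci, n_alleles), dtype)
    base = np.arange(1, n_alleles + 1, dtype=dtype)
    for loc in range(n_loci):
        ids[loc] = rng.permutation(base)
    # (n_loci, 2N) -> (N, 2, n_loci): haplotype h of founder f gets column 2f+h
    allele_ids = ids.reshape(n_loci, n_founders, 2).transpose(1, 2, 0).copy()
    return FounderAlleleLayer(allele_ids=allele_ids, n_founders=n_founders)


def recode_alleles(
    layer: FounderAlleleLayer,
    scenario: str,
    rng: np.random.Generator | int | None = None,
    snp_locus_idx: np.ndarray | None = None,
) -> FounderAlleleLayer:
    """Attach a bi-allelic recode map for SNP loci to a founder layer.

    Every founder allele id is independently mapped to code 1 with probability
    ``p`` (and 2 otherwise), where ``p = 0.5`` under ``fixed_half`` or a
    per-locus draw from U(0, 0.5) under ``uniform_0_to_half``.  The realized
    frequency of code 1 among the 2N founder alleles is recorded as the true
    base frequency of the locus.  Recoding is a pure function of (locus, id).

    ``snp_locus_idx`` selects which merged-locus columns are SNPs (defaults to
    all loci, i.e. a SNP-only layer).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(rng)
    if snp_locus_idx is None:
        snp_locus_idx = np.arange(layer.n_loci)
    n_snp = len(snp_locus_idx)
    n_alleles = 2 * layer.n_founders
    if scenario == "fixed_half":
        target = np.full(n_snp, 0.5)
    else:
        target = rng.uniform(0.0, 0.5, n_snp)
    u = rng.random((n_snp, n_alleles))
    codes = np.where(u < target[:, None], 1, 2).astype(np.uint8)
    recode = np.empty((n_snp, n_alleles + 1), np.uint8)
    recode[:, 0] = 0
    recode[:, 1:] = codes
    layer.recode_map = recode
    layer.scenario = scenario
    layer.target_freq = target
    layer.base_freq = (codes == 1).mean(axis=1)
    layer.snp_locus_idx = snp_locus_idx  # type: ignore[attr-defined]
    return layer


def genotype_codes(ids_snp: np.ndarray, recode_map: np.ndarray) -> np.ndarray:
    """Bi-allelic genotype dose from founder allele ids at SNP loci.

    Parameters
    ----------
    ids_snp : (n_animals, 2, n_snp) integer array of founder allele ids.
    recode_map : (n_snp, 2N+1) code table from :func:`recode_alleles`.

    Returns
    -------
    dose : (n_animals, n_snp) int8, number of copies of allele "1" (0/1/2).
    """
    n_snp = ids_snp.shape[2]
    cols = np.arange(n_snp)
    c0 = recode_map[cols[None, :], ids_snp[:, 0, :]]
    c1 = recode_map[cols[None, :], ids_snp[:, 1, :]]
    return ((c0 == 1).astype(np.int8) + (c1 == 1).astype(np.int8))


def true_breeding_values(
    ids_qtl: np.ndarray, effects: QTLEffectTable
) -> np.ndarray:
    """Sum of QTL allele effects per animal (``ids_qtl``: (n, 2, n_qtl))."""
    n_qtl = ids_qtl.shape[2]
    rows = np.arange(n_qtl)
    e = effects.effect
    return (
        e[rows[None, :], ids_qtl[:, 0, :]].sum(axis=1)
        + e[rows[None, :], ids_qtl[:, 1, :]].sum(axis=1)
    )


def sample_qtl_effects(
    n_qtl: int,
    n_founder_alleles: int,
    founder_ids_qtl: np.ndarray,
    gamma_shape: float = 0.4,
    sigma_a_target: float = 0.3,
    rng: np.random.Generator | int | None = None,
    max_alleles: int | None = None,
) -> QTLEffectTable:
    """Sample signed gamma QTL effects and normalize to a target additive variance.

    Effect magnitudes are Gamma(``gamma_shape``, 1) draws; signs are positive
    or negative with equal probability.  One common scale factor is applied so
    the empirical variance of founder true breeding values equals
    ``sigma_a_target``.

    ``max_alleles`` optionally caps the number of distinct effects per QTL:
    founder allele ids are folded onto ``id mod max_alleles`` effect classes,
    mimicking a lower-allelism QTL model.  Default: every founder allele id
    has its own effect (fully multi-allelic gene-dropping reading).
    """
    if gamma_shape <= 0 or sigma_a_target <= 0:
        raise ValueError("gamma_shape and sigma_a_target must be positive")
    if founder_ids_qtl.shape[0] == 0:
        raise ValueError("need at least one founder to normalize QTL effects")
    rng = np.random.default_rng(rng)
    raw = rng.gamma(gamma_shape, 1.0, size=(n_qtl, n_founder_alleles))
    sign = rng.choice([-1.0, 1.0], size=(n_qtl, n_founder_alleles))
    eff = np.zeros((n_qtl, n_founder_alleles + 1))
    eff[:, 1:] = raw * sign
    if max_alleles is not None and max_alleles < n_founder_alleles:
        folded = eff[:, 1 : max_alleles + 1]
        idx = (np.arange(n_founder_alleles) % max_alleles) + 1
        eff[:, 1:] = folded[:, idx - 1]
    table = QTLEffectTable(effect=eff, gamma_shape=gamma_shape, scale_factor=1.0)
    if n_qtl > 0:
        tbv = true_breeding_values(founder_ids_qtl, table)
        v = tbv.var()
        if v <= 0:
            raise ValueError("founder TBV variance is zero; cannot normalize")
        table.scale_factor = float(np.sqrt(sigma_a_target / v))
        table.effect = eff * table.scale_factor
    return table
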