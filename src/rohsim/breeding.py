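"""Overlapping-generation breeding simulation under four selection criteria.

The default configuration reproduces the study design this package targets:
a base population of 50 sires and 500 dams, 60 breeding cycles in which each
dam produces two progeny by a randomly drawn current sire, half the sires and
30% of the dams replaced each cycle by the top-ranked offspring of the
matching sex, and a single trait with h2 = 0.3 and phenotypic variance 1
(sigma_a^2 = 0.3, sigma_e^2 = 0.7).  Selection criteria:

* ``random`` — iid uniform scores (no selection pressure);
* ``phenotype`` — the animal's own record;
* ``blup_ebv`` — animal-model BLUP via Henderson's mixed-model equations with
  a sparse pedigree A-inverse, re-estimated each cycle on all records;
* ``gblup_gebv`` — genomic BLUP with a VanRaden relationship matrix built
  from a rolling reference window of recent cohorts (solved in marker space,
  which is algebraically identical).

Parent culling is oldest-first by default (ties broken by the selection
score), with rank-based culling available via ``culling="rank"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from . import gene_drop, genome_sim, inbreeding
from .genome_sim import FounderAlleleLayer, GenomeMap, QTLEffectTable

__all__ = [
    "SimConfig",
    "SimResult",
    "Snapshot",
    "run_simulation",
    "score_candidates",
    "blup_ebv",
    "gblup_gebv",
    "henderson_a_inverse",
]

CRITERIA = ("random", "phenotype", "blup_ebv", "gblup_gebv")


@dataclass
class SimConfig:
    """Breeding-program configuration (defaults = the study conditions)."""

    n_sires: int = 50
    n_dams: int = 500
    progeny_per_dam: int = 2
    sire_replacement: float = 0.5
    dam_replacement: float = 0.3
    n_cycles: int = 60
    h2: float = 0.3
    Vp: float = 1.0
    selection: str = "random"
    scenario: str = "fixed_half"
    snapshot_cycles: tuple[int, ...] = (5, 10, 20, 30, 40, 60)
    n_replicates: int = 20
    seed: int | None = None
    # genome scale
    n_chrom: int = 29
    total_cm: float = 2496.0
    n_snp: int = 54_000
    n_qtl: int = 750
    gamma_shape: float = 0.4
    # bookkeeping / solver details
    culling: str = "age"          # "age" (oldest first), "rank" (lowest score) or "random"
    mating: str = "random"        # "random" sire draw with replacement, or "balanced" even usage
    reference_window: int = 3     # GBLUP: cohorts of the last k cycles form the reference
    blup_tol: float = 1e-8

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.Vp

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.Vp

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_a2

    @property
    def k_sire_repl(self) -> int:
        return int(round(self.n_sires * self.sire_replacement))

    @property
    def k_dam_repl(self) -> int:
        return int(round(self.n_dams * self.dam_replacement))

    def validate(self) -> None:
        if self.selection not in CRITERIA:
            raise ValueError(f"unknown selection criterion {self.selection!r}")
        if self.culling not in ("age", "rank", "random"):
            raise ValueError("culling must be 'age', 'rank' or 'random'")
        if not set(self.snapshot_cycles) <= set(range(1, self.n_cycles + 1)):
            raise ValueError("snapshot cycles must lie in 1..n_cycles")
        if min(self.n_sires, self.n_dams, self.progeny_per_dam, self.n_cycles) < 1:
            raise ValueError("population sizes must be positive")


@dataclass
class Snapshot:
    """Genotypes of one offspring cohort (allele-"1" dose, 0/1/2)."""

    cycle: int
    animal_index: np.ndarray   # row indices into the per-animal result arrays
    dose: np.ndarray           # (n_cohort, n_snp) int8


@dataclass
class SimResult:
    """Full output of one simulation replicate."""

    config: SimConfig
    genome: GenomeMap
    layer: FounderAlleleLayer
    effects: QTLEffectTable
    sire: np.ndarray           # 0-based parent index, -1 for founders
    dam: np.ndarray
    sex: np.ndarray            # 0 male, 1 female
    birth: np.ndarray          # breeding cycle of birth (founders 0)
    tbv: np.ndarray
    phen: np.ndarray
    f_true: np.ndarray
    f_ped: np.ndarray
    snapshots: dict[int, Snapshot] = field(default_factory=dict)

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    def cohort(self, cycle: int) -> np.ndarray:
        """Row indices of the offspring cohort born in ``cycle``."""
        return np.flatnonzero(self.birth == cycle)

    def pedigree_frame(self) -> pd.DataFrame:
        """Pedigree as 1-based records (0 = unknown parent)."""
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n_animals + 1),
                "sire": self.sire + 1,
                "dam": self.dam + 1,
                "sex": np.where(self.sex == 0, "M", "F"),
                "birth_cycle": self.birth,
            }
        )


def henderson_a_inverse(
    sire: np.ndarray, dam: np.ndarray, F: np.ndarray | None = None
) -> scipy.sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix by Henderson's rules.

    With ``F`` given (pedigree inbreeding of all animals) the inbreeding-
    adjusted Mendelian sampling variances are used; with ``F=None`` the
    unadjusted variant (all F treated as 0) is built.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    n = len(sire)
    if F is None:
        F = np.zeros(n)
    fs = np.where(sire >= 0, F[np.clip(sire, 0, None)], 0.0)
    fd = np.where(dam >= 0, F[np.clip(dam, 0, None)], 0.0)
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & ~both
    one_d = (dam >= 0) & ~both
    d = np.full(n, 1.0)
    d[both] = 0.5 - 0.25 * (fs[both] + fd[both])
    d[one_s] = 0.75 - 0.25 * fs[one_s]
    d[one_d] = 0.75 - 0.25 * fd[one_d]
    alpha = 1.0 / d
    i = np.arange(n)
    rows, cols, vals = [i], [i], [alpha]
    for par in (sire, dam):
        m = par >= 0
        rows += [i[m], par[m]]
        cols += [par[m], i[m]]
        vals += [-0.5 * alpha[m], -0.5 * alpha[m]]
    for pa, pb in ((sire, sire), (dam, dam), (sire, dam), (dam, sire)):
        m = (pa >= 0) & (pb >= 0)
        rows.append(pa[m])
        cols.append(pb[m])
        vals.append(0.25 * alpha[m])
    A_inv = scipy.sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A_inv.tocsr()


def blup_ebv(
    sire: np.ndarray,
    dam: np.ndarray,
    phen: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    F: np.ndarray | None = None,
    use_inbreeding: bool = True,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Animal-model BLUP: overall mean plus one additive effect per animal.

    Solves Henderson's mixed-model equations

        [ X'X  X'Z          ] [mu]   [X'y]
        [ Z'X  Z'Z + lam*Ainv] [u ] = [Z'y]

    with X = 1, Z = incidence of records on animals, lam = sigma_e2/sigma_a2,
    by preconditioned conjugate gradients to a relative residual of ``tol``.
    Missing phenotypes (NaN) are allowed; animals without records are
    predicted through the pedigree.  Returns ``(mu_hat, ebv)``.
    """
    phen = np.asarray(phen, float)
    n = len(phen)
    has = ~np.isnan(phen)
    if not has.any():
        raise ValueError("no phenotype records: MME singular")
    if use_inbreeding and F is None:
        F = inbreeding.f_ped(sire, dam)
    A_inv = henderson_a_inverse(sire, dam, F if use_inbreeding else None)
    lam = sigma_e2 / sigma_a2
    y = np.where(has, phen, 0.0)
    rec = has.astype(float)
    # MME as a blocked sparse operator: unknowns [mu, u_0..u_{n-1}]
    C = scipy.sparse.bmat(
        [
            [scipy.sparse.csr_matrix(np.array([[rec.sum()]])), scipy.sparse.csr_matrix(rec[None, :])],
            [scipy.sparse.csr_matrix(rec[:, None]), scipy.sparse.diags(rec) + lam * A_inv],
        ],
        format="csr",
    )
    rhs = np.concatenate([[y.sum()], y])
    M = scipy.sparse.diags(1.0 / C.diagonal())
    x, info = scipy.sparse.linalg.cg(C, rhs, x0=x0, M=M, rtol=tol, atol=0.0, maxiter=20_000)
    if info != 0:
        raise RuntimeError(f"MME conjugate-gradient solve did not converge (info={info})")
    return float(x[0]), x[1:]


def gblup_gebv(
    ref_dose: np.ndarray,
    ref_phen: np.ndarray,
    cand_dose: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    method: str = "markers",
    ridge: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Genomic breeding values for candidates from a phenotyped reference set.

    Model: ``y = 1*mu + g + e`` with ``Var(g) = G*sigma_a2`` and G the
    VanRaden matrix built with the observed allele frequencies of the
    reference set.  ``method="markers"`` solves the equivalent SNP-BLUP ridge
    system in marker space (exactly the same predictions, much cheaper when
    markers < reference animals); ``method="grm"`` works in animal space via
    G directly (adding ``ridge`` to the phenotypic covariance diagonal only
    if the factorization fails).  Returns ``(mu_hat, gebv_candidates)``.
    """
    ref_dose = np.asarray(ref_dose, np.float64)
    cand_dose = np.asarray(cand_dose, np.float64)
    y = np.asarray(ref_phen, float)
    n, m = ref_dose.shape
    p = ref_dose.mean(axis=0) / 2.0
    kept = (p > 0.0) & (p < 1.0)
    if not kept.any():
        raise ValueError("all loci monomorphic in the reference; G undefined")
    Zr = ref_dose[:, kept] - 2.0 * p[kept]
    Zc = cand_dose[:, kept] - 2.0 * p[kept]
    k = float(2.0 * (p[kept] * (1.0 - p[kept])).sum())
    if method == "markers":
        mk = Zr.shape[1]
        lam = sigma_e2 * k / sigma_a2
        C = np.empty((mk + 1, mk + 1))
        C[0, 0] = n
        C[0, 1:] = Zr.sum(axis=0)
        C[1:, 0] = C[0, 1:]
        C[1:, 1:] = Zr.T @ Zr
        C[1:, 1:][np.diag_indices(mk)] += lam
        rhs = np.concatenate([[y.sum()], Zr.T @ y])
        sol = scipy.linalg.solve(C, rhs, assume_a="pos")
        return float(sol[0]), Zc @ sol[1:]
    if method == "grm":
        G_rr = (Zr @ Zr.T) / k
        G_cr = (Zc @ Zr.T) / k
        V = sigma_a2 * G_rr + sigma_e2 * np.eye(n)
        try:
            cf = scipy.linalg.cho_factor(V)
        except np.linalg.LinAlgError:  # pragma: no cover - V is PD in practice
            V[np.diag_indices(n)] += ridge
            cf = scipy.linalg.cho_factor(V)
        ones = np.ones(n)
        Vi_y = scipy.linalg.cho_solve(cf, y)
        Vi_1 = scipy.linalg.cho_solve(cf, ones)
        mu = float(ones @ Vi_y / (ones @ Vi_1))
        resid = scipy.linalg.cho_solve(cf, y - mu * ones)
        return mu, sigma_a2 * (G_cr @ resid)
    raise ValueError(f"unknown method {method!r}")


def score_candidates(
    criterion: str,
    candidates: np.ndarray,
    phen: np.ndarray,
    rng: np.random.Generator,
    ebv: np.ndarray | None = None,
    gebv: np.ndarray | None = None,
) -> np.ndarray:
    """Selection scores for candidate rows under the configured criterion.

    ``ebv`` / ``gebv`` must be supplied (full-length arrays) for the BLUP /
    GBLUP criteria; ``random`` draws fresh iid uniforms.
    """
    if criterion == "random":
        return rng.random(len(candidates))
    if criterion == "phenotype":
        return phen[candidates]
    if criterion == "blup_ebv":
        if ebv is None:
            raise ValueError("blup_ebv criterion requires ebv")
        return ebv[candidates]
    if criterion == "gblup_gebv":
        if gebv is None:
            raise ValueError("gblup_gebv criterion requires gebv")
        return gebv[candidates]
    raise ValueError(f"unknown selection criterion {criterion!r}")


class _ParentStore:
    """Fixed-slot haplotype (and optional dose) store for active parents."""

    def __init__(self, n_slots: int, n_loci: int, dtype, with_dose: bool, n_snp: int):
        self.hap = np.zeros((n_slots, 2, n_loci), dtype)
        self.dose = np.zeros((n_slots, n_snp), np.int8) if with_dose else None
        self.slot_of: dict[int, int] = {}
        self.free = list(range(n_slots))[::-1]

    def add(self, animal: int, hap: np.ndarray, dose: np.ndarray | None = None) -> None:
        slot = self.free.pop()
        self.slot_of[animal] = slot
        self.hap[slot] = hap
        if self.dose is not None and dose is not None:
            self.dose[slot] = dose

    def remove(self, animal: int) -> None:
        self.free.append(self.slot_of.pop(animal))

    def slots(self, animals: np.ndarray) -> np.ndarray:
        return np.array([self.slot_of[a] for a in animals], np.int64)


def _cull_order(ids, birth, scores, cycle, policy, rng):
    ids = np.asarray(ids)
    age = cycle - birth[ids]
    sc = scores[ids]
    if policy == "age":
        key = np.lexsort((ids, sc, -age))  # oldest first, then lowest score
    elif policy == "random":
        key = rng.permutation(len(ids))    # fresh uniform cull each cycle
    else:
        key = np.lexsort((ids, sc))        # lowest score first
    return ids[key]


def _select_top(cand_ids, scores, k):
    """Top-k candidate ids by score, ties broken by lowest id."""
    cand_ids = np.asarray(cand_ids)
    order = np.lexsort((cand_ids, -scores))
    return cand_ids[order[:k]]


def run_simulation(
    config: SimConfig,
    genome: GenomeMap | None = None,
    layer: FounderAlleleLayer | None = None,
    effects: QTLEffectTable | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimResult:
    """Run one replicate of the breeding program.

    Each cycle: mate every dam to one randomly drawn current sire (two
    progeny, sex Bernoulli(0.5)), phenotype the offspring at birth, score
    candidates by the configured criterion, replace the culled parents with
    the top-ranked offspring of each sex, and record a genotype snapshot at
    the scheduled cycles.  Genome, founder layer and QTL effects are built
    from the config when not supplied.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if genome is None:
        genome = genome_sim.build_genome(
            config.n_chrom, config.total_cm, config.n_snp, config.n_qtl, rng
        )
    n_founders = config.n_sires + config.n_dams
    if layer is None:
        layer = genome_sim.assign_founder_alleles(n_founders, genome.n_loci, rng)
        genome_sim.recode_alleles(layer, config.scenario, rng, genome.snp_locus_idx)
    if effects is None:
        effects = genome_sim.sample_qtl_effects(
            genome.n_qtl,
            2 * n_founders,
            layer.allele_ids[:, :, genome.qtl_locus_idx],
            config.gamma_shape,
            config.sigma_a2,
            rng,
        )
    n_total = n_founders + config.n_cycles * config.n_dams * config.progeny_per_dam
    sire = np.full(n_total, -1, np.int64)
    dam = np.full(n_total, -1, np.int64)
    sex = np.empty(n_total, np.int8)
    birth = np.zeros(n_total, np.int64)
    tbv = np.empty(n_total)
    phen = np.empty(n_total)
    ftrue = np.empty(n_total)
    scores = np.full(n_total, np.nan)

    sex[: config.n_sires] = 0
    sex[config.n_sires : n_founders] = 1
    snp_idx = genome.snp_locus_idx
    qtl_idx = genome.qtl_locus_idx
    f_ids = layer.allele_ids
    tbv[:n_founders] = genome_sim.true_breeding_values(f_ids[:, :, qtl_idx], effects)
    sig_e = np.sqrt(config.sigma_e2)
    phen[:n_founders] = tbv[:n_founders] + rng.normal(0.0, sig_e, n_founders)
    ftrue[:n_founders] = inbreeding.f_true(f_ids[:, :, snp_idx])
    scores[:n_founders] = rng.random(n_founders)

    need_dose = config.selection == "gblup_gebv"
    store = _ParentStore(n_founders, genome.n_loci, f_ids.dtype, need_dose, genome.n_snp)
    founder_dose = (
        genome_sim.genotype_codes(f_ids[:, :, snp_idx], layer.recode_map)
        if need_dose
        else None
    )
    for a in range(n_founders):
        store.add(a, f_ids[a], founder_dose[a] if need_dose else None)
    cur_sires = list(range(config.n_sires))
    cur_dams = list(range(config.n_sires, n_founders))

    ref_cohorts: list[tuple[int, np.ndarray, np.ndarray]] = []  # (cycle, dose, phen)
    if need_dose:
        ref_cohorts.append((0, founder_dose, phen[:n_founders].copy()))
    F_ped = inbreeding.f_ped(sire[:n_founders], dam[:n_founders])
    ebv_full: np.ndarray | None = None
    warm: np.ndarray | None = None
    snapshots: dict[int, Snapshot] = {}
    n_done = n_founders
    n_off = config.n_dams * config.progeny_per_dam

    for cycle in range(1, config.n_cycles + 1):
        sires_arr = np.asarray(cur_sires)
        dams_arr = np.asarray(cur_dams)
        if config.mating == "balanced":
            # every sire serves n_dams/n_sires randomly assigned dams
            reps = int(np.ceil(len(dams_arr) / len(sires_arr)))
            mate_sire = rng.permutation(np.tile(sires_arr, reps)[: len(dams_arr)])
        else:
            mate_sire = sires_arr[rng.integers(0, len(sires_arr), len(dams_arr))]
        off_sire = np.repeat(mate_sire, config.progeny_per_dam)
        off_dam = np.repeat(dams_arr, config.progeny_per_dam)
        off_rows = np.arange(n_done, n_done + n_off)
        sire[off_rows] = off_sire
        dam[off_rows] = off_dam
        birth[off_rows] = cycle
        sex[off_rows] = rng.integers(0, 2, n_off).astype(np.int8)

        hap = gene_drop.drop_offspring(
            store.hap, store.slots(off_sire), store.slots(off_dam), genome, rng
        )
        tbv[off_rows] = genome_sim.true_breeding_values(hap[:, :, qtl_idx], effects)
        phen[off_rows] = tbv[off_rows] + rng.normal(0.0, sig_e, n_off)
        ftrue[off_rows] = inbreeding.f_true(hap[:, :, snp_idx])

        dose = None
        if need_dose or cycle in config.snapshot_cycles:
            dose = genome_sim.genotype_codes(hap[:, :, snp_idx], layer.recode_map)
        if cycle in config.snapshot_cycles:
            snapshots[cycle] = Snapshot(cycle=cycle, animal_index=off_rows, dose=dose)

        # --- score everyone relevant under the criterion
        n_cur = n_done + n_off
        if config.selection == "random":
            scores[off_rows] = rng.random(n_off)
        elif config.selection == "phenotype":
            scores[off_rows] = phen[off_rows]
        elif config.selection == "blup_ebv":
            F_ped = inbreeding.f_ped(sire[:n_cur], dam[:n_cur], F_ped)
            x0 = None
            if warm is not None:
                x0 = np.zeros(n_cur + 1)
                x0[: len(warm)] = warm
            mu, ebv = blup_ebv(
                sire[:n_cur], dam[:n_cur], phen[:n_cur],
                config.sigma_a2, config.sigma_e2, F=F_ped, tol=config.blup_tol, x0=x0,
            )
            warm = np.concatenate([[mu], ebv])
            scores[:n_cur] = ebv
        elif config.selection == "gblup_gebv":
            lo = cycle - config.reference_window
            ref = [c for c in ref_cohorts if c[0] >= lo]
            ref_dose = np.concatenate([c[1] for c in ref], axis=0)
            ref_phen = np.concatenate([c[2] for c in ref])
            parents = np.concatenate([sires_arr, dams_arr])
            parent_dose = store.dose[store.slots(parents)]
            mu, pred = gblup_gebv(
                ref_dose, ref_phen, np.concatenate([dose, parent_dose], axis=0),
                config.sigma_a2, config.sigma_e2,
            )
            scores[off_rows] = pred[:n_off]
            scores[parents] = pred[n_off:]
            ref_cohorts.append((cycle, dose, phen[off_rows].copy()))
            ref_cohorts = [c for c in ref_cohorts if c[0] >= cycle + 1 - config.reference_window]

        # --- replacement
        males = off_rows[sex[off_rows] == 0]
        females = off_rows[sex[off_rows] == 1]
        k_s = min(config.k_sire_repl, len(males))
        k_d = min(config.k_dam_repl, len(females))
        new_sires = _select_top(males, scores[males], k_s)
        new_dams = _select_top(females, scores[females], k_d)
        cull_s = _cull_order(cur_sires, birth, scores, cycle, config.culling, rng)[:k_s]
        cull_d = _cull_order(cur_dams, birth, scores, cycle, config.culling, rng)[:k_d]
        for a in np.concatenate([cull_s, cull_d]):
            store.remove(int(a))
        local = {r: i for i, r in enumerate(off_rows)}
        for a in new_sires:
            store.add(int(a), hap[local[a]], dose[local[a]] if need_dose else None)
        for a in new_dams:
            store.add(int(a), hap[local[a]], dose[local[a]] if need_dose else None)
        cull_set = set(int(a) for a in cull_s)
        cur_sires = [s for s in cur_sires if s not in cull_set] + [int(a) for a in new_sires]
        cull_set = set(int(a) for a in cull_d)
        cur_dams = [d for d in cur_dams if d not in cull_set] + [int(a) for a in new_dams]
        n_done = n_cur

    F_ped = inbreeding.f_ped(sire, dam, F_ped)
    return SimResult(
        config=config, genome=genome, layer=layer, effects=effects,
        sire=sire, dam=dam, sex=sex, birth=birth, tbv=tbv, phen=phen,
        f_true=ftrue, f_ped=F_ped, snapshots=snapshots,
    )
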