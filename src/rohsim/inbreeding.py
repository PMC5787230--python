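"""Inbreeding coefficients: true (gene-dropping), pedigree, genomic, ROH-based.

Four per-animal measures of inbreeding are computed:

* ``f_true`` — realized autozygosity: the fraction of SNP loci at which the
  two founder-allele ids coincide (identity by descent read directly from the
  gene-dropping truth layer).
* ``f_ped`` — Wright's pedigree inbreeding, the expected autozygosity given
  the recorded pedigree, computed with the Meuwissen & Luo recursion (exact,
  efficient for deep pedigrees of 10^4-10^6 animals).
* ``f_grm`` — diagonal of the VanRaden genomic relationship matrix minus one,
  G = ZZ' / 2*sum(p(1-p)), under either known base allele frequencies or a
  fixed frequency of 0.5.
* ``f_roh`` — genome fraction (in SNP count) covered by detected runs of
  homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

__all__ = [
    "GRMResult",
    "f_true",
    "f_ped",
    "tabular_relationship_matrix",
    "compute_grm",
    "f_grm",
    "f_grm_diag",
    "f_roh",
]


def f_true(ids_snp: np.ndarray) -> np.ndarray:
    """Fraction of SNP loci with identical founder-allele ids, per animal.

    ``ids_snp``: (n_animals, 2, n_snp) truth-layer ids restricted to SNP loci.
    """
    return (ids_snp[:, 0, :] == ids_snp[:, 1, :]).mean(axis=1)


@numba.njit(cache=True)
def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray, F: np.ndarray, start: int) -> None:
    """Meuwissen & Luo (1992) inbreeding recursion.

    ``sire``/``dam`` are 0-based parent indices (-1 = unknown), sorted so
    parents precede offspring.  Fills ``F[start:]`` in place; ``F[:start]``
    must already be correct, which allows incremental extension as a pedigree
    grows.  a_ii = sum_j L_ij^2 D_j over ancestors j (L the Cholesky factor of
    the numerator relationship matrix, D its diagonal).
    """
    n = len(sire)
    L = np.zeros(n)
    for i in range(start, n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        a_ii = 0.0
        L[i] = 1.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            L[j] = 0.0
            sj, dj = sire[j], dam[j]
            if sj >= 0 and dj >= 0:
                dq = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dq = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dq = 0.75 - 0.25 * F[dj]
            else:
                dq = 1.0
            a_ii += lj * lj * dq
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
        F[i] = a_ii - 1.0


def f_ped(
    sire: np.ndarray,
    dam: np.ndarray,
    F_prev: np.ndarray | None = None,
) -> np.ndarray:
    """Pedigree inbreeding coefficients for a sorted pedigree.

    Parameters
    ----------
    sire, dam
        0-based parent indices per animal, -1 for unknown.  Parents must
        precede offspring (raises on violation).
    F_prev
        Optional coefficients for a leading prefix of the pedigree, enabling
        incremental computation as new cohorts are appended.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    n = len(sire)
    idx = np.arange(n)
    if np.any(sire >= idx) or np.any(dam >= idx):
        raise ValueError("pedigree not sorted: parent index must precede offspring")
    F = np.empty(n)
    start = 0
    if F_prev is not None:
        start = len(F_prev)
        F[:start] = F_prev
    _ml_inbreeding(sire, dam, F, start)
    return F


def tabular_relationship_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    O(n^2) memory; intended for small pedigrees (oracles, mating design).
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


@dataclass
class GRMResult:
    """VanRaden genomic relationship matrix and its ingredients."""

    G: np.ndarray        # (n, n)
    p: np.ndarray        # (m,) allele frequency used for centering
    denom: float         # 2 * sum p(1-p) over retained loci
    kept: np.ndarray     # boolean mask of loci contributing to G


def _grm_freqs(dose: np.ndarray, freq_mode: str, base_freqs: np.ndarray | None):
    m = dose.shape[1]
    if freq_mode == "fixed_0.5":
        p = np.full(m, 0.5)
        # fixed mode: every locus contributes 0.5 to sum p(1-p), monomorphic or not
        kept = np.ones(m, bool)
    elif freq_mode == "known_base":
        if base_freqs is None:
            raise ValueError("known_base mode requires base_freqs")
        p = np.asarray(base_freqs, float)
        if len(p) != m:
            raise ValueError("base_freqs length mismatch")
        # loci monomorphic in the base contribute nothing to numerator or denominator
        kept = (p > 0.0) & (p < 1.0)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    denom = float(2.0 * (p[kept] * (1.0 - p[kept])).sum())
    if denom <= 0.0:
        raise ValueError("2*sum(p(1-p)) is zero; GRM undefined")
    return p, kept, denom


def compute_grm(
    dose: np.ndarray,
    freq_mode: str = "fixed_0.5",
    base_freqs: np.ndarray | None = None,
) -> GRMResult:
    """G = ZZ'/2*sum(p(1-p)) with Z the dose matrix centered by 2p.

    ``dose`` is (n_animals, m) counts of the reference allele (0/1/2).  Under
    ``fixed_0.5`` every locus is centered at 1 and contributes 0.5 to the
    denominator; under ``known_base`` the realized founder frequencies are
    used and base-monomorphic loci are dropped from numerator and denominator.
    """
    dose = np.asarray(dose)
    p, kept, denom = _grm_freqs(dose, freq_mode, base_freqs)
    Z = dose[:, kept].astype(np.float64) - 2.0 * p[kept]
    G = (Z @ Z.T) / denom
    return GRMResult(G=G, p=p, denom=denom, kept=kept)


def f_grm(grm: GRMResult) -> np.ndarray:
    """Genomic inbreeding: diagonal of G minus one (may be <0 or >1)."""
    return np.diag(grm.G) - 1.0


def f_grm_diag(
    dose: np.ndarray,
    freq_mode: str = "fixed_0.5",
    base_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Diagonal-only genomic inbreeding, avoiding the full n x n G.

    Identical to ``f_grm(compute_grm(...))`` but O(n*m) time and memory;
    used for large cohorts where only per-animal coefficients are needed.
    """
    dose = np.asarray(dose)
    p, kept, denom = _grm_freqs(dose, freq_mode, base_freqs)
    Z = dose[:, kept].astype(np.float64) - 2.0 * p[kept]
    return (Z * Z).sum(axis=1) / denom - 1.0


def f_roh(
    segments: pd.DataFrame, animal_ids: np.ndarray, n_snp_total: int
) -> np.ndarray:
    """ROH inbreeding: summed segment SNP counts / total panel SNPs, per animal.

    ``segments`` is a detector output table (columns ``animal``, ``n_snp``);
    animals without segments get 0.  Raises if any animal's segments overlap,
    which would violate the detector contract.
    """
    out = np.zeros(len(animal_ids))
    if len(segments) == 0:
        return out
    _check_disjoint(segments)
    sums = segments.groupby("animal")["n_snp"].sum()
    lookup = pd.Series(np.arange(len(animal_ids)), index=animal_ids)
    rows = lookup.reindex(sums.index)
    if rows.isna().any():
        raise ValueError("segments reference animals outside animal_ids")
    out[rows.to_numpy(int)] = sums.to_numpy(float) / float(n_snp_total)
    return out


def _check_disjoint(segments: pd.DataFrame) -> None:
    s = segments.sort_values(["animal", "chrom", "start_idx"])
    same = (s["animal"].to_numpy()[1:] == s["animal"].to_numpy()[:-1]) & (
        s["chrom"].to_numpy()[1:] == s["chrom"].to_numpy()[:-1]
    )
    overlap = s["start_idx"].to_numpy()[1:] <= s["end_idx"].to_numpy()[:-1]
    if np.any(same & overlap):
        raise ValueError("overlapping ROH segments for the same animal/chromosome")
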