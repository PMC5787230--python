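"""Runs-of-homozygosity detection.

Two detector families are provided:

* :func:`detect_roh_shrink` — a longest-first scan: all maximal stretches of
  non-heterozygous genotypes allowing at most ``floor(n_snp * e)`` embedded
  heterozygous calls (``e`` the assumed genotyping error rate) are enumerated,
  accepted longest-first so segments never overlap, then filtered by minimum
  SNP count, minimum bp span and SNP density.  With ``e = 0.001`` a segment
  must contain at least 1000 called SNPs before a single heterozygote is
  tolerated.
* :func:`detect_roh_sliding` — a fixed sliding window: every window of
  ``window_snp`` SNPs passes if it contains at most ``window_het``
  heterozygous and ``window_missing`` missing calls; a SNP is ROH-eligible if
  at least 5% of the windows covering it pass, and maximal eligible runs
  meeting the same SNP-count threshold (plus bp-span, density and gap rules)
  are reported.

Genotype state codes used internally: 0 = homozygous, 1 = heterozygous,
2 = missing.  Missing calls never break a segment but are not counted in its
SNP length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

__all__ = [
    "ROHParams",
    "detect_roh_shrink",
    "detect_roh_sliding",
    "summarize_roh",
    "dose_to_state",
]

SEGMENT_COLUMNS = ["animal", "chrom", "start_idx", "end_idx", "start_bp", "end_bp", "n_snp", "n_het"]

#: minimum bp span implied by each window size at the 1 SNP / 50 kb density floor
_MIN_BP_PER_SNP = 50_000


@dataclass
class ROHParams:
    """Detection thresholds.

    ``min_length_bp`` defaults to ``min_window_snp * 50 kb`` (0.25 / 1 / 1.75 /
    2.5 Mb for windows of 5 / 20 / 35 / 50 SNPs), matching a minimum marker
    density of one SNP per 50 kb.  ``density_kb_per_snp`` optionally rejects
    segments whose average spacing exceeds the threshold; by default it is
    off — the stated marker-density requirement is a property the panel must
    satisfy globally, not a per-segment filter (a binding per-segment rule
    at the panel's own mean spacing would discard genuine long segments).
    """

    min_window_snp: int = 20
    genotype_error_rate: float = 0.001
    error_allowance: str = "floor"  # "floor": no het below 1/e SNPs; "ceil": >=1 tolerated anywhere
    density_kb_per_snp: float | None = None
    min_length_bp: int | None = None
    window_het: int = 1       # sliding variant: heterozygotes allowed per window
    window_missing: int = 5   # sliding variant: missing calls allowed per window
    hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_window_snp < 1:
            raise ValueError("min_window_snp must be >= 1")
        if self.min_length_bp is None:
            self.min_length_bp = self.min_window_snp * _MIN_BP_PER_SNP


def dose_to_state(dose: np.ndarray) -> np.ndarray:
    """Map allele-count genotypes to detector states (0 hom, 1 het, 2 missing)."""
    dose = np.asarray(dose)
    state = np.where(dose == 1, 1, 0).astype(np.int8)
    state[dose < 0] = 2
    return state


def _chrom_starts(chrom: np.ndarray) -> np.ndarray:
    """Offsets of each chromosome block in a (chrom-sorted) locus array."""
    chrom = np.asarray(chrom)
    if np.any(np.diff(chrom) < 0):
        raise ValueError("map must be sorted by chromosome")
    change = np.flatnonzero(np.diff(chrom)) + 1
    return np.concatenate([[0], change, [len(chrom)]]).astype(np.int64)


@numba.njit(cache=True)
def _shrink_scan(
    state, chrom_starts, chrom_codes, bp, err_rate, ceil_mode, min_snp, min_bp, density_kb,
    out_animal, out_chrom, out_s, out_e, out_nsnp, out_nhet,
):  # pragma: no cover - exercised via detect_roh_shrink
    n, m = state.shape
    nseg = 0
    n_blocks = len(chrom_starts) - 1
    for a in range(n):
        for blk in range(n_blocks):
            lo = chrom_starts[blk]
            hi = chrom_starts[blk + 1]
            Lc = hi - lo
            if Lc == 0:
                continue
            # het indices and prefix counts of called homozygotes
            het_idx = np.empty(Lc, np.int64)
            nhet = 0
            hompref = np.zeros(Lc + 1, np.int64)
            for i in range(Lc):
                st = state[a, lo + i]
                hompref[i + 1] = hompref[i] + (1 if st == 0 else 0)
                if st == 1:
                    het_idx[nhet] = i
                    nhet += 1
            n_called = hompref[Lc] + nhet
            R = nhet + 1
            # run r occupies local span (bound_lo[r] .. bound_hi[r]) between hets
            first_hom = np.full(R, -1, np.int64)
            last_hom = np.full(R, -1, np.int64)
            for r in range(R):
                blo = het_idx[r - 1] + 1 if r > 0 else 0
                bhi = het_idx[r] - 1 if r < nhet else Lc - 1
                for i in range(blo, bhi + 1):
                    if state[a, lo + i] == 0:
                        if first_hom[r] < 0:
                            first_hom[r] = i
                        last_hom[r] = i
            kmax = int(n_called * err_rate)
            if ceil_mode and n_called * err_rate > kmax:
                kmax += 1
            # feasibility of bridging k hets starting at run r
            feas = np.zeros((R, kmax + 1), np.uint8)
            cs = np.zeros((R, kmax + 1), np.int64)
            ce = np.zeros((R, kmax + 1), np.int64)
            cn = np.zeros((R, kmax + 1), np.int64)
            for r in range(R):
                if first_hom[r] < 0:
                    continue
                for k in range(kmax + 1):
                    b = r + k
                    if b >= R or first_hom[b] < 0:
                        continue
                    s_i = first_hom[r]
                    e_i = last_hom[b]
                    nsnp = hompref[e_i + 1] - hompref[s_i] + k
                    allow = int(nsnp * err_rate)
                    if ceil_mode and nsnp * err_rate > allow:
                        allow += 1
                    if k <= allow:
                        feas[r, k] = 1
                        cs[r, k] = s_i
                        ce[r, k] = e_i
                        cn[r, k] = nsnp
            # maximal candidates: feasible and not contained in a feasible superset
            n_cand = 0
            cand_r = np.empty(R * (kmax + 1), np.int64)
            cand_k = np.empty(R * (kmax + 1), np.int64)
            for r in range(R):
                for k in range(kmax + 1):
                    if not feas[r, k]:
                        continue
                    dominated = False
                    for da in range(0, kmax - k + 1):
                        if dominated:
                            break
                        r2 = r - da
                        if r2 < 0:
                            break
                        for db in range(0, kmax - k - da + 1):
                            if da == 0 and db == 0:
                                continue
                            if r2 + k + da + db >= R:
                                break
                            if feas[r2, k + da + db]:
                                dominated = True
                                break
                    if not dominated:
                        cand_r[n_cand] = r
                        cand_k[n_cand] = k
                        n_cand += 1
            if n_cand == 0:
                continue
            # longest-first (ties: leftmost) non-overlapping acceptance
            key = np.empty(n_cand, np.int64)
            for q in range(n_cand):
                key[q] = -(cn[cand_r[q], cand_k[q]] * (m + 1) - cs[cand_r[q], cand_k[q]])
            order = np.argsort(key)
            acc_s = np.empty(n_cand, np.int64)
            acc_e = np.empty(n_cand, np.int64)
            n_acc = 0
            for qq in range(n_cand):
                q = order[qq]
                s_i = cs[cand_r[q], cand_k[q]]
                e_i = ce[cand_r[q], cand_k[q]]
                ok = True
                for t in range(n_acc):
                    if s_i <= acc_e[t] and e_i >= acc_s[t]:
                        ok = False
                        break
                if not ok:
                    continue
                acc_s[n_acc] = s_i
                acc_e[n_acc] = e_i
                n_acc += 1
                # final filters
                nsnp = cn[cand_r[q], cand_k[q]]
                span = bp[lo + e_i] - bp[lo + s_i] + 1
                if nsnp < min_snp:
                    continue
                if span < min_bp:
                    continue
                if span / 1000.0 > density_kb * nsnp:
                    continue
                out_animal[nseg] = a
                out_chrom[nseg] = chrom_codes[blk]
                out_s[nseg] = lo + s_i
                out_e[nseg] = lo + e_i
                out_nsnp[nseg] = nsnp
                out_nhet[nseg] = cand_k[q]
                nseg += 1
    return nseg


def detect_roh_shrink(
    dose: np.ndarray,
    chrom: np.ndarray,
    bp: np.ndarray,
    params: ROHParams | None = None,
    animal_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Longest-first ROH scan with an error-rate heterozygote allowance.

    Parameters
    ----------
    dose
        (n_animals, m) allele counts; negative = missing call.
    chrom, bp
        Per-SNP chromosome code and bp position, sorted by (chrom, bp).
    params
        Detection thresholds (window size, error rate, density).
    animal_ids
        Labels for the output ``animal`` column (default: row index).

    Returns
    -------
    DataFrame with one row per accepted segment: animal, chrom, SNP index
    span (inclusive), bp span, called-SNP count and embedded het count.
    """
    params = params or ROHParams()
    dose = np.asarray(dose)
    bp = np.asarray(bp, np.int64)
    starts = _chrom_starts(chrom)
    if np.any(np.diff(bp)[np.diff(np.asarray(chrom)) == 0] <= 0):
        raise ValueError("bp positions must increase within chromosomes")
    chrom_codes = np.asarray(chrom)[starts[:-1]].astype(np.int64)
    state = dose_to_state(dose)
    cap = int((state == 1).sum() + state.shape[0] * (len(starts) + 1) + 16)
    out = [np.empty(cap, np.int64) for _ in range(6)]
    if params.error_allowance not in ("ceil", "floor"):
        raise ValueError("error_allowance must be 'ceil' or 'floor'")
    density = params.density_kb_per_snp
    nseg = _shrink_scan(
        state, starts, chrom_codes, bp,
        float(params.genotype_error_rate), params.error_allowance == "ceil",
        int(params.min_window_snp),
        int(params.min_length_bp), float(np.inf if density is None else density), *out,
    )
    return _segments_frame(out, nseg, bp, animal_ids, dose.shape[0])


def _segments_frame(out, nseg, bp, animal_ids, n_animals):
    a, c, s, e, nsnp, nhet = (x[:nseg] for x in out)
    if animal_ids is None:
        animal_ids = np.arange(n_animals)
    return pd.DataFrame(
        {
            "animal": np.asarray(animal_ids)[a],
            "chrom": c,
            "start_idx": s,
            "end_idx": e,
            "start_bp": bp[s] if nseg else np.empty(0, np.int64),
            "end_bp": bp[e] if nseg else np.empty(0, np.int64),
            "n_snp": nsnp,
            "n_het": nhet,
        }
    )


def detect_roh_sliding(
    dose: np.ndarray,
    chrom: np.ndarray,
    bp: np.ndarray,
    window_snp: int = 20,
    params: ROHParams | None = None,
    animal_ids: np.ndarray | None = None,
    max_gap_kb: float = 1000.0,
    min_length_kb: float = 1000.0,
) -> pd.DataFrame:
    """Fixed sliding-window ROH scan (PLINK-style).

    Per-SNP hit fractions are computed from all windows of ``window_snp``
    consecutive SNPs containing the SNP; a window passes with at most
    ``params.window_het`` heterozygous and ``params.window_missing`` missing
    calls.  Maximal runs of SNPs with hit fraction >= ``params.hit_fraction``
    are split at gaps larger than ``max_gap_kb`` and reported when they
    contain at least ``window_snp`` SNPs, span at least ``min_length_kb`` and
    satisfy the density rule.  Chromosomes shorter than the window are
    skipped.
    """
    params = params or ROHParams(min_window_snp=window_snp)
    dose = np.asarray(dose)
    bp = np.asarray(bp, np.int64)
    starts = _chrom_starts(chrom)
    chrom_codes = np.asarray(chrom)[starts[:-1]].astype(np.int64)
    state = dose_to_state(dose)
    n = state.shape[0]
    rows: list[tuple] = []
    if animal_ids is None:
        animal_ids = np.arange(n)
    animal_ids = np.asarray(animal_ids)
    for blk in range(len(starts) - 1):
        lo, hi = int(starts[blk]), int(starts[blk + 1])
        Lc = hi - lo
        if Lc < window_snp:
            continue
        st = state[:, lo:hi]
        het = (st == 1).astype(np.int32)
        mis = (st == 2).astype(np.int32)
        w = window_snp
        het_c = np.cumsum(np.concatenate([np.zeros((n, 1), np.int32), het], axis=1), axis=1)
        mis_c = np.cumsum(np.concatenate([np.zeros((n, 1), np.int32), mis], axis=1), axis=1)
        het_w = het_c[:, w:] - het_c[:, :-w]          # (n, n_win)
        mis_w = mis_c[:, w:] - mis_c[:, :-w]
        passing = ((het_w <= params.window_het) & (mis_w <= params.window_missing)).astype(np.int32)
        pass_c = np.cumsum(np.concatenate([np.zeros((n, 1), np.int32), passing], axis=1), axis=1)
        n_win = passing.shape[1]
        i = np.arange(Lc)
        w_lo = np.maximum(0, i - w + 1)
        w_hi = np.minimum(n_win - 1, i)
        n_cover = (w_hi - w_lo + 1).astype(np.float64)
        hits = pass_c[:, w_hi + 1] - pass_c[:, w_lo]
        eligible = (hits / n_cover) >= params.hit_fraction
        bp_c = bp[lo:hi]
        gap_break = np.zeros(Lc, bool)
        gap_break[1:] = np.diff(bp_c) > max_gap_kb * 1000.0
        for ai in range(n):
            el = eligible[ai]
            # maximal eligible runs, split at large gaps
            start = -1
            for j in range(Lc + 1):
                if start >= 0 and (j == Lc or not el[j] or gap_break[j]):
                    _emit_sliding(rows, st[ai], bp_c, start, j - 1, window_snp,
                                  min_length_kb, params, chrom_codes[blk], lo,
                                  animal_ids[ai])
                    start = -1
                if j < Lc and el[j] and start < 0:
                    start = j
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS) if rows else pd.DataFrame(
        {c: np.empty(0, np.int64) for c in SEGMENT_COLUMNS}
    )


def _emit_sliding(rows, st_row, bp_c, start, end, window_snp, min_length_kb, params,
                  chrom_code, lo, animal_id):
    n_called = int(np.sum(st_row[start : end + 1] != 2))
    n_het = int(np.sum(st_row[start : end + 1] == 1))
    span = int(bp_c[end] - bp_c[start] + 1)
    if n_called < window_snp:
        return
    if span < min_length_kb * 1000.0:
        return
    density = 50.0 if params.density_kb_per_snp is None else params.density_kb_per_snp
    if span / 1000.0 > density * n_called:
        return
    rows.append(
        (animal_id, int(chrom_code), lo + start, lo + end,
         int(bp_c[start]), int(bp_c[end]), n_called, n_het)
    )


def summarize_roh(segments: pd.DataFrame, animal_ids: np.ndarray) -> pd.DataFrame:
    """Per-animal ROH summary: segment count and min/max/mean length in SNP.

    Animals with no segments appear with ``n_roh = 0`` and NaN lengths (they
    are excluded from cohort length means but not from count means).
    """
    animal_ids = np.asarray(animal_ids)
    base = pd.DataFrame(index=pd.Index(animal_ids, name="animal"))
    if len(segments):
        g = segments.groupby("animal")["n_snp"]
        stats = pd.DataFrame(
            {"n_roh": g.size(), "min_snp": g.min(), "max_snp": g.max(), "mean_snp": g.mean()}
        )
    else:
        stats = pd.DataFrame(columns=["n_roh", "min_snp", "max_snp", "mean_snp"])
    out = base.join(stats)
    out["n_roh"] = out["n_roh"].astype(float).fillna(0).astype(int)
    for col in ("min_snp", "max_snp", "mean_snp"):
        out[col] = out[col].astype(float)
    return out.reset_index()
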