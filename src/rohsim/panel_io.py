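"""SNP-panel I/O and the real-data-style trend analysis layer.

Reads and writes PLINK text (.ped/.map) and binary (.bed/.bim/.fam) panels,
generates a synthetic medium-density cattle-like panel with birth years, a
pedigree, and a controllable two-slope inbreeding trend with a changepoint
year (a stand-in for proprietary genotype archives), and computes per-year
inbreeding/ROH trend reports.

Genotype convention: ``dose`` counts copies of allele "1" (the A1 allele in
.bim), with -1 for missing.  Coordinates are 1-based inclusive bp spans and
chromosome codes are plain integers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import gene_drop, genome_sim, inbreeding, roh_detect
from .roh_detect import ROHParams

__all__ = [
    "Panel",
    "PanelFixtureConfig",
    "PanelFixture",
    "TrendReport",
    "read_panel",
    "write_panel",
    "generate_panel_fixture",
    "annual_trend",
    "cumulative_roh_curve",
    "roh_class_table",
]

DEFAULT_LENGTH_CLASSES_MB = ((0.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, float("inf")))


@dataclass
class Panel:
    """Genotype matrix plus map and sample metadata.

    ``dose``: (n_samples, n_snp) int8, copies of allele "1", -1 = missing.
    ``snp_map``: columns chrom, snp_id, cm, bp.  ``samples``: columns fid,
    iid, sire, dam, sex (1 male / 2 female / 0 unknown), phen.
    """

    dose: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dose.shape != (len(self.samples), len(self.snp_map)):
            raise ValueError(
                f"genotype matrix {self.dose.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snp_map)} SNPs"
            )


def write_panel(panel: Panel, prefix: str, fmt: str = "bed") -> None:
    """Write a panel as PLINK ``.ped/.map`` (text) or ``.bed/.bim/.fam`` (binary)."""
    m = panel.snp_map
    s = panel.samples
    dose = panel.dose
    if fmt == "ped":
        m[["chrom", "snp_id", "cm", "bp"]].to_csv(
            prefix + ".map", sep="\t", header=False, index=False
        )
        allele = {2: "1 1", 1: "1 2", 0: "2 2", -1: "0 0"}
        with open(prefix + ".ped", "w") as fh:
            for i in range(len(s)):
                row = s.iloc[i]
                geno = " ".join(allele[int(d)] for d in dose[i])
                fh.write(
                    f"{row.fid} {row.iid} {row.sire} {row.dam} {int(row.sex)} "
                    f"{row.phen} {geno}\n"
                )
    elif fmt == "bed":
        bim = m.copy()
        bim["a1"] = "1"
        bim["a2"] = "2"
        bim[["chrom", "snp_id", "cm", "bp", "a1", "a2"]].to_csv(
            prefix + ".bim", sep="\t", header=False, index=False
        )
        s[["fid", "iid", "sire", "dam", "sex", "phen"]].to_csv(
            prefix + ".fam", sep=" ", header=False, index=False
        )
        n = len(s)
        # 2-bit codes per sample: dose 2 -> 00 (hom A1), 1 -> 10, 0 -> 11, missing -> 01
        code = np.empty(dose.shape, np.uint8)
        code[dose == 2] = 0b00
        code[dose == 1] = 0b10
        code[dose == 0] = 0b11
        code[dose < 0] = 0b01
        pad = (-n) % 4
        if pad:
            code = np.concatenate([code, np.zeros((pad, code.shape[1]), np.uint8)], axis=0)
        quads = code.T.reshape(len(m), -1, 4)  # SNP-major
        packed = (quads[:, :, 0] | quads[:, :, 1] << 2 | quads[:, :, 2] << 4 | quads[:, :, 3] << 6)
        with open(prefix + ".bed", "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))
            fh.write(packed.astype(np.uint8).tobytes())
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_panel(prefix: str, fmt: str | None = None) -> Panel:
    """Read a PLINK panel; ``fmt`` auto-detected from the files present."""
    if fmt is None:
        if os.path.exists(prefix + ".bed"):
            fmt = "bed"
        elif os.path.exists(prefix + ".ped"):
            fmt = "ped"
        else:
            raise FileNotFoundError(f"no .bed or .ped file with prefix {prefix}")
    if fmt == "ped":
        snp_map = pd.read_csv(
            prefix + ".map", sep=r"\s+", header=None,
            names=["chrom", "snp_id", "cm", "bp"],
        )
        doses, rows = [], []
        with open(prefix + ".ped") as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.split()
                if len(parts) != 6 + 2 * len(snp_map):
                    raise ValueError(
                        f"{prefix}.ped line {ln}: expected {6 + 2 * len(snp_map)} "
                        f"fields, found {len(parts)}"
                    )
                rows.append(parts[:6])
                g = np.array(parts[6:]).reshape(-1, 2)
                d = (g == "1").sum(axis=1).astype(np.int8)
                d[(g == "0").any(axis=1)] = -1
                doses.append(d)
        samples = pd.DataFrame(rows, columns=["fid", "iid", "sire", "dam", "sex", "phen"])
        samples["sex"] = samples["sex"].astype(int)
        return Panel(np.array(doses, np.int8), snp_map, samples)
    if fmt == "bed":
        bim = pd.read_csv(
            prefix + ".bim", sep=r"\s+", header=None,
            names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        )
        samples = pd.read_csv(
            prefix + ".fam", sep=r"\s+", header=None,
            names=["fid", "iid", "sire", "dam", "sex", "phen"],
        )
        n, m = len(samples), len(bim)
        bpl = (n + 3) // 4  # bytes per SNP block
        with open(prefix + ".bed", "rb") as fh:
            raw = fh.read()
        if len(raw) < 3 or raw[:3] != bytes([0x6C, 0x1B, 0x01]):
            raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
        expect = 3 + m * bpl
        if len(raw) != expect:
            raise ValueError(
                f"{prefix}.bed truncated or oversized: expected {expect} bytes, "
                f"found {len(raw)} (first inconsistency at byte offset {min(expect, len(raw))})"
            )
        data = np.frombuffer(raw, np.uint8, offset=3).reshape(m, bpl)
        bits = np.empty((m, bpl * 4), np.uint8)
        for q in range(4):
            bits[:, q::4] = (data >> (2 * q)) & 0b11
        code = bits[:, :n].T
        dose = np.empty(code.shape, np.int8)
        dose[code == 0b00] = 2
        dose[code == 0b10] = 1
        dose[code == 0b11] = 0
        dose[code == 0b01] = -1
        return Panel(dose, bim[["chrom", "snp_id", "cm", "bp"]].copy(), samples)
    raise ValueError(f"unknown format {fmt!r}")


@dataclass
class PanelFixtureConfig:
    """Synthetic genotype-panel generator settings.

    The generator emulates a medium-density diploid cattle panel with yearly
    birth cohorts whose mean inbreeding follows a two-slope trend: a slow
    pre-changepoint increase and a faster post-changepoint increase, the
    pattern expected when genomic selection shortens the generation interval.
    The trend is realized through the mating design: each offspring's parents
    are chosen so the expected pedigree inbreeding of the cohort tracks the
    target line.
    """

    year_start: int = 1990
    year_end: int = 2016
    animals_per_year: int = 200
    changepoint_year: int = 2010
    slope_pre: float = 0.001
    slope_post: float = 0.005
    n_chrom: int = 29
    total_cm: float = 2496.0
    n_snp: int = 44_369
    scenario: str = "uniform_0_to_half"
    n_founders: int = 400
    parent_depth: int = 2       # parents drawn from cohorts of the last k years
    candidate_pairs: int = 40   # matings screened per offspring for the F target
    roh_window_snp: int = 20

    def validate(self) -> None:
        if self.slope_pre < 0 or self.slope_post < 0:
            raise ValueError("trend slopes must be non-negative")
        if not (self.year_start < self.changepoint_year <= self.year_end):
            raise ValueError("changepoint must lie within the year span")
        n_years = self.year_end - self.year_start + 1
        max_f = self.slope_pre * (self.changepoint_year - self.year_start) + (
            self.slope_post * (self.year_end - self.changepoint_year)
        )
        if max_f > 0.45:
            raise ValueError("configured slopes require unattainable inbreeding (>0.45)")
        if self.animals_per_year < 10 or self.n_founders < 20:
            raise ValueError("population too small for the mating design")
        assert n_years >= 4


@dataclass
class PanelFixture:
    """Generated panel, pedigree and per-animal trend measurements."""

    config: PanelFixtureConfig
    panel: Panel
    pedigree: pd.DataFrame     # id, sire, dam, sex, birth_year (0-based ids internally)
    birth_year: np.ndarray
    f_ped: np.ndarray
    f_true: np.ndarray
    f_roh: np.ndarray
    segments: pd.DataFrame


@dataclass
class TrendReport:
    """Per-year means and piecewise-linear trend fit around a changepoint."""

    per_year: pd.DataFrame     # year, mean, n
    changepoint: int
    slope_pre: float
    se_pre: float
    slope_post: float
    se_post: float


def _target_f(year: int, cfg: PanelFixtureConfig) -> float:
    y0 = cfg.year_start
    if year <= cfg.changepoint_year:
        return max(0.0, cfg.slope_pre * (year - y0))
    return cfg.slope_pre * (cfg.changepoint_year - y0) + cfg.slope_post * (
        year - cfg.changepoint_year
    )


def generate_panel_fixture(
    cfg: PanelFixtureConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PanelFixture:
    """Generate the synthetic panel by gene dropping through a tuned pedigree.

    Unrelated founders precede the first year.  For every offspring a set of
    candidate sire/dam pairs is screened and the pair whose pedigree kinship
    is closest to the year's target mean inbreeding is mated, so cohort-mean
    inbreeding follows the configured two-slope trend.  Founder alleles are
    dropped through the resulting pedigree, recoded to SNP genotypes, and
    ROH-based inbreeding is measured per animal.
    """
    cfg = cfg or PanelFixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(rng)
    genome = genome_sim.build_genome(cfg.n_chrom, cfg.total_cm, cfg.n_snp, 0, rng)
    layer = genome_sim.assign_founder_alleles(cfg.n_founders, genome.n_loci, rng)
    genome_sim.recode_alleles(layer, cfg.scenario, rng, genome.snp_locus_idx)

    years = list(range(cfg.year_start, cfg.year_end + 1))
    n_total = cfg.n_founders + len(years) * cfg.animals_per_year
    sire = np.full(n_total, -1, np.int64)
    dam = np.full(n_total, -1, np.int64)
    sex = np.empty(n_total, np.int8)
    birth = np.full(n_total, cfg.year_start - 1, np.int64)
    sex[: cfg.n_founders] = (np.arange(cfg.n_founders) % 2).astype(np.int8)
    A = np.zeros((n_total, n_total), np.float32)
    A[np.diag_indices(cfg.n_founders)] = 1.0

    params = ROHParams(min_window_snp=cfg.roh_window_snp)
    hap_bank: dict[int, np.ndarray] = {a: layer.allele_ids[a] for a in range(cfg.n_founders)}
    f_roh = np.zeros(n_total)
    f_true = np.zeros(n_total)
    all_segments: list[pd.DataFrame] = []
    dose_all = np.empty((n_total, genome.n_snp), np.int8)
    dose_all[: cfg.n_founders] = genome_sim.genotype_codes(
        layer.allele_ids[:, :, genome.snp_locus_idx], layer.recode_map
    )
    n_done = cfg.n_founders

    for year in years:
        pool = np.flatnonzero((birth[:n_done] >= year - cfg.parent_depth) & (birth[:n_done] < year))
        males = pool[sex[pool] == 0]
        females = pool[sex[pool] == 1]
        if len(males) == 0 or len(females) == 0:
            raise RuntimeError("parent pool lost a sex; enlarge cohorts")
        target = _target_f(year, cfg)
        rows = np.arange(n_done, n_done + cfg.animals_per_year)
        for i in rows:
            cs = males[rng.integers(0, len(males), cfg.candidate_pairs)]
            cd = females[rng.integers(0, len(females), cfg.candidate_pairs)]
            kin = 0.5 * A[cs, cd]
            # kinship is quantized (0, 1/8, 1/4, ...): randomize between the
            # nearest candidates below and above the target so the cohort
            # mean matches it in expectation; outside the attainable range
            # fall back to the closest pair.
            below = kin <= target
            if below.all() or not below.any():
                pick = int(np.argmin(np.abs(kin - target)))
            else:
                kb = np.where(below, kin, -np.inf).argmax()
                ka = np.where(~below, kin, np.inf).argmin()
                p = (target - kin[kb]) / (kin[ka] - kin[kb])
                pick = int(ka if rng.random() < p else kb)
            s, d = int(cs[pick]), int(cd[pick])
            sire[i], dam[i] = s, d
            birth[i] = year
            sex[i] = rng.integers(0, 2)
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s, d]
        # drop alleles for the cohort in one vectorized batch
        parent_rows = np.array([hap_bank_key for hap_bank_key in hap_bank], np.int64)
        bank = np.stack([hap_bank[a] for a in parent_rows])
        row_of = {a: j for j, a in enumerate(parent_rows)}
        s_rows = np.array([row_of[int(sire[i])] for i in rows], np.int64)
        d_rows = np.array([row_of[int(dam[i])] for i in rows], np.int64)
        hap = gene_drop.drop_offspring(bank, s_rows, d_rows, genome, rng)
        f_true[rows] = inbreeding.f_true(hap[:, :, genome.snp_locus_idx])
        dose = genome_sim.genotype_codes(hap[:, :, genome.snp_locus_idx], layer.recode_map)
        dose_all[rows] = dose
        seg = roh_detect.detect_roh_shrink(
            dose, genome.snp_chrom, genome.snp_bp, params, animal_ids=rows
        )
        f_roh[rows] = inbreeding.f_roh(seg, rows, genome.n_snp)
        all_segments.append(seg)
        for j, i in enumerate(rows):
            hap_bank[int(i)] = hap[j]
        # retire animals too old to be parents next year
        for a in list(hap_bank):
            if birth[a] < year + 1 - cfg.parent_depth:
                del hap_bank[a]
        n_done += cfg.animals_per_year

    f_ped = np.diag(A).astype(float) - 1.0
    segments = (
        pd.concat(all_segments, ignore_index=True)
        if all_segments
        else pd.DataFrame(columns=roh_detect.SEGMENT_COLUMNS)
    )
    samples = pd.DataFrame(
        {
            "fid": 1,
            "iid": [f"A{i + 1}" for i in range(n_total)],
            "sire": np.where(sire >= 0, sire + 1, 0),
            "dam": np.where(dam >= 0, dam + 1, 0),
            "sex": np.where(sex == 0, 1, 2),
            "phen": -9,
        }
    )
    panel = Panel(dose_all, genome.to_map_table(), samples)
    pedigree = pd.DataFrame(
        {
            "id": np.arange(1, n_total + 1),
            "sire": np.where(sire >= 0, sire + 1, 0),
            "dam": np.where(dam >= 0, dam + 1, 0),
            "sex": np.where(sex == 0, "M", "F"),
            "birth_year": birth,
        }
    )
    return PanelFixture(
        config=cfg, panel=panel, pedigree=pedigree, birth_year=birth,
        f_ped=f_ped, f_true=f_true, f_roh=f_roh, segments=segments,
    )


def annual_trend(
    f: np.ndarray, birth_year: np.ndarray, changepoint: int
) -> TrendReport:
    """Two-piece OLS trend of yearly cohort means around a changepoint year.

    Yearly means of ``f`` are regressed on year separately for years before
    the changepoint and for the changepoint onward; each period needs at
    least two distinct years (otherwise its slope is NaN).
    """
    f = np.asarray(f, float)
    birth_year = np.asarray(birth_year)
    per_year = (
        pd.DataFrame({"year": birth_year, "f": f})
        .groupby("year")["f"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean", "size": "n"})
    )

    def _fit(mask):
        sub = per_year[mask]
        if len(sub) < 2:
            return float("nan"), float("nan")
        res = scipy.stats.linregress(sub["year"], sub["mean"])
        return float(res.slope), float(res.stderr)

    slope_pre, se_pre = _fit(per_year["year"] < changepoint)
    slope_post, se_post = _fit(per_year["year"] >= changepoint)
    return TrendReport(
        per_year=per_year, changepoint=changepoint,
        slope_pre=slope_pre, se_pre=se_pre, slope_post=slope_post, se_post=se_post,
    )


def cumulative_roh_curve(
    segments: pd.DataFrame,
    n_snp_total: int,
    n_animals: int,
    length_grid_mb: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean cumulative segment count and cumulative F_ROH by maximum length.

    For each grid value L the curve reports the per-animal mean number of
    segments no longer than L Mb and the mean inbreeding contributed by them;
    both are monotone non-decreasing and the terminal F equals total F_ROH.
    """
    if length_grid_mb is None:
        length_grid_mb = np.arange(1.0, 51.0, 1.0)
    span_mb = (segments["end_bp"] - segments["start_bp"] + 1).to_numpy(float) / 1e6
    nsnp = segments["n_snp"].to_numpy(float)
    rows = []
    for L in np.asarray(length_grid_mb, float):
        m = span_mb <= L
        rows.append(
            {
                "max_length_mb": L,
                "mean_count": m.sum() / n_animals,
                "mean_f_roh": nsnp[m].sum() / (n_snp_total * n_animals),
            }
        )
    return pd.DataFrame(rows)


def roh_class_table(
    segments: pd.DataFrame,
    classes_mb: tuple[tuple[float, float], ...] = DEFAULT_LENGTH_CLASSES_MB,
    birth_year: np.ndarray | None = None,
    animal_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Relative frequency of segments per length class (optionally by year).

    ``classes_mb`` must partition (0, inf): contiguous, non-overlapping,
    starting at 0 and ending open.  With ``birth_year``/``animal_ids`` given,
    per-year segment counts by class are reported alongside the overall
    relative frequencies.
    """
    lo = np.array([c[0] for c in classes_mb])
    hi = np.array([c[1] for c in classes_mb])
    if lo[0] != 0 or not np.isinf(hi[-1]) or np.any(lo[1:] != hi[:-1]):
        raise ValueError("length classes must partition (0, inf)")
    span_mb = (segments["end_bp"] - segments["start_bp"] + 1).to_numpy(float) / 1e6
    which = np.searchsorted(hi, span_mb, side="left")
    total = max(len(segments), 1)
    labels = [f"{a:g}-{b:g}Mb" if np.isfinite(b) else f">{a:g}Mb" for a, b in classes_mb]
    out = pd.DataFrame(
        {
            "class": labels,
            "count": [int((which == i).sum()) for i in range(len(classes_mb))],
        }
    )
    out["frequency"] = out["count"] / total
    if birth_year is not None and animal_ids is not None:
        yr = pd.Series(birth_year, index=animal_ids)
        seg_year = yr.reindex(segments["animal"]).to_numpy()
        for i, lab in enumerate(labels):
            mask = which == i
            counts = pd.Series(seg_year[mask]).value_counts()
            out.attrs.setdefault("by_year", {})[lab] = counts.sort_index()
    return out
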