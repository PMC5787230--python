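"""Replicate runner and summary statistics.

Runs the breeding simulation over replicates, computes all inbreeding
measures and ROH statistics per snapshot cohort, and aggregates means with
standard errors across replicates — the machinery behind the simulated
estimator-versus-truth comparison tables, the estimator correlations, the
ROH-length distributions and the significance letter groupings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import inbreeding, roh_detect
from .breeding import SimConfig, SimResult, run_simulation
from .roh_detect import ROHParams

__all__ = [
    "ReplicateSummary",
    "run_replicates",
    "replicate_measures",
    "estimator_correlation",
    "length_distribution",
    "group_significance",
]

F_MEASURES = ["f_true", "f_ped", "f_roh", "f_grm_fixed", "f_grm_base"]


@dataclass
class ReplicateSummary:
    """Aggregated output of a replicate set.

    ``per_replicate`` holds one row per (replicate, generation) with cohort
    means of every inbreeding measure and the ROH summary statistics;
    ``correlations`` one row per (replicate, generation, pair).  ``table()``
    and ``correlation_table()`` aggregate to mean +/- SE across replicates.
    """

    config: SimConfig
    per_replicate: pd.DataFrame
    correlations: pd.DataFrame
    segments: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)
    per_animal: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        g = self.per_replicate.groupby("generation")
        cols = [c for c in self.per_replicate.columns if c not in ("replicate", "generation")]
        mean = g[cols].mean().add_suffix("_mean")
        se = g[cols].sem(ddof=1).add_suffix("_se")
        return mean.join(se).reset_index()

    def correlation_table(self) -> pd.DataFrame:
        g = self.correlations.groupby(["generation", "pair"])["r"]
        return g.agg(["mean", "sem", "count"]).reset_index()


def replicate_measures(
    res: SimResult,
    roh_params: ROHParams | None = None,
    roh_engine: str = "shrink",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, pd.DataFrame], dict[int, pd.DataFrame]]:
    """All inbreeding measures and ROH statistics for one finished replicate.

    Pedigree and true inbreeding are summarized for every cohort; the genomic
    measures (GRM- and ROH-based) only for snapshot cohorts, where genotypes
    exist.  Returns (per-generation table, correlation table, segments by
    cycle, per-animal measures by cycle).
    """
    roh_params = roh_params or ROHParams()
    genome = res.genome
    rows = []
    for gen in range(res.birth.max() + 1):
        idx = res.cohort(gen)
        rows.append(
            {
                "generation": gen,
                "f_true": res.f_true[idx].mean(),
                "f_ped": res.f_ped[idx].mean(),
            }
        )
    per_gen = pd.DataFrame(rows)
    corr_rows = []
    per_animal: dict[int, pd.DataFrame] = {}
    segments: dict[int, pd.DataFrame] = {}
    for cycle, snap in sorted(res.snapshots.items()):
        idx = snap.animal_index
        measures = {
            "animal": idx,
            "f_true": res.f_true[idx],
            "f_ped": res.f_ped[idx],
            "f_grm_fixed": inbreeding.f_grm_diag(snap.dose, "fixed_0.5"),
            "f_grm_base": inbreeding.f_grm_diag(snap.dose, "known_base", res.layer.base_freq),
        }
        if roh_engine == "shrink":
            seg = roh_detect.detect_roh_shrink(
                snap.dose, genome.snp_chrom, genome.snp_bp, roh_params, animal_ids=idx
            )
        else:
            seg = roh_detect.detect_roh_sliding(
                snap.dose, genome.snp_chrom, genome.snp_bp,
                window_snp=roh_params.min_window_snp, params=roh_params, animal_ids=idx,
            )
        measures["f_roh"] = inbreeding.f_roh(seg, idx, genome.n_snp)
        pa = pd.DataFrame(measures)
        per_animal[cycle] = pa
        segments[cycle] = seg
        summ = roh_detect.summarize_roh(seg, idx)
        gi = per_gen.index[per_gen["generation"] == cycle][0]
        per_gen.loc[gi, "f_roh"] = pa["f_roh"].mean()
        per_gen.loc[gi, "f_grm_fixed"] = pa["f_grm_fixed"].mean()
        per_gen.loc[gi, "f_grm_base"] = pa["f_grm_base"].mean()
        per_gen.loc[gi, "roh_count"] = summ["n_roh"].mean()
        per_gen.loc[gi, "roh_min_snp"] = summ["min_snp"].mean()
        per_gen.loc[gi, "roh_max_snp"] = summ["max_snp"].mean()
        per_gen.loc[gi, "roh_mean_snp"] = summ["mean_snp"].mean()
        for fa, fb in itertools.combinations(F_MEASURES, 2):
            corr_rows.append(
                {
                    "generation": cycle,
                    "pair": f"{fa}:{fb}",
                    "r": estimator_correlation(pa[fa].to_numpy(), pa[fb].to_numpy()),
                }
            )
    return per_gen, pd.DataFrame(corr_rows), segments, per_animal


def run_replicates(
    config: SimConfig,
    n_replicates: int | None = None,
    roh_params: ROHParams | None = None,
    base_seed: int | None = None,
    keep_segments: bool = False,
) -> ReplicateSummary:
    """Run the full pipeline over replicates and aggregate.

    Replicate ``i`` uses seed ``base_seed + i`` so replicate sets are
    reproducible and extensible.  Each replicate simulates, estimates all
    four inbreeding measures, detects ROH at the snapshot cycles and
    summarizes; aggregation is mean +/- SE across replicates.
    """
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    seed0 = base_seed if base_seed is not None else (config.seed or 0)
    per_rep, corrs = [], []
    summary = ReplicateSummary(config=config, per_replicate=pd.DataFrame(), correlations=pd.DataFrame())
    for rep in range(n_rep):
        res = run_simulation(config, rng=np.random.default_rng(seed0 + rep))
        per_gen, corr, segments, per_animal = replicate_measures(res, roh_params)
        per_gen.insert(0, "replicate", rep)
        corr.insert(0, "replicate", rep)
        per_rep.append(per_gen)
        corrs.append(corr)
        if keep_segments:
            for cycle, seg in segments.items():
                summary.segments[(rep, cycle)] = seg
            for cycle, pa in per_animal.items():
                summary.per_animal[(rep, cycle)] = pa
    summary.per_replicate = pd.concat(per_rep, ignore_index=True)
    summary.correlations = pd.concat(corrs, ignore_index=True)
    return summary


def estimator_correlation(f_a: np.ndarray, f_b: np.ndarray) -> float:
    """Pearson correlation between two per-animal inbreeding vectors.

    Returns NaN when either vector has fewer than 3 values or zero variance.
    """
    f_a = np.asarray(f_a, float)
    f_b = np.asarray(f_b, float)
    ok = ~(np.isnan(f_a) | np.isnan(f_b))
    if ok.sum() < 3 or f_a[ok].std() == 0 or f_b[ok].std() == 0:
        return float("nan")
    return float(np.corrcoef(f_a[ok], f_b[ok])[0, 1])


def length_distribution(
    segments: pd.DataFrame, bins: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Histogram over segment SNP lengths plus a box-plot five-number summary.

    Returns ``(binned, summary)`` where ``binned`` has columns ``bin_lo``,
    ``bin_hi``, ``count`` and ``summary`` holds min/q1/median/q3/max.
    """
    lengths = segments["n_snp"].to_numpy(float)
    if bins is None:
        upper = max(100.0, float(lengths.max()) if len(lengths) else 100.0)
        bins = np.linspace(0, upper, 21)
    counts, edges = np.histogram(lengths, bins=bins)
    binned = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
    if len(lengths):
        q = np.percentile(lengths, [0, 25, 50, 75, 100])
        summary = dict(zip(["min", "q1", "median", "q3", "max"], map(float, q)))
    else:
        summary = {k: float("nan") for k in ["min", "q1", "median", "q3", "max"]}
    return binned, summary


def _compact_letter_display(groups: list[str], differ: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every pair in
    ``differ`` ends up with disjoint letter sets.
    """
    letters: list[set[str]] = [set(groups)]
    for a, b in differ:
        for col in list(letters):
            if a in col and b in col:
                letters.remove(col)
                ca, cb = col - {b}, col - {a}
                # absorb: drop columns contained in an existing column
                for c in (ca, cb):
                    if not any(c <= other for other in letters):
                        letters.append(c)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    cols = sorted(letters, key=lambda c: sorted(groups.index(g) for g in c))
    for i, col in enumerate(cols):
        for g in groups:
            if g in col:
                out[g] += alphabet[i % len(alphabet)]
    return out


def group_significance(
    values: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    alpha: float = 0.05,
    method: str = "welch-holm",
) -> pd.DataFrame:
    """All-pairs tests across groups with a compact letter display.

    ``values`` holds one replicate-level observation per row.  Pairwise Welch
    t-tests with Holm correction (default) or Tukey HSD are applied at level
    ``alpha``; groups sharing a letter do not differ significantly.  Groups
    with fewer than 2 observations get letter ``"?"`` (not assessable).
    """
    groups = list(values[group_col].unique())
    samples = {g: values.loc[values[group_col] == g, value_col].to_numpy(float) for g in groups}
    assessable = [g for g in groups if len(samples[g]) >= 2]
    pairs = list(itertools.combinations(assessable, 2))
    if method == "welch-holm":
        pvals = [
            scipy.stats.ttest_ind(samples[a], samples[b], equal_var=False).pvalue
            for a, b in pairs
        ]
        # Holm step-down
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, oi in enumerate(order):
            running = max(running, (m - rank) * pvals[oi])
            adj[oi] = min(1.0, running)
        pvals = adj
    elif method == "tukey":
        if len(assessable) >= 2:
            res = scipy.stats.tukey_hsd(*[samples[g] for g in assessable])
            pvals = [res.pvalue[assessable.index(a), assessable.index(b)] for a, b in pairs]
        else:
            pvals = []
    else:
        raise ValueError(f"unknown method {method!r}")
    differ = {pairs[i] for i in range(len(pairs)) if pvals[i] < alpha}
    cld = _compact_letter_display(assessable, differ)
    rows = []
    for g in groups:
        rows.append(
            {
                group_col: g,
                "n": len(samples[g]),
                "mean": samples[g].mean() if len(samples[g]) else float("nan"),
                "letters": cld.get(g, "?"),
            }
        )
    out = pd.DataFrame(rows)
    pair_rows = pd.DataFrame(
        [{"a": a, "b": b, "p_adj": p} for (a, b), p in zip(pairs, pvals)]
    )
    out.attrs["pairwise"] = pair_rows
    return out
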