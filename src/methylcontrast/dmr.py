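"""Differentially methylated region calling and gene-set enrichment.

Per-probe Wald statistics are squared and smoothed with a Gaussian kernel
(sigma = lambda / C); the smoothed statistic is referred to a chi-square
with Satterthwaite effective degrees of freedom, BH-adjusted, and maximal
runs of significant probes are chained into regions.

Gene-set over-representation corrects the probes-per-gene sampling bias
with a Wallenius noncentral hypergeometric model; with equal weights it
reduces exactly to the one-sided Fisher test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .errors import UsageError

DEFAULT_LAMBDA = 1000.0
DEFAULT_C = 2.0


@dataclasses.dataclass
class DMR:
    """Aggregated region; start/end are the 1-based span of member probes."""

    chrom: str
    start: int
    end: int
    n_probes: int
    region_q: float
    max_fc: float           # extremal exponentiated estimate over members
    probe_ids: list[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise UsageError(f"DMR start {self.start} > end {self.end}")


def kernel_smooth(
    positions: np.ndarray,
    wald: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    C: float = DEFAULT_C,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothing of squared statistics on one chromosome.

    Returns (smoothed, df): per-probe weighted mean of squared statistics
    with weights w_ij = exp(-(pos_i - pos_j)^2 / (2 sigma^2)), sigma = lam/C,
    and the Satterthwaite effective df 1 / sum_j a_j^2 for normalized
    weights a_j.  Shift-invariant by construction.
    """
    positions = np.asarray(positions, float)
    wald = np.asarray(wald, float)
    if positions.ndim != 1 or positions.shape != wald.shape:
        raise UsageError("positions and stats must be equal-length vectors")
    if np.any(np.diff(positions) < 0):
        raise UsageError("positions must be sorted within the chromosome")
    if not np.all(np.isfinite(wald)):
        raise UsageError("statistics must be finite")
    n = positions.size
    if n == 0:
        return np.empty(0), np.empty(0)
    sigma = lam / C
    sq = wald * wald
    smoothed = np.empty(n)
    df = np.empty(n)
    cutoff = 6.0 * sigma  # beyond 6 sigma the weight is < 1.6e-8
    lo = np.searchsorted(positions, positions - cutoff, side="left")
    hi = np.searchsorted(positions, positions + cutoff, side="right")
    for i in range(n):
        d = positions[lo[i]:hi[i]] - positions[i]
        w = np.exp(-(d * d) / (2.0 * sigma * sigma))
        tot = w.sum()
        a = w / tot
        smoothed[i] = float(a @ sq[lo[i]:hi[i]])
        df[i] = 1.0 / float(a @ a)
    return smoothed, df


def smoothed_pvalues(smoothed: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Chi-square tail p for the Satterthwaite-matched smoothed statistic.

    The smoothed statistic S approximates c * chisq(df) with c * df = 1,
    so P(S >= s) = sf(s * df; df).
    """
    return stats.chi2.sf(np.asarray(smoothed) * np.asarray(df), np.asarray(df))


def call_regions(
    probe_table: pd.DataFrame,
    fdr: float = 0.05,
    gap: float = DEFAULT_LAMBDA,
    min_cpgs: int = 2,
) -> list[DMR]:
    """Chain BH-significant probes into maximal regions.

    ``probe_table`` needs columns chrom, pos, q (region-level BH q per
    probe) and estimate (logit-scale effect, exponentiated into the
    region fold-change).  Consecutive significant probes at most ``gap`` bp
    apart join one run; runs shorter than ``min_cpgs`` are discarded.
    region_q is the minimum member q.
    """
    dmrs: list[DMR] = []
    tab = probe_table.sort_values(["chrom", "pos"], kind="stable")
    for chrom, sub in tab.groupby("chrom", sort=True):
        sig = sub[sub["q"] < fdr]
        if sig.empty:
            continue
        pos = sig["pos"].to_numpy(int)
        breaks = np.flatnonzero(np.diff(pos) > gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            run = sig.iloc[s : e + 1]
            if len(run) < min_cpgs:
                continue
            est = run["estimate"].to_numpy(float)
            extremal = est[np.argmax(np.abs(est))]
            dmrs.append(
                DMR(
                    chrom=str(chrom),
                    start=int(run["pos"].iloc[0]),
                    end=int(run["pos"].iloc[-1]),
                    n_probes=len(run),
                    region_q=float(run["q"].min()),
                    max_fc=float(np.exp(extremal)),
                    probe_ids=[str(i) for i in run.index],
                )
            )
    return dmrs


def filter_fold_change(dmrs: list[DMR], min_fc: float = 2.0) -> list[DMR]:
    """Keep regions with fold-change > min_fc or < 1/min_fc (two-sided)."""
    if min_fc <= 1.0:
        raise UsageError(f"min_fc must exceed 1, got {min_fc}")
    return [d for d in dmrs if d.max_fc > min_fc or d.max_fc < 1.0 / min_fc]


def rank_by_fold_change(dmrs: list[DMR], top: int | None = None) -> list[DMR]:
    """Order by |log fold-change| descending, ties by region_q ascending."""
    ranked = sorted(dmrs, key=lambda d: (-abs(np.log(d.max_fc)), d.region_q))
    return ranked if top is None else ranked[:top]


CONTEXT_CATEGORIES = ("island", "shore", "shelf", "promoter", "enhancer")


def annotate_context(dmrs: list[DMR], manifest: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag each region per category if any member probe carries the flag.

    Returns (per-region context table, summary) where the summary holds the
    category distribution plus per-chromosome counts with the autosome
    mean +/- SD.
    """
    rows = []
    for i, d in enumerate(dmrs):
        sub = manifest.loc[d.probe_ids]
        rows.append(
            {
                "dmr_id": f"DMR{i:05d}",
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_probes": d.n_probes,
                "region_q": d.region_q,
                "max_fc": d.max_fc,
                "island": bool((sub["relation"] == "island").any()),
                "shore": bool((sub["relation"] == "shore").any()),
                "shelf": bool((sub["relation"] == "shelf").any()),
                "promoter": bool(sub["promoter"].any()),
                "enhancer": bool(sub["enhancer"].any()),
            }
        )
    cols = ["dmr_id", "chrom", "start", "end", "n_probes", "region_q", "max_fc",
            *CONTEXT_CATEGORIES]
    table = pd.DataFrame(rows, columns=cols)
    dist = {c: int(table[c].sum()) if len(table) else 0 for c in CONTEXT_CATEGORIES}
    per_chrom = table.groupby("chrom").size() if len(table) else pd.Series(dtype=int)
    autosomes = per_chrom[~per_chrom.index.isin(["chrX", "chrY"])]
    summary = pd.DataFrame(
        {
            "category": list(dist) + ["autosome_mean", "autosome_sd"],
            "count": list(dist.values())
            + [
                float(autosomes.mean()) if len(autosomes) else 0.0,
                float(autosomes.std(ddof=1)) if len(autosomes) > 1 else 0.0,
            ],
        }
    )
    summary.attrs["per_chrom"] = per_chrom.to_dict()
    return table, summary


def enrich_gene_sets(
    sig_probes,
    background_probes,
    gene_sets: dict[str, list[str]],
    probe_to_gene: dict[str, list[str]] | pd.Series,
) -> pd.DataFrame:
    """Probe-density-bias-aware gene-set over-representation.

    Genes are scored significant if hit by any significant probe.  The
    Wallenius odds for a set is the mean probes-per-gene inside the set
    divided by the mean outside, so probe-rich genes are expected to be
    drawn more often under the null.  Genes with zero background probes are
    excluded (counted in a warning).
    """
    sig_probes = set(map(str, sig_probes))
    background_probes = set(map(str, background_probes))
    if not sig_probes <= background_probes:
        raise UsageError("significant probes must be a subset of the background")
    if isinstance(probe_to_gene, pd.Series):
        probe_to_gene = {
            str(k): ([v] if isinstance(v, str) else list(v)) for k, v in probe_to_gene.items()
        }

    probe_count: dict[str, int] = {}
    sig_genes: set[str] = set()
    for probe in background_probes:
        for gene in probe_to_gene.get(probe, []):
            if not gene:
                continue
            probe_count[gene] = probe_count.get(gene, 0) + 1
            if probe in sig_probes:
                sig_genes.add(gene)
    universe = sorted(probe_count)
    n_universe = len(universe)
    n_sig = len(sig_genes)

    rows = []
    n_zero_probe_genes = 0
    for name, genes in gene_sets.items():
        if not genes:
            raise UsageError(f"gene set '{name}' is empty")
        members = [g for g in genes if g in probe_count]
        n_zero_probe_genes += len(genes) - len(members)
        K = len(members)
        if K == 0 or n_sig == 0:
            rows.append((name, K, 0, np.nan, 1.0))
            continue
        k = len(set(members) & sig_genes)
        # per-gene weight: marginal probability of holding >= 1 significant
        # probe when significant probes fall uniformly on the background,
        # 1 - (1 - f)^count; equal counts => equal weights => odds 1
        counts = np.array([probe_count[g] for g in universe], float)
        f = len(sig_probes) / max(len(background_probes), 1)
        weights = 1.0 - np.power(1.0 - min(f, 1.0 - 1e-12), counts)
        in_set = np.isin(np.array(universe), np.array(members))
        w_in = weights[in_set].mean()
        w_out = weights[~in_set].mean() if (~in_set).any() else w_in
        odds = w_in / w_out if w_out > 0 else 1.0
        if abs(odds - 1.0) < 1e-12:
            p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_sig))
        else:
            p = float(
                stats.nchypergeom_wallenius.sf(k - 1, n_universe, K, n_sig, odds)
            )
        rows.append((name, K, k, odds, min(max(p, 0.0), 1.0)))
    if n_zero_probe_genes:
        warnings.warn(
            f"{n_zero_probe_genes} gene-set member(s) had no background probes and were excluded",
            stacklevel=2,
        )
    out = pd.DataFrame(rows, columns=["set", "n_genes", "n_sig_genes", "odds", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["n_zero_probe_genes"] = n_zero_probe_genes
    return out


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED export: 0-based half-open, score = -10 log10(region_q) capped."""
    rows = []
    for i, d in enumerate(dmrs):
        score = min(1000.0, -10.0 * np.log10(max(d.region_q, 1e-100)))
        rows.append((d.chrom, d.start - 1, d.end, f"DMR{i:05d}", round(score, 2)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
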