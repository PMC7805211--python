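"""A/B chromatin-compartment reconstruction from methylation M-values.

Open-sea probes are kNN-imputed, median-summarized into 100 kb bins, and a
per-chromosome bin-by-bin Pearson correlation matrix is eigen-decomposed.
The entries of the unit-norm leading eigenvector are the per-bin
"eigenvalues"; positive entries are A (open), negative B (closed).

The sign of an eigenvector is arbitrary, so each chromosome is oriented so
the eigenvector correlates positively with bin probe density (CpG/gene
dense regions anchor the open compartment); exact ties orient the first
non-missing bin positive.

Cross-group discordance keeps bins whose absolute eigenvalue passes the
filter in BOTH groups and compares signs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import DataError, UsageError

BIN_SIZE = 100_000


def select_open_sea(manifest: pd.DataFrame) -> pd.Index:
    """Probes at least 4 kb from any annotated island (relation open_sea)."""
    return manifest.index[manifest["relation"] == "open_sea"]


def knn_impute(
    m_matrix: pd.DataFrame, k: int = 10, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Impute missing entries from the k nearest probes.

    Rows are probes, columns samples.  Probes missing in strictly more than
    ``max_missing_frac`` of samples are dropped; the rest have NaNs replaced
    by the unweighted mean of the k nearest probe rows under Euclidean
    distance over shared observed columns.  ``k`` is reduced (with a
    warning) when it exceeds the available donor rows.
    """
    vals = m_matrix.to_numpy(float)
    if vals.size == 0:
        return m_matrix.copy()
    missing_frac = np.mean(~np.isfinite(vals), axis=1)
    keep = missing_frac <= max_missing_frac
    kept = m_matrix.loc[keep]
    vals = kept.to_numpy(float)
    if vals.shape[0] == 0:
        return kept.copy()
    if not np.isnan(vals).any():
        return kept.copy()
    n_rows = vals.shape[0]
    if k >= n_rows:
        warnings.warn(
            f"k={k} >= candidate rows ({n_rows}); reducing to {max(1, n_rows - 1)}",
            stacklevel=2,
        )
        k = max(1, n_rows - 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals)
    if filled.shape != vals.shape:  # all-NaN columns would be dropped by sklearn
        raise DataError("imputation dropped columns; a sample has no observed probes")
    return pd.DataFrame(filled, index=kept.index, columns=kept.columns)


def assign_bins(positions: np.ndarray, bin_size: int = BIN_SIZE) -> np.ndarray:
    """Bin index of 1-based positions on a genome anchored at coordinate 0.

    A 1-based position p occupies 0-based coordinate p-1, so its half-open
    bin is (p - 1) // bin_size.
    """
    return (np.asarray(positions, int) - 1) // bin_size


def bin_median(
    m_values: pd.DataFrame,
    manifest: pd.DataFrame,
    bin_size: int = BIN_SIZE,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-summarize probe M-values into genomic bins.

    Returns (binned matrix indexed by (chrom, bin_start_0based), probe count
    per bin).  Bins with no probes simply do not appear (missing, never
    zero-filled).
    """
    sub = manifest.loc[m_values.index]
    bins = assign_bins(sub["pos"].to_numpy(int), bin_size) * bin_size
    key = pd.MultiIndex.from_arrays([sub["chrom"], bins], names=["chrom", "bin_start"])
    grouped = m_values.groupby(key).median()
    grouped.index = pd.MultiIndex.from_tuples(grouped.index, names=["chrom", "bin_start"])
    counts = pd.Series(1, index=key).groupby(level=[0, 1]).sum()
    counts.index.names = ["chrom", "bin_start"]
    return grouped.sort_index(), counts.sort_index()


@dataclasses.dataclass
class CompartmentTrack:
    """Per-group eigenvector track; eigen is NaN for missing/excluded bins."""

    group: str
    bins: pd.DataFrame  # index (chrom, bin_start), columns eigen, label, n_probes

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self.bins.xs(chrom, level="chrom", drop_level=False)


def _orient(vec: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Resolve the eigenvector sign ambiguity deterministically."""
    if len(vec) > 1 and np.std(density) > 0 and np.std(vec) > 0:
        r = np.corrcoef(vec, density)[0, 1]
        if np.isfinite(r) and abs(r) > 1e-12:
            return vec if r > 0 else -vec
    return vec if vec[0] >= 0 else -vec


def infer_track(
    binned: pd.DataFrame,
    n_probes: pd.Series,
    group: str,
    min_samples: int = 3,
    min_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome bin correlation matrix.

    ``binned`` must already be restricted to the group's samples.  Bins with
    zero variance across samples are excluded and reported missing.  A
    chromosome whose correlation matrix is degenerate (constant) raises
    :class:`DataError`.
    """
    if binned.shape[1] < min_samples:
        raise DataError(f"group '{group}' has {binned.shape[1]} samples; need >= {min_samples}")
    frames = []
    for chrom in binned.index.get_level_values("chrom").unique():
        sub = binned.xs(chrom, level="chrom")
        vals = sub.to_numpy(float)
        finite = np.isfinite(vals).all(axis=1)
        variant = finite & (np.nanstd(vals, axis=1) > 0)
        eigen = np.full(len(sub), np.nan)
        if variant.sum() >= min_bins:
            use = vals[variant]
            corr = np.corrcoef(use)
            if not np.all(np.isfinite(corr)):
                raise DataError(f"degenerate correlation matrix on {chrom}")
            evals, evecs = np.linalg.eigh(corr)
            vec = evecs[:, -1]
            vec = vec / np.linalg.norm(vec)
            dens = n_probes.xs(chrom, level="chrom").to_numpy(float)[variant]
            eigen[variant] = _orient(vec, dens)
        labels = np.where(np.isnan(eigen), None, np.where(eigen > 0, "A", "B"))
        frames.append(
            pd.DataFrame(
                {
                    "eigen": eigen,
                    "label": labels,
                    "n_probes": n_probes.xs(chrom, level="chrom").to_numpy(int),
                },
                index=pd.MultiIndex.from_product(
                    [[chrom], sub.index], names=["chrom", "bin_start"]
                ),
            )
        )
    if not frames:
        raise DataError("no chromosomes with enough bins to infer compartments")
    return CompartmentTrack(group=group, bins=pd.concat(frames).sort_index())


@dataclasses.dataclass
class DiscordantCall:
    chrom: str
    bin_start: int
    eigen_a: float
    eigen_b: float
    status: str  # concordant | discordant | filtered


def call_discordance(
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
    min_abs: float = 0.02,
) -> tuple[list[DiscordantCall], float]:
    """Compare eigenvalue signs on the shared bin grid.

    Bins with |eigen| < min_abs in either group are 'filtered'; remaining
    bins are discordant iff the signs differ.  Returns the calls and the
    concordance fraction concordant / (concordant + discordant).
    Bins missing in either track are not comparable and are excluded.
    """
    if min_abs < 0:
        raise UsageError("min_abs must be >= 0")
    a = track_a.bins["eigen"]
    b = track_b.bins["eigen"]
    common = a.index.intersection(b.index)
    calls: list[DiscordantCall] = []
    n_conc = n_disc = 0
    for chrom, bin_start in common:
        ea = float(a.loc[(chrom, bin_start)])
        eb = float(b.loc[(chrom, bin_start)])
        if np.isnan(ea) or np.isnan(eb):
            continue
        if abs(ea) < min_abs or abs(eb) < min_abs:
            status = "filtered"
        elif np.sign(ea) != np.sign(eb):
            status = "discordant"
            n_disc += 1
        else:
            status = "concordant"
            n_conc += 1
        calls.append(DiscordantCall(str(chrom), int(bin_start), ea, eb, status))
    frac = n_conc / (n_conc + n_disc) if (n_conc + n_disc) else float("nan")
    return calls, frac


def track_to_bedgraph(track: CompartmentTrack, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """bedGraph rows (chrom, 0-based half-open start/end, eigenvalue)."""
    rows = []
    for (chrom, bin_start), row in track.bins.iterrows():
        if np.isnan(row["eigen"]):
            continue
        rows.append((chrom, int(bin_start), int(bin_start) + bin_size, row["eigen"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "eigen"])


def track_to_label_bed(track: CompartmentTrack, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """BED of A/B labels (chrom, 0-based half-open start/end, label)."""
    rows = []
    for (chrom, bin_start), row in track.bins.iterrows():
        if row["label"] is None or (isinstance(row["label"], float) and np.isnan(row["label"])):
            continue
        rows.append((chrom, int(bin_start), int(bin_start) + bin_size, row["label"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def calls_to_bed(calls: list[DiscordantCall], bin_size: int = BIN_SIZE) -> pd.DataFrame:
    rows = [
        (c.chrom, c.bin_start, c.bin_start + bin_size, c.status, c.eigen_a, c.eigen_b)
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "status", "eigen_a", "eigen_b"]
    )
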