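"""Probe/sample failure filtering, blacklist removal and beta/M conversion.

Filter order in the pipeline is fixed: detection-failure masking, then
failed-sample removal, then blacklist-probe removal.  Each filter is
idempotent, and sample order never influences which samples are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BetaMatrix
from .errors import DataError, UsageError


def mark_failed(detection_p: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Boolean failure mask: an entry fails iff detection_p >= p_threshold.

    Values strictly below the threshold pass (a detection p-value of 0.005
    passes at the default 0.01 threshold; 0.02 fails).
    """
    if not (0.0 < p_threshold < 1.0):
        raise UsageError(f"p_threshold must be in (0, 1), got {p_threshold}")
    vals = detection_p.to_numpy(float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise DataError("detection p-values must lie in [0, 1]")
    return detection_p >= p_threshold


def drop_failed_samples(
    bm: BetaMatrix, max_fail_frac: float = 0.10, p_threshold: float = 0.01
) -> tuple[BetaMatrix, list[str]]:
    """Remove samples whose fraction of failed probes exceeds ``max_fail_frac``.

    The inequality is strict: a sample with exactly 10.0% failed probes is
    retained at the default threshold.  Survivor order is preserved.

    Returns the filtered matrix (with mask attached) and the dropped ids.
    Raises :class:`DataError` if every sample would be dropped.
    """
    mask = bm.mask if bm.mask is not None else mark_failed(bm.detection_p, p_threshold)
    if bm.n_probes == 0:
        return BetaMatrix(bm.beta, bm.detection_p, mask), []
    fail_frac = mask.mean(axis=0)
    dropped = [s for s in bm.sample_ids if fail_frac[s] > max_fail_frac]
    keep = [s for s in bm.sample_ids if fail_frac[s] <= max_fail_frac]
    if not keep and len(dropped):
        raise DataError("all samples exceed the failed-probe threshold; empty cohort")
    out = bm.subset_samples(keep)
    return BetaMatrix(out.beta, out.detection_p, mask[keep]), dropped


def drop_blacklisted(bm: BetaMatrix, manifest: pd.DataFrame) -> BetaMatrix:
    """Remove probes carrying the manifest blacklist flag.

    Every probe in the matrix must be present in the manifest; a missing
    probe raises a :class:`DataError` naming it.
    """
    missing = bm.probe_ids.difference(manifest.index)
    if len(missing):
        raise DataError(f"probe(s) absent from manifest: {missing[:5].tolist()}")
    flags = manifest["blacklist"].reindex(bm.probe_ids)
    keep = bm.probe_ids[~flags.to_numpy(bool)]
    return bm.subset_probes(keep)


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Smithson–Verkuilen squeeze (y*(n-1)+0.5)/n mapping [0,1] into (0,1)."""
    y = np.asarray(y, float)
    if y.size and (np.nanmin(y) < 0 or np.nanmax(y) > 1):
        raise DataError("beta values must lie in [0, 1]")
    if n is None:
        n = y.shape[-1] if y.ndim > 1 else y.size
    n = max(int(n), 2)
    return (y * (n - 1) + 0.5) / n


def beta_to_m(beta) -> np.ndarray:
    """M-value transform M = log2(beta / (1 - beta)); strictly increasing."""
    b = np.asarray(beta, float)
    if b.size and (np.nanmin(b) <= 0 or np.nanmax(b) >= 1):
        raise DataError("beta_to_m requires beta in the open interval (0, 1)")
    return np.log2(b / (1.0 - b))


def m_to_beta(m) -> np.ndarray:
    """Inverse of :func:`beta_to_m`."""
    x = np.exp2(np.asarray(m, float))
    return x / (1.0 + x)


def run_qc(
    bm: BetaMatrix,
    manifest: pd.DataFrame,
    p_threshold: float = 0.01,
    max_fail_frac: float = 0.10,
) -> tuple[BetaMatrix, dict]:
    """Full QC pass: mask failures, drop failed samples, drop blacklist probes.

    Returns the clean matrix and a counts report (input = retained + dropped
    for both probes and samples).
    """
    mask = mark_failed(bm.detection_p, p_threshold)
    bm = BetaMatrix(bm.beta, bm.detection_p, mask)
    filtered, dropped_samples = drop_failed_samples(bm, max_fail_frac, p_threshold)
    clean = drop_blacklisted(filtered, manifest)
    report = {
        "n_probes_in": int(bm.n_probes),
        "n_probes_out": int(clean.n_probes),
        "n_probes_blacklisted": int(bm.n_probes - clean.n_probes),
        "n_samples_in": int(bm.n_samples),
        "n_samples_out": int(clean.n_samples),
        "dropped_samples": dropped_samples,
        "n_failed_entries": int(mask.to_numpy().sum()),
    }
    return clean, report
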