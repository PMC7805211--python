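"""Tumor-size association: per-probe GLMM, Kendall's tau, delta-beta filter.

The size model differs deliberately from the group contrast: size in mm is
a continuous fixed effect (with age and sex), and the random intercept is
patient only — partially repeated tissue sampling, not slide nesting.

The surviving-probe rule is model q < 0.05, then tau q < 0.05, then
delta-beta (max - min) strictly > 0.2; every intermediate quantity is
recorded per probe so any filter order is auditable.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .betareg import BetaGLMM
from .data import BetaMatrix
from .diffmeth import bh_adjust, lrt_from_logliks
from .errors import DataError
from .qc import squeeze_unit_interval


def kendall_tau(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Kendall's tau-b with tie correction.

    p-value: exact permutation enumeration for n <= ``exact_max_n``,
    otherwise the tau-b normal approximation.  All-tied input raises
    :class:`DataError` (tau undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("kendall_tau requires equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DataError("kendall_tau requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("tau undefined for an all-tied vector")
    tau = _tau_b(x, y)
    if n <= exact_max_n:
        obs = abs(tau)
        taus = np.array([_tau_b(x, np.array(perm)) for perm in itertools.permutations(y)])
        p = float(np.mean(np.abs(taus) >= obs - 1e-12))
    else:
        # tau-b normal approximation with the no-tie variance; ties make
        # this mildly conservative, matching common implementations
        var = 2.0 * (2.0 * n + 5.0) / (9.0 * n * (n - 1.0))
        z = tau / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(tau), p


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    prod = dx[iu] * dy[iu]
    conc_minus_disc = prod.sum()
    tx = np.sum(dx[iu] != 0)
    ty = np.sum(dy[iu] != 0)
    denom = np.sqrt(tx * ty)
    if denom == 0:
        raise DataError("tau undefined: all pairs tied")
    return float(conc_minus_disc / denom)


@dataclasses.dataclass
class SizeHit:
    probe_id: str
    estimate: float
    q_model: float
    tau: float
    q_tau: float
    delta_beta: float
    passes_filter: bool


def fit_size_glmm(
    y: np.ndarray,
    size_mm: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    patient: np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    theta0_pair=None,
) -> dict:
    """One probe's size model: LRT on the size term, patient random intercept.

    Returns a dict with estimate, se, lrt_stat, p, logliks, converged,
    skipped.  A constant size vector yields a skipped record.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y) & np.isfinite(np.asarray(size_mm, float))
    if mask is not None:
        keep &= ~np.asarray(mask, bool)
    y, size_mm = y[keep], np.asarray(size_mm, float)[keep]
    age, sex = np.asarray(age, float)[keep], np.asarray(sex, float)[keep]
    patient = np.asarray(patient)[keep]
    skipped = {"estimate": np.nan, "se": np.nan, "lrt_stat": np.nan, "p": np.nan,
               "converged": False, "skipped": True}
    if y.size < 8 or np.ptp(size_mm) == 0:
        return skipped
    ys = squeeze_unit_interval(y, n=y.size)
    size_c = size_mm - size_mm.mean()
    age_c = (age - age.mean()) / 10.0
    X_full = np.column_stack([np.ones(y.size), size_c, age_c, sex])
    X_red = X_full[:, [0, 2, 3]]
    pat_idx = pd.factorize(patient)[0]
    t_full, t_red = (theta0_pair if theta0_pair is not None else (None, None))
    full = BetaGLMM(ys, X_full, [pat_idx]).fit(tol=tol, max_iter=max_iter, theta0=t_full)
    red = BetaGLMM(ys, X_red, [pat_idx]).fit(tol=tol, max_iter=max_iter, theta0=t_red)
    if full.skipped or red.skipped:
        return skipped
    stat, p = lrt_from_logliks(full.loglik, red.loglik)
    converged = bool(full.converged and red.converged)
    return {
        "estimate": float(full.coef[1]),
        "se": float(full.se[1]),
        "lrt_stat": stat,
        "p": p if converged else np.nan,
        "converged": converged,
        "skipped": False,
        "theta_full": full.theta,
        "theta_red": red.theta,
    }


def delta_beta(beta_row: np.ndarray) -> float:
    """Max beta minus min beta across the samples used."""
    v = np.asarray(beta_row, float)
    v = v[np.isfinite(v)]
    return float(v.max() - v.min()) if v.size else np.nan


def size_scan(
    bm: BetaMatrix,
    samples: pd.DataFrame,
    group: str = "CNF",
    q_model: float = 0.05,
    q_tau: float = 0.05,
    min_delta: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Full size-association pipeline for one group's samples.

    Stage 1: per-probe GLMM with the size term, BH across probes.
    Stage 2: Kendall's tau on model-significant probes, BH across them.
    Stage 3: delta-beta strictly > ``min_delta``.
    """
    sel = samples[samples["group"] == group]
    if sel.empty:
        raise DataError(f"no samples in group '{group}'")
    sizes = sel["size_mm"].to_numpy(float)
    if not np.isfinite(sizes).any():
        raise DataError(f"group '{group}' has no size measurements")
    sub = bm.subset_samples(sel.index)
    mask = sub.mask.to_numpy(bool) if sub.mask is not None else None
    beta = sub.beta.to_numpy(float)
    age = sel["age"].to_numpy(float)
    sex = (sel["sex"].astype(str).str.upper().isin(["M", "MALE", "1"])).to_numpy(float)
    patient = sel["patient_id"].to_numpy()

    records = []
    # order-invariant warm start from the lexicographically first probe
    thetas = None
    if len(sub.probe_ids):
        ai = int(np.argsort(sub.probe_ids)[0])
        am = mask[ai] if mask is not None else None
        ar = fit_size_glmm(beta[ai], sizes, age, sex, patient, am, tol, max_iter)
        if ar.get("converged"):
            thetas = (ar["theta_full"], ar["theta_red"])
    for i, probe in enumerate(sub.probe_ids):
        pm = mask[i] if mask is not None else None
        r = fit_size_glmm(beta[i], sizes, age, sex, patient, pm, tol, max_iter, thetas)
        r.pop("theta_full", None)
        r.pop("theta_red", None)
        r["probe_id"] = str(probe)
        records.append(r)
    df = pd.DataFrame(records).set_index("probe_id")
    df["q_model"] = bh_adjust(df["p"].to_numpy())

    df["tau"] = np.nan
    df["p_tau"] = np.nan
    model_sig = df.index[(df["q_model"] < q_model) & df["converged"].fillna(False)]
    for probe in model_sig:
        i = sub.probe_ids.get_loc(probe)
        row = beta[i].copy()
        if mask is not None:
            row[mask[i]] = np.nan
        ok = np.isfinite(row) & np.isfinite(sizes)
        try:
            tau, p = kendall_tau(sizes[ok], row[ok])
        except DataError:
            continue
        df.loc[probe, ["tau", "p_tau"]] = (tau, p)
    df["q_tau"] = np.nan
    if len(model_sig):
        df.loc[model_sig, "q_tau"] = bh_adjust(df.loc[model_sig, "p_tau"].to_numpy())

    deltas = []
    for i in range(beta.shape[0]):
        row = beta[i].copy()
        if mask is not None:
            row[mask[i]] = np.nan
        deltas.append(delta_beta(row))
    df["delta_beta"] = deltas
    df["passes_filter"] = (
        (df["q_model"] < q_model).fillna(False)
        & (df["q_tau"] < q_tau).fillna(False)
        & (df["delta_beta"] > min_delta).fillna(False)
    )
    return df
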