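"""End-to-end driver: qc -> dmp -> dmr -> compartments -> size -> enrich.

Every stage logs record counts (input = retained + dropped) into a
machine-readable run log; identical (config, inputs) runs write
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import compartments as comp
from . import dmr as dmrmod
from .config import PipelineConfig
from .data import read_gmt
from .diffmeth import scan_probes, select_dmps, select_high_effect
from .errors import DataError
from .qc import beta_to_m, run_qc, squeeze_unit_interval
from .size import size_scan
from .synthetic import read_fixture

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index: bool = True, **kw) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, **kw)


def compartment_stage(bm, samples, manifest, groups, bin_size=comp.BIN_SIZE, min_abs=0.02):
    """Open-sea M-values -> kNN impute -> 100 kb medians -> per-group tracks."""
    open_sea = comp.select_open_sea(manifest).intersection(bm.probe_ids)
    sub = bm.subset_probes(open_sea)
    beta = sub.beta.copy()
    if sub.mask is not None:
        beta = beta.mask(sub.mask)
    squeezed = squeeze_unit_interval(beta.to_numpy(float), n=beta.shape[1])
    m = pd.DataFrame(beta_to_m(squeezed), index=beta.index, columns=beta.columns)
    m[~np.isfinite(beta)] = np.nan
    m = comp.knn_impute(m)
    tracks = {}
    for group in groups:
        ids = samples.index[samples["group"] == group].intersection(m.columns)
        binned, counts = comp.bin_median(m[ids], manifest, bin_size)
        tracks[group] = comp.infer_track(binned, counts, group)
    calls, frac = comp.call_discordance(tracks[groups[0]], tracks[groups[1]], min_abs)
    return tracks, calls, frac


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run log dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": json.loads(json.dumps(config.__dict__, default=list)),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        log["failed_stage"] = stage
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
        raise DataError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # ---- load + qc
    try:
        bm, samples, manifest, _truth = read_fixture(config.input_dir)
        for g in config.contrast:
            if g not in set(samples["group"]):
                raise DataError(f"contrast group '{g}' absent from sample sheet")
        clean, qc_report = run_qc(bm, manifest, config.p_threshold, config.max_fail_frac)
        samples = samples.loc[clean.sample_ids]
        log["stages"]["qc"] = qc_report
    except Exception as e:  # noqa: BLE001
        fail("qc", e)

    # ---- differential methylation
    try:
        fits = scan_probes(clean, samples, config.contrast, manifest)
        dmps = select_dmps(fits, config.q_dmp)
        high = select_high_effect(fits, config.or_threshold)
        _write(fits, out / "dmps.tsv")
        log["stages"]["dmp"] = {
            "n_probes": int(len(fits)),
            "n_converged": int(fits["converged"].sum()),
            "n_dmps": int(len(dmps)),
            "n_high_effect": int(len(high)),
        }
    except Exception as e:  # noqa: BLE001
        fail("dmp", e)

    # ---- DMR calling
    try:
        conv = fits[fits["converged"].astype(bool)].copy()
        smoothed_parts = []
        for chrom, sub in conv.sort_values(["chrom", "pos"]).groupby("chrom"):
            sm, df_eff = dmrmod.kernel_smooth(
                sub["pos"].to_numpy(float), sub["wald"].to_numpy(float),
                config.dmr_lambda, config.dmr_C,
            )
            part = sub[["chrom", "pos", "estimate"]].copy()
            part["p_region"] = dmrmod.smoothed_pvalues(sm, df_eff)
            smoothed_parts.append(part)
        smooth_tab = pd.concat(smoothed_parts)
        smooth_tab["q"] = dmrmod.bh_adjust(smooth_tab["p_region"].to_numpy())
        dmrs = dmrmod.call_regions(
            smooth_tab, config.dmr_fdr, config.dmr_lambda, config.min_cpgs
        )
        dmrs_fc = dmrmod.filter_fold_change(dmrs, config.min_fc)
        table, summary = dmrmod.annotate_context(dmrs, manifest)
        _write(table, out / "dmrs.tsv", index=False)
        _write(dmrmod.dmrs_to_bed(dmrs), out / "dmrs.bed", index=False, header=False)
        _write(summary, out / "dmr_context.tsv", index=False)
        log["stages"]["dmr"] = {
            "n_regions": len(dmrs),
            "n_regions_fc": len(dmrs_fc),
            "per_chrom": summary.attrs["per_chrom"],
        }
    except Exception as e:  # noqa: BLE001
        fail("dmr", e)

    # ---- compartments
    try:
        tracks, calls, frac = compartment_stage(
            clean, samples, manifest, config.contrast, config.bin_size, config.min_abs_eigen
        )
        for group, track in tracks.items():
            _write(
                comp.track_to_bedgraph(track, config.bin_size),
                out / f"compartments_{group}.bedgraph", index=False, header=False,
            )
            _write(
                comp.track_to_label_bed(track, config.bin_size),
                out / f"compartments_{group}_labels.bed", index=False, header=False,
            )
        _write(comp.calls_to_bed(calls, config.bin_size), out / "discordance.bed", index=False)
        status = pd.Series([c.status for c in calls])
        log["stages"]["compartments"] = {
            "n_bins": len(calls),
            "n_concordant": int((status == "concordant").sum()),
            "n_discordant": int((status == "discordant").sum()),
            "n_filtered": int((status == "filtered").sum()),
            "concordance_fraction": None if np.isnan(frac) else float(frac),
        }
    except Exception as e:  # noqa: BLE001
        fail("compartments", e)

    # ---- size association
    try:
        has_size = samples["size_mm"].notna() & (samples["group"] == config.size_group)
        if has_size.sum() >= 8:
            hits = size_scan(clean, samples, config.size_group,
                             min_delta=config.min_delta_beta)
            _write(hits, out / "size_hits.tsv")
            log["stages"]["size"] = {
                "n_probes": int(len(hits)),
                "n_model_sig": int((hits["q_model"] < 0.05).sum()),
                "n_pass": int(hits["passes_filter"].sum()),
            }
        else:
            log["stages"]["size"] = {"skipped": "not enough sized samples"}
    except Exception as e:  # noqa: BLE001
        fail("size", e)

    # ---- enrichment
    try:
        gmt = Path(config.input_dir) / "gene_sets.gmt"
        if gmt.exists() and len(dmps):
            gene_sets = read_gmt(gmt)
            enr = dmrmod.enrich_gene_sets(
                dmps, fits.index, gene_sets, manifest["gene"].reindex(fits.index)
            )
            _write(enr, out / "enrichment.tsv", index=False)
            log["stages"]["enrich"] = {
                "n_sets": len(enr),
                "n_sig": int((enr["q"] < 0.05).sum()),
            }
        else:
            log["stages"]["enrich"] = {"skipped": "no gene_sets.gmt or no DMPs"}
    except Exception as e:  # noqa: BLE001
        fail("enrich", e)

    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return log


def recovery_metrics(config: PipelineConfig, truth) -> dict:
    """Compare pipeline outputs under ``config.out_dir`` against a SimTruth."""
    out = Path(config.out_dir)
    metrics: dict = {}
    fits = pd.read_csv(out / "dmps.tsv", sep="\t", index_col="probe_id")
    called = set(fits.index[(fits["q"] < config.q_dmp) & fits["converged"]])
    planted = set(truth.dmp_probe_ids) & set(fits.index)
    if planted:
        tp = len(called & planted)
        metrics["dmp_sensitivity"] = tp / len(planted)
        metrics["dmp_fdr"] = (len(called) - tp) / max(len(called), 1)
    if truth.dmr_intervals:
        dmrs = pd.read_csv(out / "dmrs.tsv", sep="\t")
        jaccards = []
        for chrom, start, end, _delta in truth.dmr_intervals:
            best = 0.0
            for _, row in dmrs[dmrs["chrom"] == chrom].iterrows():
                inter = max(0, min(end, row["end"]) - max(start, row["start"]) + 1)
                union = (end - start + 1) + (row["end"] - row["start"] + 1) - inter
                best = max(best, inter / union if union else 0.0)
            jaccards.append(best)
        metrics["dmr_jaccard_mean"] = float(np.mean(jaccards))
    return metrics
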