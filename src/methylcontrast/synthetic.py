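"""Synthetic EPIC-like cohort generation with a planted-truth record.

The generator emulates the hierarchical structure the downstream models
assume: patients nested within array slides, beta-distributed probe noise
with shared precision, planted group effects on the logit scale, planted
DMR intervals, per-chromosome compartment block structure with
group-discordant blocks, size-associated probes, and random probe failures.

logit(mu) = baseline + group_effect + slide_u + patient_u
            + size_slope * (size - size_center)            (planted probes)
            + amplitude * block_label * chrom_factor       (open-sea probes)

and y ~ Beta(mu * phi, (1 - mu) * phi), clamped into (0, 1).

Identical (config, seed) pairs regenerate byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import data as dio
from .data import BetaMatrix
from .errors import ConfigurationError

GROUPS = ("CNF", "PNF")
_CLAMP = 1e-6


@dataclasses.dataclass
class SimConfig:
    """Cohort-generator configuration; all stochastic choices flow from seed."""

    n_probes: int = 1000
    n_patients_per_group: int = 15
    tumors_per_patient: int = 2
    n_normal: int = 0
    n_slides: int = 6
    chrom_layout: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),)
    mean_gap_bp: float = 1500.0
    baseline_logit_mean: float = 0.0
    baseline_logit_sd: float = 1.0
    sigma_slide: float = 0.25
    sigma_patient: float = 0.25
    phi: float = 50.0
    group_effect_delta: float = 1.0
    frac_dmp: float = 0.0
    dmp_sign_mixed: bool = False
    dmr_blocks: tuple[tuple[str, int, int, float], ...] = ()
    island_len: int = 1000
    island_spacing: int = 50_000
    compartment_block_len: int = 500_000
    compartment_amplitude: float = 0.0
    frac_discordant_blocks: float = 0.0
    size_effect_slope: float = 0.0
    frac_size_probes: float = 0.0
    size_mm_range: tuple[float, float] = (2.0, 20.0)
    detection_fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        pos_fields = [
            "n_probes", "n_patients_per_group", "tumors_per_patient", "n_slides",
            "mean_gap_bp", "island_len", "island_spacing", "compartment_block_len",
        ]
        for f in pos_fields:
            if getattr(self, f) <= 0:
                raise ConfigurationError(f, "must be positive")
        for f in ("frac_dmp", "frac_discordant_blocks", "frac_size_probes",
                  "detection_fail_rate"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f, f"fraction must be in [0, 1], got {v}")
        if self.phi <= 0:
            raise ConfigurationError("phi", "precision must be > 0")
        if self.sigma_slide < 0 or self.sigma_patient < 0:
            raise ConfigurationError("sigma_slide/sigma_patient", "must be >= 0")
        if self.n_normal < 0:
            raise ConfigurationError("n_normal", "must be >= 0")
        if not self.chrom_layout:
            raise ConfigurationError("chrom_layout", "needs at least one chromosome")
        for name, length in self.chrom_layout:
            if length <= 0:
                raise ConfigurationError("chrom_layout", f"{name} length must be positive")
        if self.size_mm_range[0] >= self.size_mm_range[1]:
            raise ConfigurationError("size_mm_range", "low bound must be < high bound")


@dataclasses.dataclass
class SimTruth:
    """Planted effects, recorded for parameter-recovery tests."""

    dmp_probe_ids: list[str]
    dmr_intervals: list[tuple[str, int, int, float]]
    compartment_blocks: list[dict]   # chrom, start, end (1-based incl), label per group
    discordant_blocks: list[int]     # indices into compartment_blocks
    size_probe_ids: list[str]
    probe_effects: dict[str, float]  # signed logit group effect, planted probes only
    baseline_logit: list[float]      # per probe, manifest order
    size_center_mm: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["dmr_intervals"] = [tuple(t) for t in d["dmr_intervals"]]
        return cls(**d)


def island_relation(pos: int, islands: np.ndarray) -> str:
    """Relation of a 1-based position to island segments [(start, end), ...].

    island: inside a segment; shore: gap 1..2000 bp; shelf: 2001..3999 bp;
    open_sea: >= 4000 bp (or no islands at all).
    """
    if islands.size == 0:
        return "open_sea"
    starts, ends = islands[:, 0], islands[:, 1]
    inside = (pos >= starts) & (pos <= ends)
    if inside.any():
        return "island"
    dist = np.minimum(np.abs(pos - starts), np.abs(pos - ends)).min()
    if dist <= 2000:
        return "shore"
    if dist < 4000:
        return "shelf"
    return "open_sea"


def _chrom_islands(length: int, island_len: int, spacing: int) -> np.ndarray:
    starts = np.arange(spacing // 2, length - island_len, spacing, dtype=int)
    if starts.size == 0:
        return np.empty((0, 2), int)
    return np.column_stack([starts + 1, starts + island_len])  # 1-based inclusive


def _place_probes(cfg: SimConfig, rng, blocks_by_chrom, density_labels) -> pd.DataFrame:
    """Draw probe positions per chromosome as cumulative exponential gaps.

    Compartment A-blocks (reference label +1) receive double probe density so
    the eigenvector orientation anchor (probe density) is informative.
    """
    total_len = sum(l for _, l in cfg.chrom_layout)
    recs = []
    for chrom, length in cfg.chrom_layout:
        n_c = max(2, int(round(cfg.n_probes * length / total_len)))
        gaps = rng.exponential(cfg.mean_gap_bp, n_c)
        labels = density_labels.get(chrom)
        if labels is not None and cfg.compartment_amplitude > 0:
            # walk positions sequentially, halving the gap inside A blocks
            pos_list: list[int] = []
            pos = 0.0
            for g in gaps:
                blk = min(int(pos) // cfg.compartment_block_len, len(labels) - 1)
                pos += g * (0.5 if labels[blk] > 0 else 1.0)
                pos_list.append(int(round(pos)))
            pos_arr = np.array(pos_list, float)
        else:
            pos_arr = np.round(np.cumsum(gaps))
        if pos_arr[-1] >= length:
            pos_arr = pos_arr * (length - 1) / pos_arr[-1]
        pos_arr = np.maximum.accumulate(np.round(pos_arr).astype(int))
        # enforce strictly increasing 1-based positions
        pos_arr = pos_arr + np.arange(n_c)
        pos_arr = np.clip(pos_arr + 1, 1, None)
        for p in pos_arr:
            recs.append((chrom, int(p)))
    # inject probes so every requested DMR block holds >= 2 probes
    have = {}
    for chrom, p in recs:
        have.setdefault(chrom, []).append(p)
    for chrom, start, end, _delta in cfg.dmr_blocks:
        inside = [p for p in have.get(chrom, []) if start <= p <= end]
        needed = 2 - len(inside)
        for k in range(max(0, needed)):
            newp = int(start + (end - start) * (k + 1) / (needed + 1))
            recs.append((chrom, newp))
            have.setdefault(chrom, []).append(newp)
    recs.sort(key=lambda t: ([c for c, _ in cfg.chrom_layout].index(t[0]), t[1]))
    # dedupe identical positions
    out, seen = [], set()
    for chrom, p in recs:
        while (chrom, p) in seen:
            p += 1
        seen.add((chrom, p))
        out.append((chrom, p))
    df = pd.DataFrame(out, columns=["chrom", "pos"])
    df.index = pd.Index([f"cg{i:08d}" for i in range(len(df))], name="probe_id")
    return df


def _make_samples(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    size_lo, size_hi = cfg.size_mm_range
    pid = 0
    for group in GROUPS:
        for _ in range(cfg.n_patients_per_group):
            patient = f"PT{pid:03d}"
            slide = f"SL{pid % cfg.n_slides:02d}"
            age = int(rng.integers(20, 71))
            sex = "F" if rng.random() < 0.5 else "M"
            for t in range(cfg.tumors_per_patient):
                size = float(np.round(rng.uniform(size_lo, size_hi), 2)) if group == "CNF" else np.nan
                rows.append((f"{patient}_T{t}", patient, slide, group, age, sex, size))
            pid += 1
    for _ in range(cfg.n_normal):
        patient = f"PT{pid:03d}"
        slide = f"SL{pid % cfg.n_slides:02d}"
        age = int(rng.integers(20, 71))
        sex = "F" if rng.random() < 0.5 else "M"
        rows.append((f"{patient}_T0", patient, slide, "normal", age, sex, np.nan))
        pid += 1
    df = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "slide_id", "group", "age", "sex", "size_mm"]
    ).set_index("sample_id")
    return df


def simulate_cohort(cfg: SimConfig) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (BetaMatrix, sample sheet, manifest, truth) from config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # compartment reference blocks (alternating labels) and discordance plan
    blocks, density_labels, discordant_idx = [], {}, []
    if cfg.compartment_amplitude > 0:
        bi = 0
        all_block_ids = []
        for chrom, length in cfg.chrom_layout:
            n_blocks = max(1, length // cfg.compartment_block_len)
            labels = np.array([1 if k % 2 == 0 else -1 for k in range(n_blocks)])
            density_labels[chrom] = labels
            for k in range(n_blocks):
                start = k * cfg.compartment_block_len + 1
                end = min((k + 1) * cfg.compartment_block_len, length)
                blocks.append(
                    {"chrom": chrom, "start": int(start), "end": int(end),
                     "labels": {g: int(labels[k]) for g in GROUPS}}
                )
                all_block_ids.append(bi)
                bi += 1
        n_disc = int(np.floor(cfg.frac_discordant_blocks * len(blocks)))
        discordant_idx = sorted(rng.choice(len(blocks), size=n_disc, replace=False).tolist()) if n_disc else []
        for i in discordant_idx:
            blocks[i]["labels"]["PNF"] = -blocks[i]["labels"]["PNF"]

    manifest = _place_probes(cfg, rng, blocks, density_labels)
    n_probes = len(manifest)

    # island relations
    islands_by_chrom = {
        chrom: _chrom_islands(length, cfg.island_len, cfg.island_spacing)
        for chrom, length in cfg.chrom_layout
    }
    manifest["relation"] = [
        island_relation(p, islands_by_chrom[c])
        for c, p in zip(manifest["chrom"], manifest["pos"])
    ]
    # gene / promoter / enhancer / blacklist annotation: genes tile the genome
    gene_span = 100_000
    manifest["gene"] = [
        f"G_{c}_{(p - 1) // gene_span:04d}" for c, p in zip(manifest["chrom"], manifest["pos"])
    ]
    tss_offset = (manifest["pos"].to_numpy(int) - 1) % gene_span
    manifest["promoter"] = tss_offset <= 1500
    manifest["enhancer"] = (tss_offset >= 60_000) & (tss_offset <= 62_000)
    manifest["blacklist"] = rng.random(n_probes) < 0.02

    samples = _make_samples(cfg, rng)
    n_samples = len(samples)

    # planted probe sets
    eligible = np.arange(n_probes)
    n_dmp = int(np.floor(cfg.frac_dmp * n_probes))
    dmp_idx = np.sort(rng.choice(eligible, size=n_dmp, replace=False)) if n_dmp else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_dmp) if cfg.dmp_sign_mixed else np.ones(n_dmp)
    effect = np.zeros(n_probes)
    effect[dmp_idx] = cfg.group_effect_delta * signs

    dmr_intervals = []
    for chrom, start, end, delta in cfg.dmr_blocks:
        inside = manifest.index[
            (manifest["chrom"] == chrom)
            & (manifest["pos"] >= start)
            & (manifest["pos"] <= end)
        ]
        ilocs = manifest.index.get_indexer(inside)
        effect[ilocs] += delta
        dmr_intervals.append((chrom, int(start), int(end), float(delta)))

    n_size = int(np.floor(cfg.frac_size_probes * n_probes))
    size_idx = np.sort(rng.choice(eligible, size=n_size, replace=False)) if n_size else np.array([], int)

    baseline = rng.normal(cfg.baseline_logit_mean, cfg.baseline_logit_sd, n_probes)

    # sample-level structure; random intercepts are drawn independently per
    # probe (matching the per-probe model fitted downstream — a slide or
    # repeat-sampling effect perturbs each probe's methylation independently)
    slide_levels, slide_codes = np.unique(samples["slide_id"], return_inverse=True)
    patient_levels, patient_codes = np.unique(samples["patient_id"], return_inverse=True)
    slide_u = rng.normal(0.0, cfg.sigma_slide, (n_probes, len(slide_levels)))
    patient_u = rng.normal(0.0, cfg.sigma_patient, (n_probes, len(patient_levels)))
    is_pnf = (samples["group"] == "PNF").to_numpy()
    is_cnf = (samples["group"] == "CNF").to_numpy()

    eta = baseline[:, None] + np.zeros((n_probes, n_samples))
    eta += slide_u[:, slide_codes] + patient_u[:, patient_codes]
    eta[:, is_pnf] += effect[:, None]

    size_center = float(np.mean(cfg.size_mm_range))
    if n_size and cfg.size_effect_slope != 0.0:
        sizes = samples["size_mm"].to_numpy(float)
        size_dev = np.where(is_cnf, np.nan_to_num(sizes - size_center), 0.0)
        eta[size_idx, :] += cfg.size_effect_slope * size_dev[None, :]

    # compartment signal: shared per-sample chromosome factor times block label
    if cfg.compartment_amplitude > 0:
        chrom_names = [c for c, _ in cfg.chrom_layout]
        factors = rng.normal(0.0, 1.0, (len(chrom_names), n_samples))
        group_of = samples["group"].to_numpy()
        open_sea = (manifest["relation"] == "open_sea").to_numpy()
        chrom_arr = manifest["chrom"].to_numpy()
        pos_arr = manifest["pos"].to_numpy(int)
        label_lookup = {}
        for b in blocks:
            for g in GROUPS:
                label_lookup[(b["chrom"], (b["start"] - 1) // cfg.compartment_block_len, g)] = b["labels"][g]
        for ci, chrom in enumerate(chrom_names):
            on_chrom = (chrom_arr == chrom) & open_sea
            if not on_chrom.any():
                continue
            blk_of_probe = (pos_arr[on_chrom] - 1) // cfg.compartment_block_len
            for si in range(n_samples):
                g = group_of[si]
                if g not in GROUPS:
                    continue
                labels = np.array(
                    [label_lookup.get((chrom, int(b), g), 0) for b in blk_of_probe], float
                )
                eta[on_chrom, si] += cfg.compartment_amplitude * labels * factors[ci, si]

    mu = expit(eta)
    beta_vals = rng.beta(mu * cfg.phi, (1.0 - mu) * cfg.phi)
    beta_vals = np.clip(beta_vals, _CLAMP, 1.0 - _CLAMP)

    detp = rng.uniform(0.0, 0.009, (n_probes, n_samples))
    if cfg.detection_fail_rate > 0:
        fail = rng.random((n_probes, n_samples)) < cfg.detection_fail_rate
        detp = np.where(fail, rng.uniform(0.02, 1.0, (n_probes, n_samples)), detp)

    beta_df = pd.DataFrame(beta_vals, index=manifest.index, columns=samples.index)
    detp_df = pd.DataFrame(detp, index=manifest.index, columns=samples.index)
    bm = BetaMatrix(beta_df, detp_df)

    truth = SimTruth(
        dmp_probe_ids=manifest.index[dmp_idx].tolist(),
        dmr_intervals=dmr_intervals,
        compartment_blocks=blocks,
        discordant_blocks=list(discordant_idx),
        size_probe_ids=manifest.index[size_idx].tolist(),
        probe_effects={
            str(manifest.index[i]): float(effect[i]) for i in np.nonzero(effect)[0]
        },
        baseline_logit=[float(b) for b in baseline],
        size_center_mm=size_center,
    )
    return bm, samples, dio.validate_manifest(manifest[dio.MANIFEST_COLUMNS]), truth


def make_gene_sets(manifest: pd.DataFrame, rng_or_seed=0, n_sets: int = 10, set_size: int = 15) -> dict:
    """Random gene sets over the manifest's gene universe (GMT payload)."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    genes = sorted({g for g in manifest["gene"] if g})
    sets = {}
    for i in range(n_sets):
        k = min(set_size, len(genes))
        sets[f"SET_{i:02d}"] = sorted(rng.choice(genes, size=k, replace=False).tolist())
    return sets


def write_fixture(dir_path, bm: BetaMatrix, samples: pd.DataFrame, manifest: pd.DataFrame,
                  truth: SimTruth | None = None, gene_sets: dict | None = None) -> list[Path]:
    """Write the plain-text fixture files; round-trips losslessly."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    dio.write_beta_matrix(bm, d / "beta.tsv", d / "detp.tsv")
    written += [d / "beta.tsv", d / "detp.tsv"]
    dio.write_samples(samples, d / "samples.csv")
    written.append(d / "samples.csv")
    dio.write_manifest(manifest, d / "manifest.tsv")
    written.append(d / "manifest.tsv")
    if truth is not None:
        (d / "truth.json").write_text(truth.to_json())
        written.append(d / "truth.json")
    if gene_sets is not None:
        dio.write_gmt(gene_sets, d / "gene_sets.gmt")
        written.append(d / "gene_sets.gmt")
    return written


def read_fixture(dir_path):
    """Read a fixture directory back; returns (bm, samples, manifest, truth | None)."""
    d = Path(dir_path)
    bm = dio.read_beta_matrix(d / "beta.tsv", d / "detp.tsv")
    samples = dio.read_samples(d / "samples.csv")
    manifest = dio.read_manifest(d / "manifest.tsv")
    truth = None
    if (d / "truth.json").exists():
        truth = SimTruth.from_json((d / "truth.json").read_text())
    return bm, samples, manifest, truth
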