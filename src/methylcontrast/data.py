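"""Core data containers and plain-text readers/writers.

All genomic coordinates held in memory are 1-based inclusive.  Conversion to
0-based half-open happens only at BED/bedGraph export boundaries.

Fixture directory layout::

    beta.tsv       probe rows x sample columns, tab separated
    detp.tsv       detection p-values, same shape as beta.tsv
    samples.csv    sample_id,patient_id,slide_id,group,age,sex,size_mm
    manifest.tsv   probe_id,chrom,pos,relation,gene,promoter,enhancer,blacklist
    truth.json     planted-effect record (synthetic cohorts only)
    gene_sets.gmt  optional GMT gene sets (synthetic cohorts only)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

RELATIONS = ("island", "shore", "shelf", "open_sea")

SAMPLE_COLUMNS = ["patient_id", "slide_id", "group", "age", "sex", "size_mm"]
MANIFEST_COLUMNS = ["chrom", "pos", "relation", "gene", "promoter", "enhancer", "blacklist"]


@dataclasses.dataclass
class BetaMatrix:
    """Probes x samples methylation fractions plus detection p-values.

    ``beta`` and ``detection_p`` share index (probe ids) and columns
    (sample ids).  ``mask`` is True where the measurement failed detection
    (computed lazily by :func:`methylcontrast.qc.mark_failed`) or is missing.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise DataError(
                f"beta shape {self.beta.shape} != detection_p shape {self.detection_p.shape}"
            )
        if not self.beta.index.equals(self.detection_p.index) or not self.beta.columns.equals(
            self.detection_p.columns
        ):
            raise DataError("beta and detection_p must share probe and sample ids")
        if self.mask is not None and self.mask.shape != self.beta.shape:
            raise DataError("mask shape does not match beta shape")
        vals = self.beta.to_numpy(float)
        finite = np.isfinite(vals)
        if self.mask is not None:
            finite = finite | self.mask.to_numpy(bool)
        if not finite.all():
            raise DataError("beta contains non-finite values outside the missing mask")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.copy(),
            self.detection_p.copy(),
            None if self.mask is None else self.mask.copy(),
        )

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.loc[probe_ids],
            self.detection_p.loc[probe_ids],
            None if self.mask is None else self.mask.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(
            self.beta[sample_ids],
            self.detection_p[sample_ids],
            None if self.mask is None else self.mask[sample_ids],
        )


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest (indexed by probe_id) and return it.

    Required columns: chrom, pos (1-based), relation, gene, promoter,
    enhancer, blacklist.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataError(f"manifest missing columns: {missing}")
    if manifest.index.has_duplicates:
        dupes = manifest.index[manifest.index.duplicated()][:3].tolist()
        raise DataError(f"duplicate probe ids in manifest, e.g. {dupes}")
    if len(manifest) and (manifest["pos"].to_numpy(int) < 1).any():
        raise DataError("manifest positions must be >= 1 (1-based)")
    bad = set(manifest["relation"].unique()) - set(RELATIONS)
    if bad:
        raise DataError(f"unknown island relation values: {sorted(bad)}")
    return manifest


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DataError(f"sample sheet missing columns: {missing}")
    if samples.index.has_duplicates:
        raise DataError("duplicate sample ids in sample sheet")
    return samples


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------

# %.17g guarantees exact binary64 round-trips through text
_FLOAT_FMT = "%.17g"


def write_matrix_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)


def read_matrix_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def read_beta_matrix(beta_path, detp_path) -> BetaMatrix:
    return BetaMatrix(read_matrix_tsv(Path(beta_path)), read_matrix_tsv(Path(detp_path)))


def write_beta_matrix(bm: BetaMatrix, beta_path, detp_path) -> None:
    write_matrix_tsv(Path(beta_path), bm.beta)
    write_matrix_tsv(Path(detp_path), bm.detection_p)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path),
        sep="\t",
        index_col="probe_id",
        dtype={"chrom": str, "gene": str},
        keep_default_na=False,
        na_values=[""],
    )
    df.index = df.index.astype(str)
    df["gene"] = df["gene"].fillna("")
    for col in ("promoter", "enhancer", "blacklist"):
        df[col] = df[col].astype(bool)
    df["pos"] = df["pos"].astype(int)
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(Path(path), sep="\t", index_label="probe_id")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path),
        index_col="sample_id",
        dtype={"patient_id": str, "slide_id": str},
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    validate_samples(samples).to_csv(Path(path), index_label="sample_id", float_format=_FLOAT_FMT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(Path(path), "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
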