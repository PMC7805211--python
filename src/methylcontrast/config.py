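"""Pipeline configuration: flat YAML-compatible key-value file."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and paths for one end-to-end run."""

    input_dir: str = "."
    out_dir: str = "out"
    contrast: tuple[str, str] = ("CNF", "PNF")
    p_threshold: float = 0.01
    max_fail_frac: float = 0.10
    q_dmp: float = 0.05
    or_threshold: float = 4.0
    dmr_lambda: float = 1000.0
    dmr_C: float = 2.0
    dmr_fdr: float = 0.05
    min_cpgs: int = 2
    min_fc: float = 2.0
    bin_size: int = 100_000
    min_abs_eigen: float = 0.02
    size_group: str = "CNF"
    min_delta_beta: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        domains = {
            "p_threshold": (0.0, 1.0, False),
            "max_fail_frac": (0.0, 1.0, True),
            "q_dmp": (0.0, 1.0, False),
            "dmr_fdr": (0.0, 1.0, False),
            "min_delta_beta": (0.0, 1.0, True),
        }
        for field, (lo, hi, closed) in domains.items():
            v = getattr(self, field)
            ok = lo <= v <= hi if closed else lo < v < hi
            if not ok:
                raise ConfigurationError(field, f"must be in {'[' if closed else '('}{lo}, {hi}{']' if closed else ')'}")
        if self.or_threshold <= 1:
            raise ConfigurationError("or_threshold", "must exceed 1")
        if self.min_fc <= 1:
            raise ConfigurationError("min_fc", "must exceed 1")
        for field in ("dmr_lambda", "dmr_C", "bin_size", "min_cpgs"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(field, "must be positive")
        if self.min_abs_eigen < 0:
            raise ConfigurationError("min_abs_eigen", "must be >= 0")
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ConfigurationError("contrast", "needs two distinct group labels")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["contrast"] = list(self.contrast)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        try:
            is_file = Path(str(path_or_text)).exists()
        except OSError:  # e.g. inline YAML text longer than NAME_MAX
            is_file = False
        text = Path(path_or_text).read_text() if is_file else str(path_or_text)
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration key")
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
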