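"""Pipeline configuration: a single YAML file validated before any
computation runs.

Relative paths in the file resolve against the file's directory.  Genomic
coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .core import DEFAULT_LOWER, DEFAULT_UPPER
from .errors import ConfigurationError
from .methylation import CpgIslandConfig


@dataclass(frozen=True)
class AssayConfig:
    """One pyrosequencing assay: gene, reporter SNP and the fixed allele
    orientation (numerator = allele1); per-gene neutralization flag for the
    summary table (on for bi-directional ASE genes)."""

    gene: str
    rsnp_id: str
    allele1: str
    allele2: str
    neutralize: bool = True

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ConfigurationError(f"{self.gene}: assay alleles must differ")


@dataclass(frozen=True)
class CandidateConfig:
    """Candidate regulatory SNP to test for association with ASE."""

    snp_id: str
    ref: str = ""
    alt: str = ""


@dataclass(frozen=True)
class Thresholds:
    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER
    min_het: int = 10
    control_band: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.lower < 1 < self.upper:
            raise ConfigurationError(
                f"need 0 < lower < 1 < upper, got ({self.lower}, {self.upper})"
            )
        if self.min_het < 1 or not 0 < self.control_band < 1:
            raise ConfigurationError("bad min_het or control_band")


@dataclass(frozen=True)
class Flags:
    welch_methylation: bool = False
    bh_correction: bool = False
    per_breed_bias: bool = False
    gdna_per_breed: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    measurements: Path
    genotypes: Path
    output_dir: Path
    assays: Tuple[AssayConfig, ...]
    methylation: Optional[Path] = None
    candidates: Tuple[CandidateConfig, ...] = ()
    islands: Tuple[CpgIslandConfig, ...] = ()
    thresholds: Thresholds = field(default_factory=Thresholds)
    flags: Flags = field(default_factory=Flags)
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("measurements", "genotypes", "methylation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if not self.assays:
            raise ConfigurationError("at least one assay must be configured")

    @classmethod
    def from_dict(cls, data: Dict, base_dir: Path = Path(".")) -> "PipelineConfig":
        base = Path(base_dir)

        def path_of(key: str, section: Dict) -> Optional[Path]:
            v = section.get(key)
            return None if v is None else (base / v)

        inputs = data.get("inputs", {})
        assays = tuple(
            AssayConfig(
                gene=a["gene"],
                rsnp_id=a["rsnp_id"],
                allele1=a["allele1"],
                allele2=a["allele2"],
                neutralize=bool(a.get("neutralize", True)),
            )
            for a in data.get("assays", [])
        )
        candidates = tuple(
            CandidateConfig(snp_id=c["snp_id"], ref=c.get("ref", ""), alt=c.get("alt", ""))
            if isinstance(c, dict)
            else CandidateConfig(snp_id=str(c))
            for c in data.get("candidate_snps", [])
        )
        islands = tuple(
            CpgIslandConfig(
                island_id=i["island_id"],
                chrom=i["chrom"],
                start=int(i["start"]),
                end=int(i["end"]),
                site_positions=tuple(int(p) for p in i["sites"]),
            )
            for i in data.get("islands", [])
        )
        thr = data.get("thresholds", {})
        flg = data.get("flags", {})
        meas = path_of("measurements", inputs)
        geno = path_of("genotypes", inputs)
        if meas is None or geno is None:
            raise ConfigurationError("inputs.measurements and inputs.genotypes are required")
        return cls(
            measurements=meas,
            genotypes=geno,
            methylation=path_of("methylation", inputs),
            output_dir=base / data.get("output_dir", "pyroase_out"),
            assays=assays,
            candidates=candidates,
            islands=islands,
            thresholds=Thresholds(
                lower=float(thr.get("lower", DEFAULT_LOWER)),
                upper=float(thr.get("upper", DEFAULT_UPPER)),
                min_het=int(thr.get("min_het", 10)),
                control_band=float(thr.get("control_band", 0.15)),
            ),
            flags=Flags(
                welch_methylation=bool(flg.get("welch_methylation", False)),
                bh_correction=bool(flg.get("bh_correction", False)),
                per_breed_bias=bool(flg.get("per_breed_bias", False)),
                gdna_per_breed=bool(flg.get("gdna_per_breed", True)),
            ),
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        cfg = cls.from_dict(data, base_dir=path.parent)
        cfg.validate_paths()
        return cfg
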