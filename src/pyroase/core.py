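"""Allelic-ratio arithmetic for pyrosequencing ASE assays.

The quantitative unit of the whole pipeline is the *allelic transcript
ratio*: the percentage of one allele incorporated at a reporter SNP divided
by the percentage of the other, measured by pyrosequencing in cDNA and, as a
control, in heterozygous genomic DNA.  In gDNA of a heterozygote both alleles
are present in equimolar amounts, so the mean gDNA ratio of an assay measures
its nucleotide-incorporation bias; dividing every ratio by that mean removes
the bias.  A sample shows allele-specific expression (ASE) when its
replicate-mean normalized ratio leaves the 40:60–60:40 band, i.e. falls
below 2/3 or above 1.5.

All percentages live on the 0–100 scale and logarithms are base 10
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import stdev
from typing import Iterable, Literal, Sequence, Union

import numpy as np

from .errors import (
    ConfigurationError,
    InconsistentGroupError,
    InsufficientControlError,
    InvalidAssayError,
    InvalidMeasurementError,
)

Material = Literal["cDNA", "gDNA"]
ASECategory = Literal["balanced", "ase_allele1", "ase_allele2"]

#: tolerance for the two allele percentages of one read-out summing to 100
#: (instrument exports round to 0.1, so sums can drift slightly)
PCT_SUM_TOL = 0.5

#: classification thresholds for the 60:40 allelic-proportion rule.  The
#: lower bound is the exact reciprocal of the upper (2/3, printed 0.667) so
#: that relabelling the two alleles mirrors the classification exactly.
DEFAULT_UPPER = 1.5
DEFAULT_LOWER = 1.0 / DEFAULT_UPPER

MATERIALS = ("cDNA", "gDNA")
CATEGORIES = ("balanced", "ase_allele1", "ase_allele2")


@dataclass(frozen=True)
class PyroMeasurement:
    """One pyrosequencing read-out: allele percentages for one
    sample/assay/replicate, from cDNA or gDNA.

    Percentages of exactly 0 or 100 are rejected: a true heterozygote cannot
    express 0% of an allele at pyrosequencing depth, so such values indicate
    a failed assay or a genotyping error, not a computable ratio.
    """

    sample_id: str
    gene: str
    material: Material
    allele1_label: str
    allele2_label: str
    pct_allele1: float
    pct_allele2: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise InvalidMeasurementError(
                f"material must be one of {MATERIALS}, got {self.material!r}"
            )
        if self.allele1_label == self.allele2_label:
            raise InvalidMeasurementError(
                f"allele labels must differ, both are {self.allele1_label!r}"
            )
        for name, pct in (
            ("pct_allele1", self.pct_allele1),
            ("pct_allele2", self.pct_allele2),
        ):
            if not math.isfinite(pct) or not 0.0 < pct < 100.0:
                raise InvalidMeasurementError(
                    f"{name}={pct!r} outside (0, 100): failed assay"
                )
        total = self.pct_allele1 + self.pct_allele2
        if abs(total - 100.0) > PCT_SUM_TOL:
            raise InvalidMeasurementError(
                f"allele percentages sum to {total}, expected 100 ± {PCT_SUM_TOL}"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise InvalidMeasurementError(
                f"replicate index must be a positive integer, got {self.replicate!r}"
            )


@dataclass(frozen=True)
class GeneAssay:
    """A pyrosequencing assay: the reporter SNP, the fixed allele orientation
    (numerator = ``allele1``) and the estimated incorporation bias."""

    gene: str
    rsnp_id: str
    allele1: str
    allele2: str
    gdna_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise InvalidAssayError("assay alleles must differ")
        if not (math.isfinite(self.gdna_bias) and self.gdna_bias > 0):
            raise InvalidAssayError(f"gdna_bias must be > 0, got {self.gdna_bias!r}")


@dataclass(frozen=True)
class AllelicRatio:
    """Replicate-averaged allelic ratio for one sample × gene × material.

    ``raw_ratio`` is the replicate-mean of per-replicate raw ratios,
    ``normalized_ratio`` the same after division by the assay's gDNA bias,
    ``neutralized_ratio`` folds direction away (max(r, 1/r) ≥ 1) and
    ``log10_ratio`` is the signed log of the normalized ratio.
    """

    sample_id: str
    gene: str
    material: Material
    raw_ratio: float
    normalized_ratio: float
    n_replicates: int
    replicate_sd: float
    neutralized_ratio: float
    log10_ratio: float

    def __post_init__(self) -> None:
        if self.raw_ratio <= 0 or self.normalized_ratio <= 0:
            raise InvalidMeasurementError("allelic ratios must be positive")
        if self.n_replicates < 1 or self.replicate_sd < 0:
            raise InvalidMeasurementError("bad replicate summary")


@dataclass(frozen=True)
class ASECall:
    """Classification of one sample's replicate-mean normalized ratio against
    the 60:40 band.  Values exactly at a threshold are balanced."""

    sample_id: str
    gene: str
    tissue: str
    category: ASECategory
    lower_threshold: float
    upper_threshold: float
    ratio_used: float


def compute_ratio(pct_allele1: float, pct_allele2: float) -> float:
    """Allelic ratio: percentage of allele 1 divided by percentage of allele 2.

    A 60:40 allelic proportion gives 1.5; 40:60 gives 2/3 (0.667).
    """
    for pct in (pct_allele1, pct_allele2):
        if not math.isfinite(pct) or not 0.0 < pct <= 100.0:
            raise InvalidMeasurementError(
                f"percentage {pct!r} outside (0, 100]: failed assay"
            )
    total = pct_allele1 + pct_allele2
    if abs(total - 100.0) > PCT_SUM_TOL:
        raise InvalidMeasurementError(
            f"percentages sum to {total}, expected 100 ± {PCT_SUM_TOL}"
        )
    return pct_allele1 / pct_allele2


def estimate_gdna_bias(gdna_ratios: Sequence[float]) -> float:
    """Incorporation bias of an assay: the arithmetic mean of raw allelic
    ratios measured in heterozygous genomic DNA, where 1:1 is expected."""
    ratios = np.asarray(list(gdna_ratios), dtype=float)
    if ratios.size == 0:
        raise InsufficientControlError(
            "no heterozygous gDNA ratios: cannot estimate assay bias"
        )
    if not np.all(np.isfinite(ratios)) or np.any(ratios <= 0):
        raise InvalidMeasurementError("gDNA ratios must be finite and positive")
    return float(ratios.mean())


def normalize_ratio(raw_ratio: float, gdna_bias: float) -> float:
    """Divide a raw allelic ratio by the assay's mean gDNA ratio."""
    if not (math.isfinite(gdna_bias) and gdna_bias > 0):
        raise InvalidAssayError(f"gdna_bias must be > 0, got {gdna_bias!r}")
    if not (math.isfinite(raw_ratio) and raw_ratio > 0):
        raise InvalidMeasurementError(f"raw ratio must be > 0, got {raw_ratio!r}")
    return raw_ratio / gdna_bias


def neutralize(ratio: float) -> float:
    """Fold the direction of imbalance away: max(r, 1/r) ≥ 1."""
    if not (math.isfinite(ratio) and ratio > 0):
        raise InvalidMeasurementError(f"ratio must be > 0, got {ratio!r}")
    return max(ratio, 1.0 / ratio)


def average_replicates(
    measurements: Iterable[PyroMeasurement], gdna_bias: float = 1.0
) -> AllelicRatio:
    """Combine technical replicates of one sample × gene × material into one
    :class:`AllelicRatio`.

    Each replicate's raw ratio is normalized by ``gdna_bias`` first and the
    normalized ratios are then arithmetically averaged; ``replicate_sd`` is
    their sample standard deviation (0 when n = 1).
    """
    ms = list(measurements)
    if not ms:
        raise InconsistentGroupError("no measurements to average")
    first = ms[0]
    for m in ms[1:]:
        if (
            m.sample_id != first.sample_id
            or m.gene != first.gene
            or m.material != first.material
            or m.allele1_label != first.allele1_label
            or m.allele2_label != first.allele2_label
        ):
            raise InconsistentGroupError(
                "replicates must share sample, gene, material and allele order"
            )
    normalized = [
        normalize_ratio(compute_ratio(m.pct_allele1, m.pct_allele2), gdna_bias)
        for m in ms
    ]
    raw = [compute_ratio(m.pct_allele1, m.pct_allele2) for m in ms]
    mean_norm = float(np.mean(normalized))
    sd = float(stdev(normalized)) if len(normalized) > 1 else 0.0
    return AllelicRatio(
        sample_id=first.sample_id,
        gene=first.gene,
        material=first.material,
        raw_ratio=float(np.mean(raw)),
        normalized_ratio=mean_norm,
        n_replicates=len(ms),
        replicate_sd=sd,
        neutralized_ratio=neutralize(mean_norm),
        log10_ratio=math.log10(mean_norm),
    )


def classify_ase(
    ratio: Union[AllelicRatio, float],
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    tissue: str = "",
) -> ASECall:
    """Classify a replicate-mean normalized ratio against the 60:40 band.

    Strictly above ``upper`` → ASE towards allele 1; strictly below ``lower``
    → ASE towards allele 2; anything else (including values exactly at a
    threshold) is balanced.
    """
    if not (0.0 < lower < 1.0 < upper):
        raise ConfigurationError(
            f"thresholds must satisfy 0 < lower < 1 < upper, got ({lower}, {upper})"
        )
    if isinstance(ratio, AllelicRatio):
        value = ratio.normalized_ratio
        sample_id, gene = ratio.sample_id, ratio.gene
    else:
        value = float(ratio)
        sample_id, gene = "", ""
    if not (math.isfinite(value) and value > 0):
        raise InvalidMeasurementError(f"ratio must be > 0, got {value!r}")
    if value > upper:
        category: ASECategory = "ase_allele1"
    elif value < lower:
        category = "ase_allele2"
    else:
        category = "balanced"
    return ASECall(
        sample_id=sample_id,
        gene=gene,
        tissue=tissue,
        category=category,
        lower_threshold=lower,
        upper_threshold=upper,
        ratio_used=value,
    )
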