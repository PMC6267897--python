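"""Synthetic cohorts with the statistical structure the ASE analysis assumes.

The measurement model: a reporter-SNP heterozygote carries one haplotype
with assay allele 1 and one with allele 2.  A cis effect multiplies the
expression of one haplotype by a fold ``f``, so the true allele-1 transcript
odds are ``f`` (or ``1/f``).  The pyrosequencing assay adds a multiplicative
incorporation bias ``b`` to the allelic odds of *both* materials, giving
expected measured allele-1 fractions

* gDNA:  b / (1 + b)
* cDNA:  b·f / (1 + b·f)

Each technical replicate draws the measured fraction from a beta
distribution with that mean and a precision (concentration) parameter, so
noise is bounded and realistic for percentage read-outs; exported
percentages are rounded to 0.1 like instrument output, while the emitted
ground truth keeps full precision.

A candidate regulatory SNP can be simulated in configurable linkage
disequilibrium with the causal cis variant, with phase emitted, to exercise
the phase-corrected association test.  Per-CpG methylation levels are drawn
with a group-level shift in truly imbalanced samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import core, inference
from .errors import ConfigurationError, ManifestError
from .inference import DiplotypeRecord, phase_correct
from .methylation import CpgIslandConfig

#: tissue label used for genomic-DNA rows in the measurement table
GDNA_TISSUE = "gDNA"


@dataclass(frozen=True)
class FoldSpec:
    """Distribution of the per-animal cis fold effect.

    * ``point`` — every animal has allele-1 odds ``fold`` (``fold=1`` is the
      null; direction fixed towards allele 1).
    * ``lognormal`` — log10 odds ~ Normal(0, ``sigma_log10``): a smooth
      bi-directional spread of imbalance, the fat-tissue default.
    * ``two_point`` — a fraction ``ase_fraction`` of animals get fold
      ``fold`` with the over-expressed allele chosen at random; the rest are
      balanced.
    """

    kind: str = "lognormal"
    fold: float = 1.8
    sigma_log10: float = 0.12
    ase_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("point", "lognormal", "two_point"):
            raise ConfigurationError(f"unknown fold kind {self.kind!r}")
        if self.fold <= 0 or self.sigma_log10 < 0 or not 0 <= self.ase_fraction <= 1:
            raise ConfigurationError("invalid fold-spec parameters")


@dataclass(frozen=True)
class CandidateSnpSpec:
    """Candidate regulatory SNP, in LD ``r2_with_causal`` with the causal
    cis variant; phase relative to the reporter SNP is emitted."""

    snp_id: str = "rs_candidate"
    ref: str = "G"
    alt: str = "A"
    alt_freq: float = 0.3
    r2_with_causal: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alt_freq < 1:
            raise ConfigurationError("candidate alt_freq must be in (0,1)")
        if not 0 <= self.r2_with_causal <= 1:
            raise ConfigurationError("r2_with_causal must be in [0,1]")


@dataclass(frozen=True)
class CausalSpec:
    """Causal cis variant: a haplotype carrying the alt allele is expressed
    ``fold`` times the ref haplotype.  When set, it overrides the marginal
    fold distribution."""

    fold: float = 1.8
    alt_freq: float = 0.3

    def __post_init__(self) -> None:
        if self.fold <= 0 or not 0 < self.alt_freq < 1:
            raise ConfigurationError("invalid causal-spec parameters")


@dataclass(frozen=True)
class MethylationSimSpec:
    """True per-site percent-5-mC means for the balanced (control) and ASE
    groups of one island, plus the per-sample noise SD."""

    island: CpgIslandConfig
    ctrl_means: Tuple[float, ...]
    ase_means: Tuple[float, ...]
    noise_sd: float = 1.5

    def __post_init__(self) -> None:
        n = len(self.island.site_positions)
        if len(self.ctrl_means) != n or len(self.ase_means) != n:
            raise ConfigurationError(
                f"{self.island.island_id}: need one mean per site ({n})"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


def default_islands() -> Tuple[MethylationSimSpec, ...]:
    """Two 5'-flanking CpG islands with low methylation and one shifted site
    each in the ASE group, echoing the subtle differences the analysis is
    meant to resolve."""
    cgi1 = CpgIslandConfig(
        island_id="CGi1",
        chrom="SSC8",
        start=18527230,
        end=18528335,
        site_positions=(18527610, 18527645, 18527678, 18527702, 18527731),
    )
    cgi2 = CpgIslandConfig(
        island_id="CGi2",
        chrom="SSC8",
        start=18524520,
        end=18526314,
        site_positions=(18525190, 18525215, 18525237, 18525261, 18525290, 18525316),
    )
    ctrl1 = (3.0, 4.0, 3.5, 4.5, 4.0)
    ase1 = (3.0, 4.0, 6.0, 4.5, 4.0)  # +2.5 at SSC8:18527678
    ctrl2 = (2.0, 2.5, 2.0, 2.5, 3.0, 2.0)
    ase2 = (2.0, 4.5, 4.0, 2.5, 3.0, 2.0)  # shifts at 18525215 / 18525237
    return (
        MethylationSimSpec(cgi1, ctrl1, ase1, noise_sd=1.5),
        MethylationSimSpec(cgi2, ctrl2, ase2, noise_sd=1.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults emulate the fat-tissue scenario: four breeds with the study's
    cohort sizes, an A/T reporter SNP, a mild incorporation bias, duplicate
    measurements with beta noise, and a smooth bi-directional spread of cis
    folds that puts roughly a sixth of samples past the 60:40 threshold.
    """

    seed: int
    breeds: Tuple[Tuple[str, int], ...] = (
        ("PLW", 51),
        ("PL", 35),
        ("Duroc", 38),
        ("Pietrain", 21),
    )
    rsnp_het_fraction: float = 0.45
    gene: str = "PPARGC1A"
    rsnp_id: str = "rs45430917"
    allele1: str = "A"
    allele2: str = "T"
    assay_bias_b: float = 1.1
    cis_fold: FoldSpec = field(default_factory=FoldSpec)
    noise_concentration: float = 1000.0
    n_replicates: int = 2
    tissues: Tuple[str, ...] = ("subcutaneous_fat", "visceral_fat")
    candidate: Optional[CandidateSnpSpec] = None
    causal: Optional[CausalSpec] = None
    methylation: Tuple[MethylationSimSpec, ...] = field(default_factory=default_islands)
    ase_truth_threshold: float = 1.5

    def __post_init__(self) -> None:
        problems = []
        if not 0 < self.rsnp_het_fraction < 1:
            problems.append("rsnp_het_fraction must be in (0,1)")
        if self.assay_bias_b <= 0:
            problems.append("assay_bias_b must be positive")
        if self.noise_concentration <= 0:
            problems.append("noise_concentration must be positive")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if any(n < 0 for _, n in self.breeds):
            problems.append("breed sizes must be non-negative")
        if self.candidate is not None and self.candidate.r2_with_causal > 0 and self.causal is None:
            problems.append("candidate r2_with_causal > 0 requires a causal spec")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class SimulatedCohort:
    """Tables in the exact TSV dialects the analysis consumes, plus full
    ground truth for parameter-recovery scoring."""

    config: SimulationConfig
    measurements: pd.DataFrame
    genotypes: pd.DataFrame
    methylation: pd.DataFrame
    ground_truth: Dict

    def write(self, out_dir) -> Dict[str, Path]:
        from . import io as pio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "measurements": out / "measurements.tsv",
            "genotypes": out / "genotypes.tsv",
            "methylation": out / "methylation.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        pio.write_tsv(self.measurements, paths["measurements"])
        pio.write_tsv(self.genotypes, paths["genotypes"])
        pio.write_tsv(self.methylation, paths["methylation"])
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=1, sort_keys=True) + "\n"
        )
        return paths


def _haplotype_freqs(q_causal: float, q_cand: float, r: float) -> np.ndarray:
    """Joint (causal, candidate) haplotype frequencies with correlation r:
    order (alt,alt), (alt,ref), (ref,alt), (ref,ref)."""
    d = r * math.sqrt(q_causal * (1 - q_causal) * q_cand * (1 - q_cand))
    freqs = np.array(
        [
            q_causal * q_cand + d,
            q_causal * (1 - q_cand) - d,
            (1 - q_causal) * q_cand - d,
            (1 - q_causal) * (1 - q_cand) + d,
        ]
    )
    if np.any(freqs < -1e-12):
        raise ConfigurationError("LD parameter incompatible with allele frequencies")
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def _draw_odds(spec: FoldSpec, rng: np.random.Generator) -> float:
    """Per-animal allele-1 transcript odds under the marginal fold model."""
    if spec.kind == "point":
        return spec.fold
    if spec.kind == "lognormal":
        return float(10 ** rng.normal(0.0, spec.sigma_log10))
    if rng.random() < spec.ase_fraction:
        return spec.fold if rng.random() < 0.5 else 1.0 / spec.fold
    return 1.0


def _measured_percent(
    mean_frac: float, concentration: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate allele-1 percentages: beta noise around the expected
    fraction, rounded to 0.1 like instrument exports."""
    p = rng.beta(mean_frac * concentration, (1 - mean_frac) * concentration, size=n)
    pct = np.round(100.0 * p, 1)
    return np.clip(pct, 0.1, 99.9)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort: measurement, genotype and methylation tables in
    the pipeline's TSV dialects, plus ground truth.

    Generation order is fixed (breeds in config order, animals in index
    order, one sequential RNG), so identical configs give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    b = config.assay_bias_b
    kappa = config.noise_concentration
    cand = config.candidate
    causal = config.causal

    if cand is not None:
        q_causal = causal.alt_freq if causal is not None else cand.alt_freq
        hap_freqs = _haplotype_freqs(
            q_causal, cand.alt_freq, math.sqrt(cand.r2_with_causal)
        )
    meas_rows: List[dict] = []
    geno_rows: List[dict] = []
    meth_rows: List[dict] = []
    truth_animals: Dict[str, dict] = {}

    for breed, n in config.breeds:
        for i in range(n):
            sid = f"{breed}{i + 1:03d}"
            het = rng.random() < config.rsnp_het_fraction
            if het:
                rsnp_gt = f"{config.allele1}/{config.allele2}"
            else:
                a = config.allele1 if rng.random() < 0.5 else config.allele2
                rsnp_gt = f"{a}/{a}"
            geno_rows.append(
                {
                    "sample_id": sid,
                    "breed": breed,
                    "snp_id": config.rsnp_id,
                    "genotype": rsnp_gt,
                    "phase": ".",
                }
            )

            # candidate / causal haplotypes: hap_a is the haplotype carrying
            # assay allele 1 in heterozygotes (arbitrary in homozygotes)
            causal_a = causal_b = False
            cand_a = cand_b = None
            if cand is not None:
                ha, hb = rng.choice(4, size=2, p=hap_freqs)
                causal_a, cand_a = ha < 2, ha in (0, 2)
                causal_b, cand_b = hb < 2, hb in (0, 2)
                cand_gt = "/".join(
                    sorted(cand.alt if x else cand.ref for x in (cand_a, cand_b))
                )
                if het and cand_a != cand_b:
                    phase = "cis_alt" if cand_a else "cis_ref"
                else:
                    phase = "."
                geno_rows.append(
                    {
                        "sample_id": sid,
                        "breed": breed,
                        "snp_id": cand.snp_id,
                        "genotype": cand_gt,
                        "phase": phase,
                    }
                )

            if not het:
                continue

            if causal is not None:
                wa = causal.fold if causal_a else 1.0
                wb = causal.fold if causal_b else 1.0
                odds = wa / wb
            else:
                odds = _draw_odds(config.cis_fold, rng)

            ase_true = core.neutralize(odds) > config.ase_truth_threshold
            truth_animals[sid] = {
                "breed": breed,
                "fold_odds_allele1": odds,
                "over_expressed_allele": (
                    config.allele1 if odds > 1 else config.allele2 if odds < 1 else None
                ),
                "ase_true": bool(ase_true),
                "expected_cdna_frac1": b * odds / (1 + b * odds),
                "expected_gdna_frac1": b / (1 + b),
                "candidate_genotype": cand_gt if cand is not None else None,
                "phase": phase if cand is not None else None,
                "causal_het": bool(causal_a != causal_b) if causal is not None else None,
            }

            mu_g = b / (1 + b)
            for rep, pct in enumerate(
                _measured_percent(mu_g, kappa, config.n_replicates, rng), start=1
            ):
                meas_rows.append(
                    {
                        "sample_id": sid,
                        "breed": breed,
                        "tissue": GDNA_TISSUE,
                        "gene": config.gene,
                        "material": "gDNA",
                        "allele1": config.allele1,
                        "allele2": config.allele2,
                        "pct_allele1": pct,
                        "pct_allele2": round(100.0 - pct, 1),
                        "replicate": rep,
                    }
                )
            mu_c = b * odds / (1 + b * odds)
            for tissue in config.tissues:
                for rep, pct in enumerate(
                    _measured_percent(mu_c, kappa, config.n_replicates, rng), start=1
                ):
                    meas_rows.append(
                        {
                            "sample_id": sid,
                            "breed": breed,
                            "tissue": tissue,
                            "gene": config.gene,
                            "material": "cDNA",
                            "allele1": config.allele1,
                            "allele2": config.allele2,
                            "pct_allele1": pct,
                            "pct_allele2": round(100.0 - pct, 1),
                            "replicate": rep,
                        }
                    )

            for spec in config.methylation:
                means = spec.ase_means if ase_true else spec.ctrl_means
                for tissue in config.tissues:
                    values = np.clip(
                        rng.normal(means, spec.noise_sd), 0.0, 100.0
                    )
                    for pos, val in zip(spec.island.site_positions, values):
                        meth_rows.append(
                            {
                                "sample_id": sid,
                                "tissue": tissue,
                                "island_id": spec.island.island_id,
                                "chrom": spec.island.chrom,
                                "position": pos,
                                "pct_5mc": round(float(val), 2),
                                "conversion_control_pass": 1,
                            }
                        )

    measurements = pd.DataFrame(
        meas_rows,
        columns=[
            "sample_id",
            "breed",
            "tissue",
            "gene",
            "material",
            "allele1",
            "allele2",
            "pct_allele1",
            "pct_allele2",
            "replicate",
        ],
    )
    genotypes = pd.DataFrame(
        geno_rows, columns=["sample_id", "breed", "snp_id", "genotype", "phase"]
    )
    methylation = pd.DataFrame(
        meth_rows,
        columns=[
            "sample_id",
            "tissue",
            "island_id",
            "chrom",
            "position",
            "pct_5mc",
            "conversion_control_pass",
        ],
    )
    truth = {
        "assay": {
            "gene": config.gene,
            "rsnp_id": config.rsnp_id,
            "allele1": config.allele1,
            "allele2": config.allele2,
            "bias_b": b,
        },
        "animals": truth_animals,
        "methylation": {
            spec.island.island_id: {
                str(pos): {"ctrl": c, "ase": a}
                for pos, c, a in zip(
                    spec.island.site_positions, spec.ctrl_means, spec.ase_means
                )
            }
            for spec in config.methylation
        },
        "seed": config.seed,
    }
    return SimulatedCohort(config, measurements, genotypes, methylation, truth)


# ---------------------------------------------------------------------------
# Array-level helpers for Monte-Carlo suites (no table round-trip)

def simulate_ratio_groups(
    n_cdna: int,
    n_gdna: int,
    rng: np.random.Generator,
    fold: float = 1.0,
    bias: float = 1.1,
    concentration: float = 1000.0,
    n_replicates: int = 2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample normalized ratios for a cDNA group at cis fold ``fold`` and
    its heterozygous gDNA controls; normalization uses the bias *estimated*
    from the gDNA group, exactly as the pipeline would."""
    mu_c = bias * fold / (1 + bias * fold)
    mu_g = bias / (1 + bias)
    pc = rng.beta(mu_c * concentration, (1 - mu_c) * concentration, (n_cdna, n_replicates))
    pg = rng.beta(mu_g * concentration, (1 - mu_g) * concentration, (n_gdna, n_replicates))
    raw_c = (pc / (1 - pc)).mean(axis=1)
    raw_g = (pg / (1 - pg)).mean(axis=1)
    bias_hat = core.estimate_gdna_bias(raw_g)
    return raw_c / bias_hat, raw_g / bias_hat


def rejection_rate(
    fold: float,
    n_per_group: int,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    bias: float = 1.1,
    concentration: float = 1000.0,
    n_replicates: int = 2,
    neutralize_first: bool = False,
) -> float:
    """Monte-Carlo rejection rate of the cDNA-vs-gDNA Welch test at level
    ``alpha``; ``fold=1`` gives the type-I error."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cdna, gdna = simulate_ratio_groups(
            n_per_group, n_per_group, rng, fold=fold, bias=bias,
            concentration=concentration, n_replicates=n_replicates,
        )
        res = inference.test_cdna_vs_gdna(cdna, gdna, neutralize_first=neutralize_first)
        hits += res.p_value < alpha
    return hits / n_reps


def simulate_association_groups(
    n_het: int,
    n_hom: int,
    rng: np.random.Generator,
    causal_fold: float = 1.8,
    r2: float = 1.0,
    cand_alt_freq: float = 0.3,
    causal_alt_freq: float = 0.3,
    bias: float = 1.1,
    concentration: float = 1000.0,
    n_replicates: int = 2,
    n_gdna: int = 14,
) -> Tuple[np.ndarray, np.ndarray]:
    """Phase-corrected log10 ratios for ``n_het`` candidate heterozygotes and
    raw log10 ratios for ``n_hom`` homozygotes, all reporter-SNP hets.

    Candidate and causal alleles are drawn per haplotype from the two-locus
    distribution at correlation sqrt(r2); at r2 = 1 with matched frequencies
    the candidate *is* the driver, at r2 = 0 it is unlinked.  Normalization
    divides by a bias estimate from ``n_gdna`` simulated controls (an
    additive constant on the log scale, common to both groups).
    """
    r = math.sqrt(r2)
    freqs = _haplotype_freqs(causal_alt_freq, cand_alt_freq, r)
    q = cand_alt_freq
    # P(causal alt | candidate allele) from the haplotype table
    p_c_given_alt = freqs[0] / (freqs[0] + freqs[2]) if freqs[0] + freqs[2] > 0 else 0.0
    p_c_given_ref = freqs[1] / (freqs[1] + freqs[3]) if freqs[1] + freqs[3] > 0 else 0.0

    mu_g = bias / (1 + bias)
    pg = rng.beta(mu_g * concentration, (1 - mu_g) * concentration, (n_gdna, n_replicates))
    bias_hat = core.estimate_gdna_bias((pg / (1 - pg)).mean(axis=1))

    def measure(odds: float) -> float:
        mu = bias * odds / (1 + bias * odds)
        p = rng.beta(mu * concentration, (1 - mu) * concentration, n_replicates)
        return math.log10((p / (1 - p)).mean() / bias_hat)

    het_logs = np.empty(n_het)
    for i in range(n_het):
        # one haplotype carries the candidate alt allele, the other the ref;
        # which one is cis to assay allele 1 defines the phase
        alt_cis1 = rng.random() < 0.5
        causal_on_alt_hap = rng.random() < p_c_given_alt
        causal_on_ref_hap = rng.random() < p_c_given_ref
        w_alt = causal_fold if causal_on_alt_hap else 1.0
        w_ref = causal_fold if causal_on_ref_hap else 1.0
        odds = (w_alt / w_ref) if alt_cis1 else (w_ref / w_alt)
        record = DiplotypeRecord(
            sample_id=f"het{i}",
            candidate_snp_id="cand",
            candidate_genotype="het",
            phase="cis_alt" if alt_cis1 else "cis_ref",
        )
        het_logs[i] = phase_correct(measure(odds), record)

    p_hom_alt = q * q / (q * q + (1 - q) ** 2)
    hom_logs = np.empty(n_hom)
    for i in range(n_hom):
        alt_hom = rng.random() < p_hom_alt
        p_c = p_c_given_alt if alt_hom else p_c_given_ref
        causal_a = rng.random() < p_c
        causal_b = rng.random() < p_c
        wa = causal_fold if causal_a else 1.0
        wb = causal_fold if causal_b else 1.0
        hom_logs[i] = measure(wa / wb)
    return het_logs, hom_logs


def association_rejection_rate(
    n_het: int,
    n_hom: int,
    n_reps: int,
    seed: int,
    r2: float,
    causal_fold: float = 1.8,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Monte-Carlo rejection rate of the phase-corrected variant-association
    test; ``r2=0`` (candidate unlinked to the driver) gives the null rate."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        het, hom = simulate_association_groups(
            n_het, n_hom, rng, causal_fold=causal_fold, r2=r2, **kwargs
        )
        res = inference.test_variant_association(het, hom)
        hits += res.p_value < alpha
    return hits / n_reps


def simulate_methylation_groups(
    island: CpgIslandConfig,
    ase_means: Sequence[float],
    ctrl_means: Sequence[float],
    noise_sd: float,
    n_ase: int,
    n_ctrl: int,
    rng: np.random.Generator,
    tissue: str = "visceral_fat",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample per-site percent-5-mC tables for an ASE and a control
    group, normal noise truncated to [0, 100], in the methylation-record
    dialect."""

    def group(prefix: str, means: Sequence[float], n: int) -> pd.DataFrame:
        values = np.clip(
            rng.normal(np.asarray(means, float), noise_sd, (n, len(means))), 0.0, 100.0
        )
        rows = []
        for i in range(n):
            for pos, v in zip(island.site_positions, values[i]):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i}",
                        "tissue": tissue,
                        "island_id": island.island_id,
                        "chrom": island.chrom,
                        "position": pos,
                        "pct_5mc": float(v),
                        "conversion_control_pass": True,
                    }
                )
        return pd.DataFrame(rows)

    return group("ase", ase_means, n_ase), group("ctl", ctrl_means, n_ctrl)


def simulate_null_and_power_grid(
    cells: Sequence[Mapping],
    base_seed: int,
    out_dir=None,
) -> Dict:
    """Deterministic manifest (and optionally datasets) for a grid of
    simulation scenarios.

    Each cell is a mapping with a unique ``id`` and optional overrides:
    ``fold`` (point cis fold), ``n_animals`` (one all-heterozygote breed),
    ``concentration`` and ``replicates`` (number of datasets for the cell).
    Per-cell seeds are spawned from ``base_seed`` so the mapping cell →
    seeds → datasets is reproducible run to run.
    """
    ids = [c["id"] for c in cells]
    if len(ids) != len(set(ids)):
        raise ManifestError(f"duplicate cell ids in grid: {sorted(ids)}")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(cells))
    manifest: Dict = {"base_seed": int(base_seed), "cells": []}
    for cell, child in zip(cells, children):
        reps = int(cell.get("replicates", 1))
        seeds = [int(s) % (2**31) for s in child.generate_state(reps)]
        entry = {
            "id": cell["id"],
            "params": {
                "fold": float(cell.get("fold", 1.0)),
                "n_animals": int(cell.get("n_animals", 14)),
                "concentration": float(cell.get("concentration", 1000.0)),
            },
            "seeds": seeds,
            "datasets": [],
        }
        if out_dir is not None:
            for j, s in enumerate(seeds):
                cfg = SimulationConfig(
                    seed=s,
                    breeds=(("SIM", entry["params"]["n_animals"]),),
                    rsnp_het_fraction=0.999999,
                    cis_fold=FoldSpec(kind="point", fold=entry["params"]["fold"]),
                    noise_concentration=entry["params"]["concentration"],
                    candidate=None,
                    methylation=(),
                )
                sub = Path(out_dir) / f"{cell['id']}_rep{j}"
                simulate_cohort(cfg).write(sub)
                entry["datasets"].append(str(sub.name))
        manifest["cells"].append(entry)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    return manifest
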