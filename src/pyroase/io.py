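"""Readers and writers for the pipeline's plain-text dialects.

All tables are UTF-8 TSV with a header row and ``.`` for missing values.
Rows violating their contract are never silently dropped: readers return an
exclusion table with one machine-readable reason code per rejected row.
Genotypes can alternatively come from a VCF 4.2 file (optional dependency
``cyvcf2``); multi-allelic records are rejected to the exclusion table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import MATERIALS, PCT_SUM_TOL
from .errors import ConfigurationError

MEASUREMENT_COLUMNS = [
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
]
GENOTYPE_COLUMNS = ["sample_id", "breed", "snp_id", "genotype", "phase"]
METHYLATION_COLUMNS = [
    "sample_id",
    "tissue",
    "island_id",
    "chrom",
    "position",
    "pct_5mc",
    "conversion_control_pass",
]

EXCLUSION_COLUMNS = ["source", "row", "sample_id", "reason"]


def write_tsv(df: pd.DataFrame, path) -> Path:
    """Deterministic TSV export: '.' for missing, %.6g floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
    return path


def _read_raw(path, required: List[str], optional: List[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path), sep="\t", dtype=str, na_values=["."], keep_default_na=False
    )
    missing = set(required) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    for col in optional:
        if col not in df.columns:
            df[col] = np.nan
    return df


def _exclusions(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=EXCLUSION_COLUMNS)


def read_measurements(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read pyrosequencing allele-percentage measurements.

    Returns (valid rows with numeric columns coerced, exclusion table).
    Reason codes: ``missing_field``, ``bad_material``, ``same_alleles``,
    ``pct_out_of_range``, ``pct_sum_violation``, ``bad_replicate``.
    """
    df = _read_raw(path, MEASUREMENT_COLUMNS)
    excl: List[dict] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask: np.ndarray, reason: str) -> None:
        nonlocal keep
        for idx in df.index[mask & keep]:
            excl.append(
                {
                    "source": "measurements",
                    "row": int(idx) + 2,  # 1-based line number incl. header
                    "sample_id": df.at[idx, "sample_id"],
                    "reason": reason,
                }
            )
        keep &= ~mask

    required_str = ["sample_id", "breed", "tissue", "gene", "material", "allele1", "allele2"]
    reject(df[required_str].isna().any(axis=1).to_numpy(), "missing_field")
    reject((~df["material"].isin(MATERIALS)).to_numpy(), "bad_material")
    reject((df["allele1"] == df["allele2"]).to_numpy(), "same_alleles")

    p1 = pd.to_numeric(df["pct_allele1"], errors="coerce")
    p2 = pd.to_numeric(df["pct_allele2"], errors="coerce")
    bad_pct = (
        p1.isna() | p2.isna() | (p1 <= 0) | (p1 >= 100) | (p2 <= 0) | (p2 >= 100)
    ).to_numpy()
    reject(bad_pct, "pct_out_of_range")
    with np.errstate(invalid="ignore"):
        bad_sum = (np.abs(p1 + p2 - 100.0) > PCT_SUM_TOL).fillna(False).to_numpy()
    reject(bad_sum, "pct_sum_violation")

    rep = pd.to_numeric(df["replicate"], errors="coerce")
    reject((rep.isna() | (rep < 1) | (rep % 1 != 0)).fillna(True).to_numpy(), "bad_replicate")

    out = df[keep].copy()
    out["pct_allele1"] = p1[keep].astype(float)
    out["pct_allele2"] = p2[keep].astype(float)
    out["replicate"] = rep[keep].astype(int)
    return out.reset_index(drop=True), _exclusions(excl)


def read_genotypes(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read an 'A/G'-style genotype table (phase column optional)."""
    df = _read_raw(path, GENOTYPE_COLUMNS[:4], optional=["phase"])
    excl: List[dict] = []
    keep = df[["sample_id", "breed", "snp_id", "genotype"]].notna().all(axis=1)
    for idx in df.index[~keep]:
        excl.append(
            {
                "source": "genotypes",
                "row": int(idx) + 2,
                "sample_id": df.at[idx, "sample_id"],
                "reason": "missing_field",
            }
        )
    out = df[keep].copy()
    out["phase"] = out["phase"].fillna(".")
    return out.reset_index(drop=True), _exclusions(excl)


def read_genotypes_vcf(
    path, breeds: Mapping[str, str], snp_ids: Optional[List[str]] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes from a VCF 4.2 file via cyvcf2.

    ``breeds`` maps VCF sample names to breed labels (samples without a
    mapping are excluded).  Multi-allelic records are rejected to the
    exclusion table; phase is emitted as '.' (real-data phase is an input
    column of the TSV dialect, never inferred here).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "VCF input needs the optional cyvcf2 dependency (pip install pyroase[vcf])"
        ) from exc
    rows: List[dict] = []
    excl: List[dict] = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_ids is not None and snp_id not in snp_ids:
            continue
        if len(var.ALT) != 1:
            excl.append(
                {"source": "vcf", "row": var.POS, "sample_id": ".",
                 "reason": "multiallelic_record"}
            )
            continue
        for sample, gt in zip(samples, var.gt_bases):
            if sample not in breeds:
                excl.append(
                    {"source": "vcf", "row": var.POS, "sample_id": sample,
                     "reason": "unknown_breed"}
                )
                continue
            gt = gt.replace("|", "/")
            if "." in gt.split("/"):
                excl.append(
                    {"source": "vcf", "row": var.POS, "sample_id": sample,
                     "reason": "missing_genotype"}
                )
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "breed": breeds[sample],
                    "snp_id": snp_id,
                    "genotype": gt,
                    "phase": ".",
                }
            )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS), _exclusions(excl)


def read_methylation(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read per-CpG percent-5-mC records (1-based positions)."""
    df = _read_raw(path, METHYLATION_COLUMNS[:6], optional=["conversion_control_pass"])
    excl: List[dict] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask: np.ndarray, reason: str) -> None:
        nonlocal keep
        for idx in df.index[mask & keep]:
            excl.append(
                {
                    "source": "methylation",
                    "row": int(idx) + 2,
                    "sample_id": df.at[idx, "sample_id"],
                    "reason": reason,
                }
            )
        keep &= ~mask

    reject(
        df[["sample_id", "tissue", "island_id", "chrom"]].isna().any(axis=1).to_numpy(),
        "missing_field",
    )
    pos = pd.to_numeric(df["position"], errors="coerce")
    reject((pos.isna() | (pos < 1) | (pos % 1 != 0)).fillna(True).to_numpy(), "bad_position")
    pct = pd.to_numeric(df["pct_5mc"], errors="coerce")
    reject((pct.isna() | (pct < 0) | (pct > 100)).fillna(True).to_numpy(), "pct_out_of_range")

    ccp = df["conversion_control_pass"].fillna("1").astype(str).str.lower()
    ccp_bool = ccp.isin(["1", "true", "yes", "pass"])
    reject((~ccp_bool & ~ccp.isin(["0", "false", "no", "fail"])).to_numpy(), "bad_control_flag")
    reject((~ccp_bool).to_numpy(), "conversion_control_fail")

    out = df[keep].copy()
    out["position"] = pos[keep].astype(int)
    out["pct_5mc"] = pct[keep].astype(float)
    out["conversion_control_pass"] = True
    return out.reset_index(drop=True), _exclusions(excl)
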