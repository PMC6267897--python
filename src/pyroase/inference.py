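"""Group-level ASE statistics.

Three questions are answered here, each within heterozygous carriers of the
reporter SNP:

* Does a breed × tissue cDNA group deviate from its gDNA controls?  Tested
  on log10 ratios with a two-tailed Welch (unequal-variance) t-test,
  optionally after neutralizing the direction of imbalance, mirroring the
  per-cell tests behind the aggregate summary table.
* Is imbalance one- or bi-directional across unrelated animals?  Counted
  from individual ASE calls: consistent over-expression of one allele points
  to a linked cis element, either-direction imbalance to an unlinked one.
* Does a candidate regulatory variant drive the imbalance?  Each candidate
  heterozygote's log ratio is phase-corrected so the numerator haplotype
  always carries the same candidate allele, then candidate heterozygotes are
  compared with homozygotes (who cannot show a candidate-driven imbalance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .core import AllelicRatio, ASECall, neutralize
from .errors import (
    CannotAnchorError,
    DegenerateVarianceError,
    EmptyGroupError,
    InconsistentGroupError,
    InsufficientSampleError,
    UnphasedRecordError,
)

CandidateGenotype = Literal["hom_ref", "het", "hom_alt"]
Phase = Literal["cis_ref", "cis_alt", "unknown"]
Directionality = Literal["none", "one_directional", "bi_directional"]


def significance_code(p_value: float) -> str:
    """Map a p-value to the conventional star code (strict inequalities,
    most stringent applicable): *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupTestResult:
    group1_label: str
    group2_label: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_statistic: float
    df: float
    p_value: float
    significance_code: str


@dataclass(frozen=True)
class DiplotypeRecord:
    """Reporter-SNP heterozygote with its candidate-SNP genotype and, for
    candidate heterozygotes, the phase: which candidate allele sits on the
    haplotype carrying assay allele 1."""

    sample_id: str
    candidate_snp_id: str
    candidate_genotype: CandidateGenotype
    phase: Phase = "unknown"


@dataclass(frozen=True)
class DirectionalityCall:
    gene: str
    breed: str
    tissue: str
    value: Directionality
    n_ase_allele1: int
    n_ase_allele2: int


def welch_t_test(
    xs: Sequence[float],
    ys: Sequence[float],
    group1_label: str = "group1",
    group2_label: str = "group2",
) -> GroupTestResult:
    """Two-tailed t-test with unequal variances (Welch–Satterthwaite df)."""
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientSampleError(
            f"need ≥2 observations per group, got {x.size} and {y.size}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientSampleError("non-finite values in test input")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise DegenerateVarianceError(
            "both groups have zero variance; t statistic undefined"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    return GroupTestResult(
        group1_label=group1_label,
        group2_label=group2_label,
        n1=int(x.size),
        n2=int(y.size),
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        significance_code=significance_code(p),
    )


def _ratio_values(ratios: Iterable[Union[AllelicRatio, float]]) -> np.ndarray:
    vals = [
        r.normalized_ratio if isinstance(r, AllelicRatio) else float(r)
        for r in ratios
    ]
    return np.asarray(vals, dtype=float)


def test_cdna_vs_gdna(
    cdna_ratios: Iterable[Union[AllelicRatio, float]],
    gdna_ratios: Iterable[Union[AllelicRatio, float]],
    neutralize_first: bool = False,
    group1_label: str = "cDNA",
    group2_label: str = "gDNA",
) -> GroupTestResult:
    """Welch test of cDNA vs gDNA log10 allelic ratios for one breed × tissue.

    With ``neutralize_first`` both groups are folded to max(r, 1/r) before
    the log transform, so the comparison is of imbalance magnitude — the
    right choice for genes whose ASE is bi-directional, where signed logs
    would average towards zero.
    """
    c = _ratio_values(cdna_ratios)
    g = _ratio_values(gdna_ratios)
    if neutralize_first:
        c = np.array([neutralize(v) for v in c])
        g = np.array([neutralize(v) for v in g])
    return welch_t_test(np.log10(c), np.log10(g), group1_label, group2_label)


def classify_directionality(
    calls: Sequence[ASECall], breed: str = ""
) -> DirectionalityCall:
    """Count ASE directions in one gene × breed × tissue group of calls."""
    if not calls:
        raise EmptyGroupError("no ASE calls in group")
    genes = {c.gene for c in calls}
    tissues = {c.tissue for c in calls}
    if len(genes) > 1 or len(tissues) > 1:
        raise InconsistentGroupError(
            "directionality must be assessed within one gene × tissue"
        )
    n1 = sum(1 for c in calls if c.category == "ase_allele1")
    n2 = sum(1 for c in calls if c.category == "ase_allele2")
    if n1 > 0 and n2 > 0:
        value: Directionality = "bi_directional"
    elif n1 > 0 or n2 > 0:
        value = "one_directional"
    else:
        value = "none"
    return DirectionalityCall(
        gene=genes.pop(),
        breed=breed,
        tissue=tissues.pop(),
        value=value,
        n_ase_allele1=n1,
        n_ase_allele2=n2,
    )


def is_heterozygous(genotype: str) -> bool:
    """True for 'A/T'-style genotypes whose two alleles differ."""
    alleles = str(genotype).replace("|", "/").split("/")
    return len(alleles) == 2 and alleles[0] != alleles[1] and "." not in alleles


def filter_informative_groups(
    genotypes: pd.DataFrame, min_het: int = 10
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Keep only (snp_id, breed) groups with at least ``min_het`` reporter-SNP
    heterozygotes; quantitative ASE analysis is restricted to those.

    ``genotypes`` needs columns sample_id, breed, snp_id, genotype.  Returns
    the retained (snp_id, breed) pairs and a per-group audit table with the
    heterozygote count and a ``retained`` flag.
    """
    required = {"sample_id", "breed", "snp_id", "genotype"}
    missing = required - set(genotypes.columns)
    if missing:
        raise InconsistentGroupError(f"genotype table missing columns {sorted(missing)}")
    if genotypes.empty:
        audit = pd.DataFrame(columns=["snp_id", "breed", "n_het", "retained"])
        return [], audit
    df = genotypes.copy()
    df["is_het"] = df["genotype"].map(is_heterozygous)
    counts = (
        df.groupby(["snp_id", "breed"], sort=True)["is_het"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"is_het": "n_het"})
    )
    counts["retained"] = counts["n_het"] >= min_het
    retained = [
        (row.snp_id, row.breed) for row in counts.itertuples() if row.retained
    ]
    return retained, counts


def phase_correct(log10_ratio: float, record: DiplotypeRecord) -> float:
    """Re-orient one heterozygote's log ratio onto a fixed candidate allele.

    For candidate heterozygotes the sign is flipped when the candidate *alt*
    allele is cis to assay allele 1 (phase ``cis_alt``), so that after
    correction the numerator haplotype always carries the candidate reference
    allele.  Homozygotes pass through unchanged.  Flipping the sign is
    equivalent to taking the reciprocal of the ratio before the log.
    """
    if record.candidate_genotype != "het":
        return float(log10_ratio)
    if record.phase == "unknown":
        raise UnphasedRecordError(
            f"candidate heterozygote {record.sample_id} has unknown phase"
        )
    return -float(log10_ratio) if record.phase == "cis_alt" else float(log10_ratio)


def test_variant_association(
    het_group: Sequence[float],
    hom_group: Sequence[float],
    group1_label: str = "candidate_het",
    group2_label: str = "candidate_hom",
) -> GroupTestResult:
    """Welch test of phase-corrected log ratios: candidate heterozygotes vs
    homozygotes (all among reporter-SNP heterozygotes).

    If the candidate variant drives the imbalance, heterozygotes carry a
    consistent phase-corrected shift while homozygotes centre on zero.
    ``het_group`` must already be phase-corrected via :func:`phase_correct`.
    """
    return welch_t_test(het_group, hom_group, group1_label, group2_label)


@dataclass(frozen=True)
class SummaryTable:
    """Aggregate per-gene summary mirroring a breeds × tissues mean-log table
    with a gDNA anchor column and significance codes per cell."""

    gene: str
    means: pd.DataFrame  # breeds × (tissues..., gDNA), mean log10 ratios
    codes: pd.DataFrame  # same shape, significance codes vs gDNA ('' for gDNA)
    fivenum: pd.DataFrame  # per breed × group: min, q1, median, q3, max of ratios
    tests: Tuple[GroupTestResult, ...]


def aggregate_summary_table(
    ratios: pd.DataFrame,
    neutralize_first: bool = True,
    gdna_per_breed: bool = True,
) -> SummaryTable:
    """Build the per-gene summary: mean log10 (optionally neutralized)
    allelic ratios per breed × tissue, a gDNA column, and Welch significance
    codes of each cDNA cell against its gDNA anchor.

    ``ratios`` needs columns sample_id, breed, tissue, material,
    normalized_ratio (one row per sample × tissue × material) and must
    contain exactly one gene.  gDNA rows anchor each breed row (pooled across
    breeds when ``gdna_per_breed`` is off).  Also returns five-number
    summaries (on the ratio scale, not logs) per group for box-plot style
    reporting.  Cells are invariant to input row order.
    """
    required = {"sample_id", "breed", "tissue", "material", "normalized_ratio"}
    missing = required - set(ratios.columns)
    if missing:
        raise InconsistentGroupError(f"ratio table missing columns {sorted(missing)}")
    genes = set(ratios["gene"]) if "gene" in ratios.columns else {""}
    if len(genes) != 1:
        raise InconsistentGroupError("summary table is per gene; got several")
    gene = genes.pop()

    gdna = ratios[ratios["material"] == "gDNA"]
    cdna = ratios[ratios["material"] == "cDNA"]
    if gdna.empty:
        raise CannotAnchorError("no gDNA ratios: summary table cannot be anchored")

    def transform(values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if neutralize_first:
            v = np.maximum(v, 1.0 / v)
        return np.log10(v)

    breeds = sorted(set(cdna["breed"]) | set(gdna["breed"]))
    tissues = sorted(set(cdna["tissue"]))
    columns = tissues + ["gDNA"]
    means = pd.DataFrame(index=breeds, columns=columns, dtype=float)
    codes = pd.DataFrame("", index=breeds, columns=columns, dtype=object)
    tests: List[GroupTestResult] = []
    fivenum_rows: List[dict] = []

    def fivenum(breed: str, group: str, values: np.ndarray) -> None:
        q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
        fivenum_rows.append(
            {
                "breed": breed,
                "group": group,
                "n": int(values.size),
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )

    for breed in breeds:
        anchor = gdna if not gdna_per_breed else gdna[gdna["breed"] == breed]
        gvals = anchor["normalized_ratio"].to_numpy(dtype=float)
        if gvals.size:
            glog = transform(gvals)
            means.loc[breed, "gDNA"] = glog.mean()
            fivenum(breed, "gDNA", np.sort(gvals))
        for tissue in tissues:
            sub = cdna[(cdna["breed"] == breed) & (cdna["tissue"] == tissue)]
            cvals = sub["normalized_ratio"].to_numpy(dtype=float)
            if cvals.size == 0:
                continue
            clog = transform(cvals)
            means.loc[breed, tissue] = clog.mean()
            fivenum(breed, tissue, np.sort(cvals))
            if cvals.size >= 2 and gvals.size >= 2:
                try:
                    res = welch_t_test(
                        clog, glog, f"{breed}/{tissue}", f"{breed}/gDNA"
                    )
                except DegenerateVarianceError:
                    # identical constant groups: no evidence of deviation
                    codes.loc[breed, tissue] = "ns"
                    continue
                tests.append(res)
                codes.loc[breed, tissue] = res.significance_code
            else:
                codes.loc[breed, tissue] = "na"

    fivenum_df = pd.DataFrame(
        fivenum_rows, columns=["breed", "group", "n", "min", "q1", "median", "q3", "max"]
    ).sort_values(["breed", "group"], ignore_index=True)
    return SummaryTable(
        gene=gene, means=means, codes=codes, fivenum=fivenum_df, tests=tuple(tests)
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional reporting flag)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))
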