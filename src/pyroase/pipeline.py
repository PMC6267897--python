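"""End-to-end orchestration: tables in → ratios, calls, tests, summaries out.

Stage order mirrors the analysis: read and validate inputs; restrict each
assay to breeds with enough reporter-SNP heterozygotes; estimate the assay's
incorporation bias from heterozygous gDNA and normalize every ratio by it;
classify each sample against the 60:40 band; test cDNA vs gDNA per breed ×
tissue; test candidate promoter variants with phase-corrected ratios; and
compare CpG methylation between ASE and balanced samples.  Every record any
filter drops is written once to the exclusion log with a reason code, and
the run log records the seed, versions and counts at every filter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import core, inference, io, methylation as meth
from .config import AssayConfig, PipelineConfig
from .errors import PyroaseError
from .inference import DiplotypeRecord, GroupTestResult

RATIO_COLUMNS = [
    "sample_id",
    "breed",
    "tissue",
    "gene",
    "material",
    "n_replicates",
    "raw_ratio",
    "normalized_ratio",
    "replicate_sd",
    "neutralized_ratio",
    "log10_ratio",
]


@dataclass
class PipelineResult:
    config: PipelineConfig
    ratios: pd.DataFrame
    calls: pd.DataFrame
    directionality: pd.DataFrame
    summaries: Dict[str, inference.SummaryTable]
    group_tests: List[GroupTestResult]
    variant_tests: pd.DataFrame
    methylation_tests: pd.DataFrame
    exclusions: pd.DataFrame
    counts: Dict[str, int]
    paths: Dict[str, Path]


def _excl(source: str, sample_id: str, reason: str, row: int = 0) -> dict:
    return {"source": source, "row": row, "sample_id": sample_id, "reason": reason}


def quantify(
    measurements: pd.DataFrame,
    genotypes: pd.DataFrame,
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[dict], Dict[str, int]]:
    """Filter to informative groups, estimate per-assay gDNA bias, and build
    the replicate-averaged normalized ratio table."""
    excl: List[dict] = []
    counts: Dict[str, int] = {"measurement_rows_in": len(measurements)}
    ratio_rows: List[dict] = []
    call_rows: List[dict] = []
    thr = config.thresholds

    known_genes = {a.gene for a in config.assays}
    for _, row in measurements[~measurements["gene"].isin(known_genes)].iterrows():
        excl.append(_excl("measurements", row["sample_id"], "no_assay_configured"))
    for assay in config.assays:
        gt = genotypes[genotypes["snp_id"] == assay.rsnp_id]
        het_samples = set(gt.loc[gt["genotype"].map(inference.is_heterozygous), "sample_id"])
        counts[f"{assay.gene}_genotyped"] = int(gt["sample_id"].nunique())
        counts[f"{assay.gene}_heterozygous"] = len(het_samples)

        retained, audit = inference.filter_informative_groups(gt, min_het=thr.min_het)
        retained_breeds = {b for snp, b in retained if snp == assay.rsnp_id}
        for rec in audit.itertuples():
            if not rec.retained:
                excl.append(
                    _excl("groups", f"{assay.gene}:{rec.breed}", "breed_below_min_het")
                )
        counts[f"{assay.gene}_retained_breeds"] = len(retained_breeds)

        m = measurements[measurements["gene"] == assay.gene]
        orient_bad = (m["allele1"] != assay.allele1) | (m["allele2"] != assay.allele2)
        for _, row in m[orient_bad].iterrows():
            excl.append(
                _excl("measurements", row["sample_id"], "allele_orientation_mismatch")
            )
        m = m[~orient_bad]
        not_het = ~m["sample_id"].isin(het_samples)
        for _, row in m[not_het].iterrows():
            excl.append(_excl("measurements", row["sample_id"], "not_heterozygous"))
        m = m[~not_het]
        bad_breed = ~m["breed"].isin(retained_breeds)
        for _, row in m[bad_breed].iterrows():
            excl.append(_excl("measurements", row["sample_id"], "breed_below_min_het"))
        m = m[~bad_breed]
        counts[f"{assay.gene}_measurement_rows_assayed"] = len(m)
        if m.empty:
            continue

        def sample_raw_means(sub: pd.DataFrame) -> pd.Series:
            raw = sub["pct_allele1"] / sub["pct_allele2"]
            return raw.groupby(sub["sample_id"]).mean()

        gdna = m[m["material"] == "gDNA"]
        bias_by_breed: Dict[str, float] = {}
        if config.flags.per_breed_bias:
            for breed, sub in gdna.groupby("breed"):
                bias_by_breed[breed] = core.estimate_gdna_bias(sample_raw_means(sub))
        else:
            bias = core.estimate_gdna_bias(sample_raw_means(gdna))
            bias_by_breed = {breed: bias for breed in m["breed"].unique()}

        for (sid, breed, tissue, material), sub in m.groupby(
            ["sample_id", "breed", "tissue", "material"], sort=True
        ):
            ms = [
                core.PyroMeasurement(
                    sample_id=sid,
                    gene=assay.gene,
                    material=material,
                    allele1_label=assay.allele1,
                    allele2_label=assay.allele2,
                    pct_allele1=r.pct_allele1,
                    pct_allele2=r.pct_allele2,
                    replicate=int(r.replicate),
                )
                for r in sub.itertuples()
            ]
            ar = core.average_replicates(ms, gdna_bias=bias_by_breed[breed])
            ratio_rows.append(
                {
                    "sample_id": sid,
                    "breed": breed,
                    "tissue": tissue,
                    "gene": assay.gene,
                    "material": material,
                    "n_replicates": ar.n_replicates,
                    "raw_ratio": ar.raw_ratio,
                    "normalized_ratio": ar.normalized_ratio,
                    "replicate_sd": ar.replicate_sd,
                    "neutralized_ratio": ar.neutralized_ratio,
                    "log10_ratio": ar.log10_ratio,
                }
            )
            if material == "cDNA":
                call = core.classify_ase(
                    ar, lower=thr.lower, upper=thr.upper, tissue=tissue
                )
                call_rows.append(
                    {
                        "sample_id": sid,
                        "breed": breed,
                        "tissue": tissue,
                        "gene": assay.gene,
                        "category": call.category,
                        "ratio_used": call.ratio_used,
                        "lower_threshold": call.lower_threshold,
                        "upper_threshold": call.upper_threshold,
                    }
                )

    ratios = pd.DataFrame(ratio_rows, columns=RATIO_COLUMNS)
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "sample_id",
            "breed",
            "tissue",
            "gene",
            "category",
            "ratio_used",
            "lower_threshold",
            "upper_threshold",
        ],
    )
    counts["ratio_rows"] = len(ratios)
    counts["ase_calls"] = len(calls)
    return ratios, calls, excl, counts


def directionality_table(calls: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for (gene, breed, tissue), sub in calls.groupby(["gene", "breed", "tissue"], sort=True):
        group_calls = [
            core.ASECall(
                sample_id=r.sample_id,
                gene=gene,
                tissue=tissue,
                category=r.category,
                lower_threshold=r.lower_threshold,
                upper_threshold=r.upper_threshold,
                ratio_used=r.ratio_used,
            )
            for r in sub.itertuples()
        ]
        d = inference.classify_directionality(group_calls, breed=breed)
        rows.append(
            {
                "gene": gene,
                "breed": breed,
                "tissue": tissue,
                "directionality": d.value,
                "n_ase_allele1": d.n_ase_allele1,
                "n_ase_allele2": d.n_ase_allele2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "breed", "tissue", "directionality", "n_ase_allele1", "n_ase_allele2"],
    )


def variant_association_table(
    ratios: pd.DataFrame,
    genotypes: pd.DataFrame,
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Phase-corrected candidate-variant association per assay × SNP × tissue."""
    excl: List[dict] = []
    rows: List[dict] = []
    cdna = ratios[ratios["material"] == "cDNA"]
    for assay in config.assays:
        gene_ratios = cdna[cdna["gene"] == assay.gene]
        for cand in config.candidates:
            gt = genotypes[genotypes["snp_id"] == cand.snp_id]
            gt_by_sample = {r.sample_id: (r.genotype, r.phase) for r in gt.itertuples()}
            for tissue, sub in gene_ratios.groupby("tissue", sort=True):
                het_logs: List[float] = []
                hom_logs: List[float] = []
                het_gts: set = set()
                hom_gts: set = set()
                for r in sub.itertuples():
                    if r.sample_id not in gt_by_sample:
                        excl.append(
                            _excl("association", r.sample_id, "no_candidate_genotype")
                        )
                        continue
                    genotype, phase = gt_by_sample[r.sample_id]
                    if inference.is_heterozygous(genotype):
                        if phase not in ("cis_ref", "cis_alt"):
                            excl.append(_excl("association", r.sample_id, "unphased"))
                            continue
                        rec = DiplotypeRecord(
                            sample_id=r.sample_id,
                            candidate_snp_id=cand.snp_id,
                            candidate_genotype="het",
                            phase=phase,
                        )
                        het_logs.append(inference.phase_correct(r.log10_ratio, rec))
                        het_gts.add(genotype)
                    else:
                        hom_logs.append(float(r.log10_ratio))
                        hom_gts.add(genotype)
                if len(het_logs) < 2 or len(hom_logs) < 2:
                    excl.append(
                        _excl(
                            "association",
                            f"{assay.gene}:{cand.snp_id}:{tissue}",
                            "insufficient_group",
                        )
                    )
                    continue
                res = inference.test_variant_association(
                    het_logs, hom_logs, f"{cand.snp_id}:het", f"{cand.snp_id}:hom"
                )
                rows.append(
                    {
                        "gene": assay.gene,
                        "snp_id": cand.snp_id,
                        "tissue": tissue,
                        "n_het": res.n1,
                        "n_hom": res.n2,
                        "mean_het": res.mean1,
                        "mean_hom": res.mean2,
                        "t_statistic": res.t_statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "significance": res.significance_code,
                        "het_genotypes": "+".join(sorted(het_gts)),
                        "hom_genotypes": "+".join(sorted(hom_gts)),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "snp_id",
            "tissue",
            "n_het",
            "n_hom",
            "mean_het",
            "mean_hom",
            "t_statistic",
            "df",
            "p_value",
            "significance",
            "het_genotypes",
            "hom_genotypes",
        ],
    )
    if config.flags.bh_correction and not df.empty:
        df["p_adjusted"] = inference.bh_adjust(df["p_value"].to_numpy())
    return df, excl


def methylation_table(
    meth_df: pd.DataFrame,
    ratios: pd.DataFrame,
    calls: pd.DataFrame,
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Per-island × tissue ASE-vs-control comparison of percent 5-mC.

    ASE-group membership comes from the first configured assay's ASE calls
    for the same tissue; the control group is selected from balanced samples
    near ratio 1 (within the configured band)."""
    excl: List[dict] = []
    rows: List[dict] = []
    if meth_df.empty or not config.islands:
        return pd.DataFrame(), excl
    gene = config.assays[0].gene
    gene_calls = calls[calls["gene"] == gene]
    cdna = ratios[(ratios["gene"] == gene) & (ratios["material"] == "cDNA")]
    for island in config.islands:
        isl_df = meth_df[meth_df["island_id"] == island.island_id]
        for tissue, sub in isl_df.groupby("tissue", sort=True):
            tissue_calls = gene_calls[gene_calls["tissue"] == tissue]
            ase_ids = set(
                tissue_calls.loc[tissue_calls["category"] != "balanced", "sample_id"]
            ) & set(sub["sample_id"])
            call_objs = [
                core.ASECall(
                    sample_id=r.sample_id,
                    gene=gene,
                    tissue=tissue,
                    category=r.category,
                    lower_threshold=r.lower_threshold,
                    upper_threshold=r.upper_threshold,
                    ratio_used=r.ratio_used,
                )
                for r in tissue_calls.itertuples()
            ]
            tissue_ratios = cdna[cdna["tissue"] == tissue]
            ratio_objs = [
                core.AllelicRatio(
                    sample_id=r.sample_id,
                    gene=gene,
                    material="cDNA",
                    raw_ratio=r.raw_ratio,
                    normalized_ratio=r.normalized_ratio,
                    n_replicates=int(r.n_replicates),
                    replicate_sd=r.replicate_sd,
                    neutralized_ratio=r.neutralized_ratio,
                    log10_ratio=r.log10_ratio,
                )
                for r in tissue_ratios.itertuples()
            ]
            ctrl_ids = set(
                meth.select_control_group(
                    call_objs, ratio_objs, band=config.thresholds.control_band
                )
            ) & set(sub["sample_id"])
            if len(ase_ids) < 2 or len(ctrl_ids) < 2:
                excl.append(
                    _excl(
                        "methylation",
                        f"{island.island_id}:{tissue}",
                        "insufficient_group",
                    )
                )
                continue
            comparisons = meth.compare_methylation(
                sub[sub["sample_id"].isin(ase_ids)],
                sub[sub["sample_id"].isin(ctrl_ids)],
                island,
                welch=config.flags.welch_methylation,
            )
            for c in comparisons:
                rows.append(
                    {
                        "island_id": c.island_id,
                        "tissue": tissue,
                        "position": c.position,
                        "n_ase": c.n_ase,
                        "mean_ase": c.mean_ase,
                        "sd_ase": c.sd_ase,
                        "n_ctrl": c.n_ctrl,
                        "mean_ctrl": c.mean_ctrl,
                        "sd_ctrl": c.sd_ctrl,
                        "t_statistic": c.t_statistic,
                        "p_value": c.p_value,
                        "tested": c.tested,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "island_id",
            "tissue",
            "position",
            "n_ase",
            "mean_ase",
            "sd_ase",
            "n_ctrl",
            "mean_ctrl",
            "sd_ctrl",
            "t_statistic",
            "p_value",
            "tested",
        ],
    )
    if config.flags.bh_correction and not df.empty:
        tested = df["tested"].astype(bool)
        adj = df["p_value"].copy()
        if tested.any():
            adj.loc[tested] = inference.bh_adjust(df.loc[tested, "p_value"].to_numpy())
        df["p_adjusted"] = adj
    return df, excl


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts to ``config.output_dir``.

    Outputs are deterministic functions of the inputs (no timestamps), so
    re-running on identical inputs reproduces every file byte for byte.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    measurements, excl_m = io.read_measurements(config.measurements)
    genotypes, excl_g = io.read_genotypes(config.genotypes)
    if config.methylation is not None:
        meth_df, excl_meth = io.read_methylation(config.methylation)
    else:
        meth_df, excl_meth = pd.DataFrame(columns=io.METHYLATION_COLUMNS), pd.DataFrame(
            columns=io.EXCLUSION_COLUMNS
        )

    ratios, calls, excl_q, counts = quantify(measurements, genotypes, config)
    direction = directionality_table(calls, config)

    summaries: Dict[str, inference.SummaryTable] = {}
    group_tests: List[GroupTestResult] = []
    for assay in config.assays:
        sub = ratios[ratios["gene"] == assay.gene]
        if sub.empty or (sub["material"] == "gDNA").sum() == 0:
            continue
        table = inference.aggregate_summary_table(
            sub,
            neutralize_first=assay.neutralize,
            gdna_per_breed=config.flags.gdna_per_breed,
        )
        summaries[assay.gene] = table
        group_tests.extend(table.tests)

    variant_df, excl_v = variant_association_table(ratios, genotypes, config)
    meth_tests, excl_mt = methylation_table(meth_df, ratios, calls, config)

    exclusions = pd.concat(
        [excl_m, excl_g, excl_meth, pd.DataFrame(excl_q + excl_v + excl_mt,
                                                 columns=io.EXCLUSION_COLUMNS)],
        ignore_index=True,
    )

    paths: Dict[str, Path] = {}
    paths["ratios"] = io.write_tsv(ratios, out / "ratios.tsv")
    paths["ase_calls"] = io.write_tsv(calls, out / "ase_calls.tsv")
    paths["directionality"] = io.write_tsv(direction, out / "directionality.tsv")
    paths["variant_association"] = io.write_tsv(variant_df, out / "variant_association.tsv")
    paths["methylation_comparison"] = io.write_tsv(
        meth_tests, out / "methylation_comparison.tsv"
    )
    paths["exclusions"] = io.write_tsv(exclusions, out / "exclusions.tsv")
    for gene, table in summaries.items():
        merged = table.means.copy()
        for col in table.codes.columns:
            if col != "gDNA":
                merged[f"{col}_sig"] = table.codes[col]
        merged.insert(0, "breed", merged.index)
        paths[f"summary_{gene}"] = io.write_tsv(
            merged.reset_index(drop=True), out / f"summary_{gene}.tsv"
        )
        paths[f"fivenum_{gene}"] = io.write_tsv(table.fivenum, out / f"fivenum_{gene}.tsv")
    if config.islands:
        bed = meth.islands_to_bed(config.islands)
        (out / "tested_sites.bed").write_text(bed)
        paths["tested_sites"] = out / "tested_sites.bed"

    tests_json = [dataclasses.asdict(t) for t in group_tests]
    (out / "group_tests.json").write_text(
        json.dumps(tests_json, indent=1, sort_keys=True) + "\n"
    )
    paths["group_tests"] = out / "group_tests.json"

    import scipy

    counts["exclusions"] = len(exclusions)
    log_lines = [
        "pyroase run log",
        f"seed: {config.seed}",
        f"versions: pyroase={_version()} numpy={np.__version__} "
        f"pandas={pd.__version__} scipy={scipy.__version__}",
        f"thresholds: lower={config.thresholds.lower:.6g} "
        f"upper={config.thresholds.upper:.6g} min_het={config.thresholds.min_het}",
    ]
    for key in sorted(counts):
        log_lines.append(f"count {key}: {counts[key]}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out / "run_log.txt"

    return PipelineResult(
        config=config,
        ratios=ratios,
        calls=calls,
        directionality=direction,
        summaries=summaries,
        group_tests=group_tests,
        variant_tests=variant_df,
        methylation_tests=meth_tests,
        exclusions=exclusions,
        counts=counts,
        paths=paths,
    )


def _version() -> str:
    from . import __version__

    return __version__
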