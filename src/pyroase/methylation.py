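"""Per-CpG-site methylation comparison between ASE and balanced samples.

Bisulfite pyrosequencing yields a percent 5-methylcytosine value per CpG
site per sample.  For each configured CpG island the pipeline compares, site
by site, samples showing allelic imbalance against control samples whose
allelic ratio sits close to 1.  The per-site test is the classic pooled
(equal-variance) Student t-test; Welch is available behind a flag.  All
genomic coordinates are 1-based inclusive; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import AllelicRatio, ASECall
from .errors import (
    ConfigurationError,
    EmptyGroupError,
    InsufficientGroupError,
    UnknownSiteError,
)


@dataclass(frozen=True)
class CpgIslandConfig:
    """A configured CpG island and the CpG coordinates of its assayed
    amplicon (1-based inclusive; sites strictly increasing)."""

    island_id: str
    chrom: str
    start: int
    end: int
    site_positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"{self.island_id}: start > end")
        sites = tuple(int(p) for p in self.site_positions)
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ConfigurationError(f"{self.island_id}: sites must strictly increase")
        if sites and not (self.start <= sites[0] and sites[-1] <= self.end):
            raise ConfigurationError(
                f"{self.island_id}: sites must lie within [{self.start}, {self.end}]"
            )
        object.__setattr__(self, "site_positions", sites)


@dataclass(frozen=True)
class MethylationRecord:
    """Percent 5-mC at one CpG site in one sample; records failing the
    bisulfite conversion control are excluded upstream."""

    sample_id: str
    tissue: str
    island_id: str
    chrom: str
    position: int
    pct_5mc: float
    conversion_control_pass: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pct_5mc) and 0.0 <= self.pct_5mc <= 100.0):
            raise ConfigurationError(f"pct_5mc {self.pct_5mc!r} outside [0, 100]")


@dataclass(frozen=True)
class CpgComparison:
    island_id: str
    position: int
    mean_ase: float
    sd_ase: float
    n_ase: int
    mean_ctrl: float
    sd_ctrl: float
    n_ctrl: int
    t_statistic: float
    p_value: float
    tested: bool


def select_control_group(
    ase_calls: Sequence[ASECall],
    ratios: Sequence[AllelicRatio],
    band: float = 0.15,
    target_n: Optional[int] = None,
) -> List[str]:
    """Pick control samples with near-equal expression of both alleles.

    Returns sample ids of calls classified balanced whose replicate-mean
    normalized ratio lies within [1−band, 1+band], sorted by |ratio − 1|
    ascending (ties broken by sample id); optionally truncated to
    ``target_n``.  Empty when every sample shows ASE.
    """
    ratio_by_sample = {r.sample_id: r.normalized_ratio for r in ratios}
    candidates = []
    for call in ase_calls:
        if call.category != "balanced":
            continue
        r = ratio_by_sample.get(call.sample_id, call.ratio_used)
        if abs(r - 1.0) <= band:
            candidates.append((abs(r - 1.0), call.sample_id))
    candidates.sort()
    ids = [sid for _, sid in candidates]
    return ids[:target_n] if target_n is not None else ids


def _records_frame(
    records: Union[pd.DataFrame, Iterable[MethylationRecord]]
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "sample_id": r.sample_id,
            "tissue": r.tissue,
            "island_id": r.island_id,
            "chrom": r.chrom,
            "position": r.position,
            "pct_5mc": r.pct_5mc,
            "conversion_control_pass": r.conversion_control_pass,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
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


def summarize_cpg(
    records: Union[pd.DataFrame, Iterable[MethylationRecord]],
    island: CpgIslandConfig,
    group_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-site mean ± SD of percent 5-mC over one group of samples.

    ``records`` must already be restricted to one island × tissue.  Sites in
    the island config with no data are reported with n = 0; records at a
    position outside the config raise :class:`UnknownSiteError`.
    """
    if len(group_ids) == 0:
        raise EmptyGroupError("no samples in methylation group")
    df = _records_frame(records)
    known = set(island.site_positions)
    observed = set(df["position"].astype(int))
    unknown = observed - known
    if unknown:
        raise UnknownSiteError(
            f"{island.island_id}: records at unconfigured positions {sorted(unknown)}"
        )
    sub = df[df["sample_id"].isin(set(group_ids))]
    rows = []
    for pos in island.site_positions:
        vals = sub.loc[sub["position"].astype(int) == pos, "pct_5mc"].to_numpy(float)
        rows.append(
            {
                "island_id": island.island_id,
                "position": pos,
                "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size else float("nan")),
            }
        )
    return pd.DataFrame(rows, columns=["island_id", "position", "n", "mean", "sd"])


def compare_methylation(
    ase_records: Union[pd.DataFrame, Iterable[MethylationRecord]],
    ctrl_records: Union[pd.DataFrame, Iterable[MethylationRecord]],
    island: CpgIslandConfig,
    welch: bool = False,
) -> List[CpgComparison]:
    """Site-by-site two-sided t-test of percent 5-mC, ASE vs control group.

    The default is the pooled equal-variance Student test; ``welch`` switches
    to unequal variances.  Sites with fewer than two values in either group
    are reported untested (NaN t and p).  Records failing the conversion
    control are dropped before testing.
    """
    ase = _records_frame(ase_records)
    ctrl = _records_frame(ctrl_records)
    ase = ase[ase["conversion_control_pass"].astype(bool)]
    ctrl = ctrl[ctrl["conversion_control_pass"].astype(bool)]
    if ase.empty or ctrl.empty:
        raise InsufficientGroupError(
            f"{island.island_id}: both ASE and control groups must be non-empty"
        )
    for df in (ase, ctrl):
        unknown = set(df["position"].astype(int)) - set(island.site_positions)
        if unknown:
            raise UnknownSiteError(
                f"{island.island_id}: records at unconfigured positions {sorted(unknown)}"
            )
    out: List[CpgComparison] = []
    for pos in island.site_positions:
        a = ase.loc[ase["position"].astype(int) == pos, "pct_5mc"].to_numpy(float)
        c = ctrl.loc[ctrl["position"].astype(int) == pos, "pct_5mc"].to_numpy(float)
        if a.size >= 2 and c.size >= 2:
            res = stats.ttest_ind(a, c, equal_var=not welch)
            t, p, tested = float(res.statistic), float(res.pvalue), True
            if math.isnan(t):  # zero variance in both groups, identical means
                t, p = 0.0, 1.0
        else:
            t, p, tested = float("nan"), float("nan"), False
        out.append(
            CpgComparison(
                island_id=island.island_id,
                position=pos,
                mean_ase=float(a.mean()) if a.size else float("nan"),
                sd_ase=float(a.std(ddof=1)) if a.size > 1 else (0.0 if a.size else float("nan")),
                n_ase=int(a.size),
                mean_ctrl=float(c.mean()) if c.size else float("nan"),
                sd_ctrl=float(c.std(ddof=1)) if c.size > 1 else (0.0 if c.size else float("nan")),
                n_ctrl=int(c.size),
                t_statistic=t,
                p_value=p,
                tested=tested,
            )
        )
    return out


def comparisons_frame(comparisons: Sequence[CpgComparison]) -> pd.DataFrame:
    """Tabular view of :func:`compare_methylation` output."""
    return pd.DataFrame(
        [
            {
                "island_id": c.island_id,
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
            for c in comparisons
        ]
    )


def islands_to_bed(islands: Sequence[CpgIslandConfig]) -> str:
    """BED (0-based half-open) lines for every assayed CpG site."""
    lines = []
    for isl in islands:
        for i, pos in enumerate(isl.site_positions, start=1):
            lines.append(f"{isl.chrom}\t{pos - 1}\t{pos}\t{isl.island_id}:CpG{i}")
    return "\n".join(lines) + ("\n" if lines else "")
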