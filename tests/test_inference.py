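"""Group-level statistics: Welch test, directionality, informative-group
filtering, phase-corrected variant association and the summary table."""

import math

import numpy as np
import pandas as pd
import pytest

from pyroase import inference, simulate
from pyroase.core import ASECall, classify_ase
from pyroase.errors import (
    CannotAnchorError,
    DegenerateVarianceError,
    EmptyGroupError,
    InconsistentGroupError,
    InsufficientSampleError,
    UnphasedRecordError,
)
from pyroase.inference import (
    DiplotypeRecord,
    aggregate_summary_table,
    classify_directionality,
    filter_informative_groups,
    phase_correct,
    significance_code,
    welch_t_test,
)
from pyroase.inference import test_cdna_vs_gdna as cdna_vs_gdna_test
from pyroase.inference import test_variant_association as variant_association_test


def test_welch_matches_independent_oracle(oracle, rng):
    """scipy-backed Welch test must agree with the hand-computed textbook
    statistic, Welch–Satterthwaite df and two-sided p to 1e-10."""
    for _ in range(100):
        nx, ny = rng.integers(2, 12, size=2)
        xs = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2.0), nx)
        ys = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2.0), ny)
        res = welch_t_test(xs, ys)
        t, df, p = oracle(xs, ys)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_welch_hand_computed_instance(oracle):
    xs = [0.10, 0.15, 0.20, 0.12]
    ys = [0.01, 0.03, 0.02, 0.04]
    t, df, p = oracle(xs, ys)
    res = welch_t_test(xs, ys)
    assert (res.t_statistic, res.df, res.p_value) == pytest.approx((t, df, p))
    assert res.p_value < 0.01 and res.t_statistic > 0


def test_welch_identical_groups():
    res = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_welch_guards():
    with pytest.raises(DegenerateVarianceError):
        welch_t_test([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
    with pytest.raises(InsufficientSampleError):
        welch_t_test([1.0], [1.0, 2.0])


def test_welch_swapping_groups_negates_t(rng):
    xs, ys = rng.normal(0, 1, 6), rng.normal(0.5, 2, 9)
    a = welch_t_test(xs, ys)
    b = welch_t_test(ys, xs)
    assert a.t_statistic == pytest.approx(-b.t_statistic)
    assert a.p_value == pytest.approx(b.p_value)
    assert (a.n1, a.n2) == (b.n2, b.n1)


@pytest.mark.parametrize(
    "p, code",
    [(0.2, "ns"), (0.05, "ns"), (0.049, "*"), (0.01, "*"), (0.009, "**"),
     (0.001, "**"), (0.0009, "***")],
)
def test_significance_codes_strict_most_stringent(p, code):
    assert significance_code(p) == code


def test_cdna_vs_gdna_identical_ratios():
    vals = [1.1, 1.2, 1.3, 0.9]
    res = cdna_vs_gdna_test(vals, vals)
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_cdna_vs_gdna_neutralize_folds_direction():
    """With neutralization, a ratio and its reciprocal carry the same
    imbalance information, so mirrored groups give identical results."""
    cdna = [1.6, 1.8, 2.0, 1.7]
    gdna = [0.95, 1.05, 1.0, 0.98]
    direct = cdna_vs_gdna_test(cdna, gdna, neutralize_first=True)
    mirrored = cdna_vs_gdna_test([1 / v for v in cdna], gdna, neutralize_first=True)
    assert direct.t_statistic == pytest.approx(mirrored.t_statistic)
    assert direct.p_value == pytest.approx(mirrored.p_value)


def _calls(categories, gene="PPARGC1A", tissue="vf"):
    return [
        ASECall(sample_id=f"s{i}", gene=gene, tissue=tissue, category=c,
                lower_threshold=2 / 3, upper_threshold=1.5, ratio_used=1.0)
        for i, c in enumerate(categories)
    ]


@pytest.mark.parametrize(
    "categories, value, n1, n2",
    [
        (["ase_allele1", "ase_allele1", "balanced"], "one_directional", 2, 0),
        (["ase_allele1", "ase_allele2"], "bi_directional", 1, 1),
        (["balanced", "balanced"], "none", 0, 0),
    ],
)
def test_classify_directionality(categories, value, n1, n2):
    d = classify_directionality(_calls(categories), breed="PLW")
    assert (d.value, d.n_ase_allele1, d.n_ase_allele2) == (value, n1, n2)


def test_classify_directionality_guards():
    with pytest.raises(EmptyGroupError):
        classify_directionality([])
    mixed = _calls(["balanced"], tissue="vf") + _calls(["balanced"], tissue="sf")
    with pytest.raises(InconsistentGroupError):
        classify_directionality(mixed)


def test_filter_informative_groups_min_het_boundary():
    rows = []
    for i in range(10):
        rows.append({"sample_id": f"a{i}", "breed": "PLW", "snp_id": "rs1",
                     "genotype": "A/T"})
    for i in range(9):
        rows.append({"sample_id": f"b{i}", "breed": "PL", "snp_id": "rs1",
                     "genotype": "A/T"})
    rows.append({"sample_id": "b9", "breed": "PL", "snp_id": "rs1", "genotype": "A/A"})
    retained, audit = filter_informative_groups(pd.DataFrame(rows), min_het=10)
    assert retained == [("rs1", "PLW")]
    audit = audit.set_index("breed")
    assert audit.loc["PL", "n_het"] == 9 and not audit.loc["PL", "retained"]
    assert audit.loc["PLW", "n_het"] == 10


def test_filter_informative_groups_empty():
    retained, audit = filter_informative_groups(
        pd.DataFrame(columns=["sample_id", "breed", "snp_id", "genotype"])
    )
    assert retained == [] and audit.empty


def _record(genotype="het", phase="cis_ref"):
    return DiplotypeRecord(sample_id="s", candidate_snp_id="rs_c",
                           candidate_genotype=genotype, phase=phase)


def test_phase_correct_orientation_and_involution():
    assert phase_correct(0.2, _record(phase="cis_ref")) == pytest.approx(0.2)
    assert phase_correct(0.2, _record(phase="cis_alt")) == pytest.approx(-0.2)
    # correcting twice under cis_alt returns the original value
    twice = phase_correct(phase_correct(0.2, _record(phase="cis_alt")),
                          _record(phase="cis_alt"))
    assert twice == pytest.approx(0.2)
    assert phase_correct(0.7, _record(genotype="hom_ref", phase="unknown")) == 0.7


def test_phase_correct_requires_phase_for_hets():
    with pytest.raises(UnphasedRecordError):
        phase_correct(0.2, _record(phase="unknown"))


def test_variant_association_identical_groups():
    res = variant_association_test([0.1, 0.2, 0.15], [0.1, 0.2, 0.15])
    assert res.p_value == pytest.approx(1.0)


def test_phase_corrected_hets_shift_when_candidate_is_driver(rng):
    """When the candidate SNP is the causal cis variant, phase correction
    aligns every heterozygote's imbalance to the same sign, so candidate
    hets show a consistent non-zero mean while homozygotes centre on 0."""
    het, hom = simulate.simulate_association_groups(
        30, 30, rng, causal_fold=1.8, r2=1.0
    )
    assert abs(het.mean()) == pytest.approx(math.log10(1.8), abs=0.05)
    assert abs(hom.mean()) < 0.05
    assert variant_association_test(het, hom).p_value < 1e-6


def test_power_non_decreasing_in_effect_and_sample_size():
    """Monte-Carlo power of the cDNA-vs-gDNA test must grow with both the
    cis fold effect and the group size (3×3 grid)."""
    folds = [1.0, 1.25, 1.6]
    ns = [8, 16, 32]
    power = np.empty((3, 3))
    for i, f in enumerate(folds):
        for j, n in enumerate(ns):
            power[i, j] = simulate.rejection_rate(
                fold=f, n_per_group=n, n_reps=300, seed=5000 + 10 * i + j
            )
    slack = 0.03  # Monte-Carlo noise at 300 replicates
    assert np.all(np.diff(power, axis=0) >= -slack)   # effect direction
    assert np.all(np.diff(power[1:], axis=1) >= -slack)  # n direction, non-null rows
    assert power[2, 2] > 0.9 > power[0, 0]


def _ratio_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "breed", "tissue", "gene", "material",
                       "normalized_ratio"]
    )


def test_summary_table_all_balanced():
    rows = []
    for i in range(4):
        rows.append((f"s{i}", "PLW", "vf", "G", "cDNA", 1.0))
        rows.append((f"g{i}", "PLW", "gDNA", "G", "gDNA", 1.0))
    table = aggregate_summary_table(_ratio_frame(rows))
    assert table.means.loc["PLW", "vf"] == pytest.approx(0.0)
    assert table.means.loc["PLW", "gDNA"] == pytest.approx(0.0)
    assert table.codes.loc["PLW", "vf"] == "ns"


def test_summary_table_log_mean_cell():
    rows = [
        ("s1", "PL", "sf", "G", "cDNA", 10 ** 0.1),
        ("s2", "PL", "sf", "G", "cDNA", 10 ** 0.3),
        ("g1", "PL", "gDNA", "G", "gDNA", 0.98),
        ("g2", "PL", "gDNA", "G", "gDNA", 1.02),
    ]
    table = aggregate_summary_table(_ratio_frame(rows))
    assert table.means.loc["PL", "sf"] == pytest.approx(0.2)


def test_summary_table_requires_gdna_anchor():
    rows = [("s1", "PL", "sf", "G", "cDNA", 1.2), ("s2", "PL", "sf", "G", "cDNA", 1.1)]
    with pytest.raises(CannotAnchorError):
        aggregate_summary_table(_ratio_frame(rows))


def test_summary_table_row_order_invariant(rng):
    rows = []
    for b in ("PLW", "PL"):
        for t in ("sf", "vf"):
            for i in range(6):
                rows.append((f"{b}{t}{i}", b, t, "G", "cDNA",
                             float(10 ** rng.normal(0.05, 0.1))))
        for i in range(6):
            rows.append((f"{b}g{i}", b, "gDNA", "G", "gDNA",
                         float(10 ** rng.normal(0, 0.02))))
    df = _ratio_frame(rows)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = aggregate_summary_table(df)
    b = aggregate_summary_table(shuffled)
    pd.testing.assert_frame_equal(a.means, b.means)
    pd.testing.assert_frame_equal(a.codes, b.codes)
    pd.testing.assert_frame_equal(a.fivenum, b.fivenum)
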