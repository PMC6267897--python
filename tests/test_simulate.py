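"""Synthetic-cohort generator: measurement model, determinism, ground-truth
consistency and the scenario-grid manifest."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from pyroase import core
from pyroase.errors import ConfigurationError, ManifestError
from pyroase.simulate import (
    CandidateSnpSpec,
    CausalSpec,
    FoldSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_null_and_power_grid,
)

SMALL = dict(breeds=(("PLW", 20), ("PL", 15)))


def test_identical_config_gives_identical_cohorts(tmp_path):
    cfg = SimulationConfig(seed=42, **SMALL)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.measurements, b.measurements)
    pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
    pd.testing.assert_frame_equal(a.methylation, b.methylation)
    assert a.ground_truth == b.ground_truth
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()


def test_measured_percentages_sum_to_100():
    cohort = simulate_cohort(SimulationConfig(seed=7, **SMALL))
    total = cohort.measurements["pct_allele1"] + cohort.measurements["pct_allele2"]
    assert np.allclose(total, 100.0, atol=1e-9)
    assert (cohort.measurements["pct_allele1"] > 0).all()
    assert (cohort.measurements["pct_allele1"] < 100).all()


def test_zero_noise_limits():
    """With vanishing noise the measured fractions converge to the model
    means: 50/50 under the null and 60/40 at fold 1.5 with no assay bias."""
    null = simulate_cohort(SimulationConfig(
        seed=1, breeds=(("X", 10),), assay_bias_b=1.0,
        cis_fold=FoldSpec(kind="point", fold=1.0),
        noise_concentration=1e9, methylation=()))
    assert np.allclose(null.measurements["pct_allele1"], 50.0, atol=0.1)
    shifted = simulate_cohort(SimulationConfig(
        seed=1, breeds=(("X", 10),), assay_bias_b=1.0,
        cis_fold=FoldSpec(kind="point", fold=1.5),
        noise_concentration=1e9, methylation=()))
    cdna = shifted.measurements.query("material == 'cDNA'")
    gdna = shifted.measurements.query("material == 'gDNA'")
    assert np.allclose(cdna["pct_allele1"], 60.0, atol=0.1)  # 1.5/(1+1.5)
    assert np.allclose(gdna["pct_allele1"], 50.0, atol=0.1)


def test_ground_truth_consistent_with_measurement_model():
    cfg = SimulationConfig(seed=3, **SMALL)
    cohort = simulate_cohort(cfg)
    b = cfg.assay_bias_b
    for info in cohort.ground_truth["animals"].values():
        f = info["fold_odds_allele1"]
        assert info["expected_cdna_frac1"] == pytest.approx(b * f / (1 + b * f))
        assert info["expected_gdna_frac1"] == pytest.approx(b / (1 + b))
        assert info["ase_true"] == (core.neutralize(f) > 1.5)


def test_gdna_bias_recovered_from_simulation():
    """Mean raw gDNA ratio over ~200 heterozygotes recovers the generating
    incorporation bias b = 1.25 within 2%."""
    cfg = SimulationConfig(seed=20240817, breeds=(("X", 250),),
                           rsnp_het_fraction=0.9, assay_bias_b=1.25,
                           methylation=(), tissues=("vf",))
    cohort = simulate_cohort(cfg)
    gdna = cohort.measurements.query("material == 'gDNA'")
    raw = (gdna["pct_allele1"] / gdna["pct_allele2"]).groupby(gdna["sample_id"]).mean()
    assert core.estimate_gdna_bias(raw) == pytest.approx(1.25, rel=0.02)


def test_bidirectional_mode_symmetric_allele_choice():
    """With a symmetric two-point fold, allele-1-over and allele-2-over
    animals should be equally frequent (binomial test, n≈1000)."""
    cfg = SimulationConfig(
        seed=9, breeds=(("X", 2000),), rsnp_het_fraction=0.5,
        cis_fold=FoldSpec(kind="two_point", fold=2.0, ase_fraction=1.0),
        methylation=(), tissues=("vf",))
    cohort = simulate_cohort(cfg)
    over = [a["over_expressed_allele"] for a in cohort.ground_truth["animals"].values()]
    n1 = sum(1 for o in over if o == "A")
    n2 = sum(1 for o in over if o == "T")
    assert binomtest(n1, n1 + n2, 0.5).pvalue > 0.01


def test_default_scenario_ase_prevalence_calibration():
    """Under the default fat-tissue fold spread a realistic minority of
    samples (roughly 10–30%) should exceed the 60:40 threshold."""
    cfg = SimulationConfig(seed=13, breeds=(("X", 500),))
    cohort = simulate_cohort(cfg)
    cdna = cohort.measurements.query("material == 'cDNA' & tissue == 'visceral_fat'")
    raw = cdna["pct_allele1"] / cdna["pct_allele2"]
    per_sample = raw.groupby(cdna["sample_id"]).mean()
    gdna = cohort.measurements.query("material == 'gDNA'")
    bias = core.estimate_gdna_bias(
        (gdna["pct_allele1"] / gdna["pct_allele2"]).groupby(gdna["sample_id"]).mean()
    )
    calls = [core.classify_ase(r / bias).category for r in per_sample]
    frac = np.mean([c != "balanced" for c in calls])
    assert 0.10 <= frac <= 0.30


def test_candidate_ld_extremes():
    """At r² = 1 with matched frequencies the candidate SNP tags the causal
    variant exactly: every truly imbalanced het is a candidate het."""
    cfg = SimulationConfig(
        seed=21, breeds=(("X", 300),),
        candidate=CandidateSnpSpec(alt_freq=0.3, r2_with_causal=1.0),
        causal=CausalSpec(fold=2.0, alt_freq=0.3), methylation=())
    cohort = simulate_cohort(cfg)
    for info in cohort.ground_truth["animals"].values():
        is_cand_het = info["candidate_genotype"] in ("A/G", "G/A")
        assert info["causal_het"] == is_cand_het
        assert info["ase_true"] == is_cand_het


def test_config_validation_lists_problems():
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, rsnp_het_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, assay_bias_b=-1.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, candidate=CandidateSnpSpec(r2_with_causal=0.5))
    with pytest.raises(ConfigurationError):
        FoldSpec(kind="gaussian")


def test_grid_single_cell_manifest(tmp_path):
    manifest = simulate_null_and_power_grid(
        [{"id": "null", "fold": 1.0, "n_animals": 5}],
        base_seed=7, out_dir=tmp_path)
    assert len(manifest["cells"]) == 1
    cell = manifest["cells"][0]
    assert len(cell["seeds"]) == 1 and len(cell["datasets"]) == 1
    assert (tmp_path / cell["datasets"][0] / "measurements.tsv").exists()
    assert json.loads((tmp_path / "manifest.json").read_text()) == manifest


def test_grid_deterministic_across_runs(tmp_path):
    cells = [{"id": "a", "fold": 1.0, "n_animals": 4},
             {"id": "b", "fold": 1.5, "n_animals": 4}]
    m1 = simulate_null_and_power_grid(cells, base_seed=3, out_dir=tmp_path / "r1")
    m2 = simulate_null_and_power_grid(cells, base_seed=3, out_dir=tmp_path / "r2")
    assert m1["cells"][0]["seeds"] == m2["cells"][0]["seeds"]
    f1 = (tmp_path / "r1" / "a_rep0" / "measurements.tsv").read_bytes()
    f2 = (tmp_path / "r2" / "a_rep0" / "measurements.tsv").read_bytes()
    assert f1 == f2


def test_grid_rejects_duplicate_cells():
    with pytest.raises(ManifestError):
        simulate_null_and_power_grid(
            [{"id": "x"}, {"id": "x"}], base_seed=1)
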