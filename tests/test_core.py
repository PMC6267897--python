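"""Ratio arithmetic: percentage → ratio, bias normalization, replicate
averaging, neutralization and threshold classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroase import core
from pyroase.core import (
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    PyroMeasurement,
    average_replicates,
    classify_ase,
    compute_ratio,
    estimate_gdna_bias,
    neutralize,
    normalize_ratio,
)
from pyroase.errors import (
    ConfigurationError,
    InconsistentGroupError,
    InsufficientControlError,
    InvalidAssayError,
    InvalidMeasurementError,
)

positive_ratios = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        (60.0, 40.0, 1.5),          # the 60:40 proportion defining the threshold
        (50.0, 50.0, 1.0),
        (40.0, 60.0, 2.0 / 3.0),    # prints as 0.667
    ],
)
def test_compute_ratio_threshold_arithmetic(p1, p2, expected):
    assert compute_ratio(p1, p2) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "p1, p2",
    [(0.0, 100.0), (100.0, 0.0), (-5.0, 105.0), (60.0, 35.0), (float("nan"), 50.0)],
)
def test_compute_ratio_rejects_failed_assays(p1, p2):
    with pytest.raises(InvalidMeasurementError):
        compute_ratio(p1, p2)


def test_compute_ratio_monotone_in_allele1_percentage():
    """p/(100−p) must strictly increase with p: more allele-1 signal, larger
    ratio (grid check across the open percentage range)."""
    grid = np.linspace(0.5, 99.5, 397)
    ratios = [compute_ratio(p, 100.0 - p) for p in grid]
    assert all(b > a for a, b in zip(ratios, ratios[1:]))


def test_estimate_gdna_bias_is_arithmetic_mean():
    assert estimate_gdna_bias([1.0, 1.0, 1.0]) == 1.0
    assert estimate_gdna_bias([1.2, 1.4]) == pytest.approx(1.3)


def test_estimate_gdna_bias_needs_controls():
    with pytest.raises(InsufficientControlError):
        estimate_gdna_bias([])
    with pytest.raises(InvalidMeasurementError):
        estimate_gdna_bias([1.0, -0.2])


@pytest.mark.parametrize(
    "raw, bias, expected", [(1.2, 1.2, 1.0), (1.5, 1.0, 1.5), (0.9, 1.2, 0.75)]
)
def test_normalize_ratio(raw, bias, expected):
    assert normalize_ratio(raw, bias) == pytest.approx(expected)


def test_normalize_ratio_rejects_bad_bias():
    with pytest.raises(InvalidAssayError):
        normalize_ratio(1.2, 0.0)


@given(st.lists(st.floats(min_value=0.5, max_value=2.0), min_size=1, max_size=30))
@settings(deadline=None)
def test_bias_normalization_centres_gdna_on_one(raws):
    """Dividing gDNA ratios by their own mean must leave mean exactly 1."""
    bias = estimate_gdna_bias(raws)
    normalized = [normalize_ratio(r, bias) for r in raws]
    assert np.mean(normalized) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("r, expected", [(0.5, 2.0), (1.0, 1.0), (3.52, 3.52)])
def test_neutralize_examples(r, expected):
    assert neutralize(r) == pytest.approx(expected)


def test_neutralize_rejects_nonpositive():
    with pytest.raises(InvalidMeasurementError):
        neutralize(0.0)


@given(positive_ratios)
def test_neutralize_idempotent_and_log_identity(r):
    n = neutralize(r)
    assert n >= 1.0
    assert neutralize(n) == n
    assert math.log10(n) == pytest.approx(abs(math.log10(r)), abs=1e-12)


def test_average_replicates_normalizes_then_averages(make_measurement):
    ms = [
        make_measurement(1.4 * 1.2, replicate=1),
        make_measurement(1.6 * 1.2, replicate=2),
    ]
    ar = average_replicates(ms, gdna_bias=1.2)
    assert ar.normalized_ratio == pytest.approx(1.5, rel=1e-9)
    assert ar.replicate_sd == pytest.approx(math.sqrt(0.02), rel=1e-6)  # ≈0.1414
    assert ar.n_replicates == 2
    assert ar.neutralized_ratio == pytest.approx(1.5, rel=1e-9)
    assert ar.log10_ratio == pytest.approx(math.log10(1.5), rel=1e-9)


def test_average_replicates_singleton_and_constant(make_measurement):
    single = average_replicates([make_measurement(1.1)], gdna_bias=1.0)
    assert single.normalized_ratio == pytest.approx(1.1, rel=1e-9)
    assert single.replicate_sd == 0.0
    const = average_replicates(
        [make_measurement(0.8, replicate=i) for i in (1, 2, 3)], gdna_bias=1.0
    )
    assert const.normalized_ratio == pytest.approx(0.8, rel=1e-9)
    assert const.replicate_sd == pytest.approx(0.0, abs=1e-12)


def test_average_replicates_rejects_mixed_groups(make_measurement):
    with pytest.raises(InconsistentGroupError):
        average_replicates(
            [make_measurement(1.2, material="cDNA"), make_measurement(1.2, material="gDNA")]
        )
    with pytest.raises(InconsistentGroupError):
        average_replicates([])


@pytest.mark.parametrize(
    "ratio, category",
    [
        (2.23, "ase_allele1"),   # largest imbalance reported for PPARA
        (1.0, "balanced"),
        (0.41, "ase_allele2"),
        (1.5, "balanced"),       # exactly at threshold: strict inequality
        (DEFAULT_LOWER, "balanced"),
        (1.5000001, "ase_allele1"),
    ],
)
def test_classify_ase_thresholds(ratio, category):
    assert classify_ase(ratio).category == category


def test_classify_ase_rejects_bad_thresholds():
    with pytest.raises(ConfigurationError):
        classify_ase(1.0, lower=1.5, upper=0.667)
    with pytest.raises(ConfigurationError):
        classify_ase(1.0, lower=0.5, upper=0.9)


MIRROR = {"ase_allele1": "ase_allele2", "ase_allele2": "ase_allele1",
          "balanced": "balanced"}


@given(positive_ratios)
def test_classify_ase_mirror_symmetry(r):
    """Relabelling allele1 ↔ allele2 maps r → 1/r and must swap the ASE
    direction while leaving balanced calls fixed."""
    assert classify_ase(1.0 / r).category == MIRROR[classify_ase(r).category]


def test_classify_ase_uses_replicate_mean_ratio(make_measurement):
    ar = average_replicates([make_measurement(1.8)], gdna_bias=1.0)
    call = classify_ase(ar, tissue="visceral_fat")
    assert call.category == "ase_allele1"
    assert call.sample_id == "s1"
    assert call.ratio_used == pytest.approx(1.8, rel=1e-9)


def test_pyromeasurement_invariants():
    kwargs = dict(sample_id="s", gene="g", material="cDNA",
                  allele1_label="A", allele2_label="T")
    with pytest.raises(InvalidMeasurementError):
        PyroMeasurement(pct_allele1=0.0, pct_allele2=100.0, **kwargs)
    with pytest.raises(InvalidMeasurementError):
        PyroMeasurement(pct_allele1=60.0, pct_allele2=39.0, **kwargs)
    with pytest.raises(InvalidMeasurementError):
        PyroMeasurement(
            sample_id="s", gene="g", material="cDNA",
            allele1_label="A", allele2_label="A",
            pct_allele1=50.0, pct_allele2=50.0,
        )
    with pytest.raises(InvalidMeasurementError):
        PyroMeasurement(pct_allele1=50.0, pct_allele2=50.0, replicate=0, **kwargs)
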