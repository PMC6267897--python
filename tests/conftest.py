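"""Shared fixtures and the independent Welch oracle used to cross-check the
pipeline's t-test."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

from pyroase.core import PyroMeasurement


def welch_oracle(xs, ys):
    """Textbook Welch statistic, Welch–Satterthwaite df and two-sided p,
    computed from first principles (independent of scipy.stats.ttest_ind)."""
    x = [float(v) for v in xs]
    y = [float(v) for v in ys]
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stdtr(df, -abs(t)))
    return t, df, p


@pytest.fixture
def oracle():
    return welch_oracle


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def measurement_from_ratio(ratio: float, sample_id="s1", gene="PPARGC1A",
                           material="cDNA", replicate=1) -> PyroMeasurement:
    """Build a read-out whose raw allelic ratio equals ``ratio`` exactly."""
    pct1 = 100.0 * ratio / (1.0 + ratio)
    return PyroMeasurement(
        sample_id=sample_id,
        gene=gene,
        material=material,
        allele1_label="A",
        allele2_label="T",
        pct_allele1=pct1,
        pct_allele2=100.0 - pct1,
        replicate=replicate,
    )


@pytest.fixture
def make_measurement():
    return measurement_from_ratio
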