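"""Endpoint arithmetic and the normality-routed statistical workflow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phacotherm as pt
from phacotherm.clinical import StatsInputError, _friedman_two
from phacotherm.cohort import generate_cohort


# ----------------------------------------------------------------------
# percent cell loss
# ----------------------------------------------------------------------

def test_percent_loss_printed_groups():
    # viscoelastic arm: 122.2 of 2307 cells/mm^2 -> 5.3%
    assert pt.percent_cell_loss(2307, 122.2) == pytest.approx(5.3)
    # irrigation arm: raw value is 4.55% (reported rounded to 4.5)
    raw = pt.percent_cell_loss(2334, 106.2, ndigits=None)
    assert raw == pytest.approx(4.5501, abs=1e-3)


def test_percent_loss_edge_cases():
    assert pt.percent_cell_loss(1234.5, 0.0) == 0.0
    with pytest.raises(StatsInputError):
        pt.percent_cell_loss(0.0, 10.0)


@given(st.floats(0.1, 1e5), st.floats(0, 1e4), st.floats(0.01, 100))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_percent_loss_scale_invariance(pre, loss, c):
    a = pt.percent_cell_loss(pre, loss, ndigits=None)
    b = pt.percent_cell_loss(c * pre, c * loss, ndigits=None)
    assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


# ----------------------------------------------------------------------
# morphometry
# ----------------------------------------------------------------------

def test_morphometry_hand_example():
    s = pt.morphometry_summary([400.0, 500.0], [6, 5])
    assert s.ave == pytest.approx(450.0)
    assert s.cv == pytest.approx(100 * 70.7107 / 450.0, abs=1e-3)
    assert s.hex_pct == pytest.approx(50.0)
    assert s.ecd == pytest.approx(1e6 / 450.0)
    assert (s.min_area, s.max_area) == (400.0, 500.0)


def test_morphometry_uniform_field():
    s = pt.morphometry_summary([450.0] * 20, [6] * 20)
    assert s.cv == 0.0
    assert s.ave == 450.0
    assert s.hex_pct == 100.0


def test_morphometry_recovers_group_statistics():
    """Cell areas drawn at the preoperative group statistics are
    summarized back to them within Monte-Carlo error."""
    rng = np.random.default_rng(7)
    n = 4000
    target_ave, target_cv, target_hex = 457.7, 34.7, 60.4
    areas = np.maximum(rng.normal(target_ave, target_ave * target_cv / 100, n),
                       60.0)
    shapes = np.where(rng.random(n) < target_hex / 100, 6, 5)
    s = pt.morphometry_summary(areas, shapes)
    assert s.ave == pytest.approx(target_ave, rel=0.02)
    assert s.cv == pytest.approx(target_cv, rel=0.05)
    assert s.hex_pct == pytest.approx(target_hex, abs=2.5)


def test_morphometry_cv_scale_invariant():
    rng = np.random.default_rng(3)
    areas = rng.uniform(200, 900, 100)
    shapes = [6] * 100
    a = pt.morphometry_summary(areas, shapes)
    b = pt.morphometry_summary(areas * 3.7, shapes)
    assert b.cv == pytest.approx(a.cv, rel=1e-12)


def test_morphometry_empty_raises():
    with pytest.raises(StatsInputError):
        pt.morphometry_summary([], [])


# ----------------------------------------------------------------------
# normality screen
# ----------------------------------------------------------------------

def test_screen_normal_sample_parametric():
    x = np.random.default_rng(0).normal(0, 1, 300)
    assert pt.normality_screen(x).parametric


def test_screen_bimodal_nonparametric():
    """Two separated point masses: overwhelmingly routed nonparametric."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(-10, 0.1, 25),
                            rng.normal(10, 0.1, 25)])
        hits += not pt.normality_screen(x).parametric
    assert hits >= 95


def test_screen_constant_sample_warns():
    with pytest.warns(UserWarning, match="constant"):
        out = pt.normality_screen([5.0] * 10)
    assert out.outcome == "nonparametric"


def test_screen_small_sample_raises():
    with pytest.raises(StatsInputError):
        pt.normality_screen([1.0, 2.0])


# ----------------------------------------------------------------------
# group comparisons
# ----------------------------------------------------------------------

def test_identical_samples_null_result():
    x = np.arange(10.0)
    r = pt.compare_groups(x, x)
    assert r.statistic == 0.0 and r.pvalue == 1.0
    assert not r.significant


def test_matched_ages_not_significant():
    """Age-matched arms (both 71.2 +- ~10 y) should not differ."""
    df = generate_cohort(seed=0)
    a = df.loc[df.group == "BSS", "age"]
    b = df.loc[df.group == "Healon", "age"]
    r = pt.compare_groups(a, b, endpoint="age")
    assert r.test in ("t", "t-student")
    assert r.pvalue > 0.05


def test_shifted_groups_detected():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 60)
    b = rng.normal(2.0, 1, 60)
    r = pt.compare_groups(a, b)
    assert r.significant


def test_nonparametric_routing():
    rng = np.random.default_rng(2)
    a = np.concatenate([rng.normal(-8, 0.1, 30), rng.normal(8, 0.1, 30)])
    b = rng.normal(0, 1, 60)
    r = pt.compare_groups(a, b)
    assert r.test == "rank-sum"
    r2 = pt.compare_groups(a, b, study_routing=True)
    assert r2.test == "Friedman"
    assert 0 <= r2.pvalue <= 1


def test_friedman_two_treatment_reduction():
    # all pairs ordered the same way -> strongest possible chi2 for n
    a = np.zeros(20)
    b = np.ones(20)
    chi2, p = _friedman_two(a, b)
    assert chi2 == pytest.approx(20.0)
    assert p < 0.001


# ----------------------------------------------------------------------
# longitudinal course and IOP peaks
# ----------------------------------------------------------------------

def test_longitudinal_detects_bcva_recovery():
    """BCVA roughly triples after surgery: the within-group course must
    be overwhelmingly significant."""
    df = generate_cohort(seed=1)
    r = pt.longitudinal_course(df, "bcva", ["pre", "1d", "1w", "1m"],
                               group="BSS")
    assert r.significant


def test_longitudinal_requires_three_timepoints():
    df = generate_cohort(seed=0)
    with pytest.raises(StatsInputError):
        pt.longitudinal_course(df, "ecd", ["pre", "1d"])


def test_iop_peak_hand_count():
    import pandas as pd
    df = pd.DataFrame({"group": ["BSS"] * 5,
                       "iop_6h": [18.0, 21.0, 25.0, 20.0, 19.0]})
    assert pt.iop_peak_count(df) == 2          # strictly above 20
    assert pt.iop_peak_count(df, threshold=15) == 5


def test_iop_peak_no_peaks_and_missing_column():
    import pandas as pd
    df = pd.DataFrame({"group": ["BSS"] * 4, "iop_6h": [15.0] * 4})
    assert pt.iop_peak_count(df) == 0
    with pytest.raises(StatsInputError):
        pt.iop_peak_count(df, timepoint="2h")


def test_iop_peak_by_group_on_cohort():
    df = generate_cohort(seed=0)
    counts = pt.iop_peak_count(df, by_group=True)
    assert set(counts) == {"BSS", "Healon"}
    assert all(0 <= v <= 47 for v in counts.values())
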