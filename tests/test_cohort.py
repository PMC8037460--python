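"""Synthetic cohort generator: determinism, moments, correlation model."""

from dataclasses import replace

import numpy as np
import pytest

import phacotherm as pt
from phacotherm.cohort import (CohortSpec, CohortSpecError, generate_cohort,
                               rho_for_loss_sd)


def test_group_sizes_and_columns():
    df = generate_cohort(seed=3)
    assert len(df) == 47 + 45
    assert (df.group == "BSS").sum() == 47
    assert (df.group == "Healon").sum() == 45
    for col in ("age", "sex", "ecd_pre", "ecd_1d", "ecd_1w", "ecd_1m",
                "iop_pre", "iop_6h", "iop_1m", "bcva_pre", "bcva_1m",
                "ave_pre", "cv_pre", "hex_pre", "phaco_time_s", "ept_s",
                "locs3"):
        assert col in df.columns
        assert df[col].notna().all()
    # sex counts are exact
    assert (df.loc[df.group == "BSS", "sex"] == "F").sum() == 32
    assert (df.loc[df.group == "Healon", "sex"] == "F").sum() == 30


def test_same_seed_identical_different_seed_not():
    a = generate_cohort(seed=11).to_csv(index=False)
    b = generate_cohort(seed=11).to_csv(index=False)
    c = generate_cohort(seed=12).to_csv(index=False)
    assert a == b
    assert a != c


def test_zero_sd_degenerates_to_means():
    spec = CohortSpec()
    bss0 = replace(spec.bss, ecd_sd=(0.0,) * 4, iop_sd=(0.0,) * 5,
                   bcva_sd=(0.0,) * 4, age=(71.2, 0.0))
    df = generate_cohort(replace(spec, bss=bss0, age_ecl_slope=0.0), seed=5)
    sub = df[df.group == "BSS"]
    assert np.allclose(sub.ecd_pre, 2334.0)
    assert np.allclose(sub.ecd_1m, 2228.0)
    assert np.allclose(sub.iop_pre, 15.2)
    assert np.allclose(sub.age, 71.2)


def test_large_sample_moment_recovery():
    """Law of large numbers: at n = 10^4 the sample mean of the
    preoperative density sits within 3 standard errors of the target."""
    spec = CohortSpec()
    big = replace(spec, bss=replace(spec.bss, n=10_000, n_female=5_000))
    df = generate_cohort(big, seed=2)
    sub = df[df.group == "BSS"]
    se = 436 / np.sqrt(10_000)
    assert abs(sub.ecd_pre.mean() - 2334) < 3 * se
    sd_se = 436 / np.sqrt(2 * 10_000)
    assert abs(sub.ecd_pre.std(ddof=1) - 436) < 3 * sd_se


def test_within_patient_correlation_reproduces_loss_sd():
    """With rho_w solved from the printed one-month loss SD, the paired
    pre-minus-one-month SD is recovered."""
    rho = rho_for_loss_sd(436, 471, 226)
    assert 0.8 < rho < 0.95
    spec = CohortSpec(rho_w=rho, age_ecl_slope=0.0)
    big = replace(spec, bss=replace(spec.bss, n=20_000, n_female=10_000))
    df = generate_cohort(big, seed=4)
    sub = df[df.group == "BSS"]
    loss_sd = (sub.ecd_pre - sub.ecd_1m).std(ddof=1)
    assert loss_sd == pytest.approx(226, rel=0.05)


def test_infeasible_loss_sd_raises():
    with pytest.raises(CohortSpecError):
        rho_for_loss_sd(100, 100, 500)


def test_age_effect_increases_loss_for_older_patients():
    spec = CohortSpec(age_ecl_slope=10.0)
    big = replace(spec, bss=replace(spec.bss, n=20_000, n_female=10_000))
    df = generate_cohort(big, seed=6)
    sub = df[df.group == "BSS"]
    loss = sub.ecd_pre - sub.ecd_1m
    old = sub.age > sub.age.median()
    assert loss[old].mean() > loss[~old].mean()


@pytest.mark.parametrize("kwargs", [
    dict(rho_w=1.0), dict(rho_w=-0.1),
])
def test_invalid_spec_raises(kwargs):
    with pytest.raises(CohortSpecError):
        CohortSpec(**kwargs)


def test_invalid_group_raises():
    spec = CohortSpec()
    with pytest.raises(CohortSpecError):
        replace(spec, bss=replace(spec.bss, n=1)).bss.validate()
    with pytest.raises(CohortSpecError):
        replace(spec.bss, ecd_sd=(-1.0, 0, 0, 0)).validate()


def test_physical_truncation():
    df = generate_cohort(seed=9)
    assert (df.filter(like="ecd_") > 0).all().all()
    assert (df.filter(like="iop_") > 0).all().all()
    assert df.filter(like="bcva_").le(1.6).all().all()
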