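import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brainfuel.longitudinal import (
    RegionalLongitudinalModel,
    bh_fdr,
    build_regional_table,
    empirical_fdr_study,
    fit_mixed_linear,
)
from brainfuel.regional import Region, RegionAtlas
from brainfuel.synthetic import CohortSpec, simulate_cohort


def _cohort(seed, **spec_kwargs):
    return simulate_cohort(dataclasses.replace(CohortSpec(seed=seed), **spec_kwargs))


# ---------------------------------------------------------------- mixed model

def test_zero_noise_slope_recovered_exactly():
    cohort = _cohort(1, between_subject_sd=0.0, residual_sd=0.0)
    fit = fit_mixed_linear(cohort, "K_Precentral")
    assert fit.slope == pytest.approx(-0.0006, abs=1e-8)


def test_slope_recovery_over_simulated_cohorts():
    """Mean estimated slope over 200 cohorts generated at slope
    -0.0006 min^-1/yr (residual SD 0.004, between-subject SD 0.006)
    lies within the Monte-Carlo CI of the truth."""
    spec_region = {"Precentral": 0.057}
    slopes = []
    for seed in range(200):
        cohort = _cohort(
            seed,
            region_baseline_means=spec_region,
            region_slopes={"Precentral": -0.0006},
        )
        slopes.append(fit_mixed_linear(cohort, "K_Precentral").slope)
    slopes = np.asarray(slopes)
    ci = 1.96 * slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert abs(slopes.mean() - (-0.0006)) < ci + 1e-12


def test_type_i_error_calibrated_under_null():
    """With all regional slopes zero the slope test rejects at ~5%:
    empirical rate over 500 runs inside the 99% binomial CI of 0.05."""
    n_runs, alpha = 500, 0.05
    rejections = 0
    for seed in range(n_runs):
        cohort = _cohort(
            seed + 10_000,
            region_baseline_means={"Precentral": 0.057},
            region_slopes={"Precentral": 0.0},
        )
        rejections += fit_mixed_linear(cohort, "K_Precentral").p_value < alpha
    half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / n_runs)
    assert abs(rejections / n_runs - alpha) < half_width


def test_slope_invariant_to_age_shift():
    cohort = _cohort(4)
    base = fit_mixed_linear(cohort, "K_Thalamus")
    shifted = cohort.assign(age_yr=cohort["age_yr"] + 17.3)
    again = fit_mixed_linear(shifted, "K_Thalamus")
    assert again.slope == pytest.approx(base.slope, rel=1e-6)


def test_single_subject_rejected():
    cohort = _cohort(2)
    solo = cohort[cohort.subject_id == cohort.subject_id.iloc[0]]
    with pytest.raises(ValueError):
        fit_mixed_linear(solo, "K_Caudate")


# ------------------------------------------------------------------- BH-FDR

def _bh_oracle(p, q):
    """Exhaustive-threshold reference: reject at the largest p-value t
    such that t <= q * (#{p <= t}) / m; no such t means no rejections."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    best = None
    for t in sorted(p):
        if t <= q * (p <= t).sum() / m:
            best = t
    if best is None:
        return np.zeros(m, dtype=bool)
    return p <= best


def test_bh_small_family_all_rejected():
    reject, adjusted = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert reject.all()
    assert np.all(adjusted <= 0.05)


def test_bh_no_signal_none_rejected():
    reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
    assert not reject.any()


@given(
    p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10),
    q=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
)
def test_bh_matches_exhaustive_oracle(p, q):
    reject, _ = bh_fdr(p, q=q)
    assert np.array_equal(reject, _bh_oracle(p, q))


@given(p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_sandwiched_between_bonferroni_and_raw(p):
    q = 0.05
    reject, _ = bh_fdr(p, q=q)
    p_arr = np.asarray(p)
    bonf = p_arr <= q / len(p_arr)
    raw = p_arr <= q
    assert reject[bonf].all()          # never fewer than Bonferroni
    assert raw[reject].all()           # never more than raw thresholding


def test_bh_invalid_values_rejected():
    with pytest.raises(ValueError):
        bh_fdr([0.1, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([-0.01])
    with pytest.raises(ValueError):
        bh_fdr([])


def test_empirical_fdr_controlled():
    """Over 300 simulated 43-region slope families with 10 true effects
    the BH step keeps the empirical FDR at or below ~q."""
    efdr = empirical_fdr_study(n_regions=43, n_nonnull=10, n_reps=300, q=0.05, seed=2)
    assert efdr <= 0.08


# ------------------------------------------------------- regional table layer

def test_regional_table_shape_and_order(atlas):
    cohort = _cohort(6)
    res = build_regional_table(cohort, atlas, q=0.05)
    assert list(res.frame["region"]) == atlas.names
    assert set(["T0", "T2", "T4", "SEM", "fixed_effect", "p_value", "fdr_significant"]).issubset(
        res.frame.columns
    )
    assert res.frame["p_value"].between(0, 1).all()


def test_regional_table_flags_missing_region(atlas):
    cohort = _cohort(7).drop(columns=["K_Insula"])
    res = build_regional_table(cohort, atlas, q=0.05)
    row = res.frame.set_index("region").loc["Insula"]
    assert bool(row["missing"]) and np.isnan(row["fixed_effect"])
    assert not row["fdr_significant"]


def test_regional_table_single_subject_rejected(atlas):
    cohort = _cohort(8)
    solo = cohort[cohort.subject_id == cohort.subject_id.iloc[0]]
    with pytest.raises(ValueError):
        build_regional_table(solo, atlas)


def test_null_cohort_rarely_rejects_after_fdr():
    """With every regional slope zero the report's FDR flags fire in at
    most ~q of the replicates (family-wise empirical FDR under the
    global null)."""
    names = [f"R{i}" for i in range(10)]
    mini_atlas = RegionAtlas(tuple(Region(i + 1, n, "frontal") for i, n in enumerate(names)))
    means = {n: 0.05 for n in names}
    slopes = {n: 0.0 for n in names}
    n_runs, q = 100, 0.05
    any_rejection = 0
    for seed in range(n_runs):
        cohort = _cohort(seed + 500, region_baseline_means=means, region_slopes=slopes)
        res = build_regional_table(cohort, mini_atlas, q=q)
        any_rejection += bool(res.frame["fdr_significant"].any())
    # under the global null FDP is 0/1, so the empirical FDR is the
    # fraction of replicates with any rejection; allow 2 binomial SDs
    assert any_rejection / n_runs <= q + 2 * np.sqrt(q * (1 - q) / n_runs)


def test_simulated_table2_cohort_recovers_slope_signs(atlas):
    """Cohorts generated from the glucose reference means and slopes at
    low noise reproduce the sign of every fixed-effect estimate in at
    least 90% of region-fits."""
    spec0 = CohortSpec(seed=0)
    true_signs = np.sign([spec0.region_slopes[r] for r in atlas.names])
    match = total = 0
    for seed in range(15):
        cohort = _cohort(seed, between_subject_sd=0.002, residual_sd=0.001)
        res = build_regional_table(cohort, atlas, q=0.05)
        est_signs = np.sign(res.frame["fixed_effect"].to_numpy())
        match += (est_signs == true_signs).sum()
        total += len(true_signs)
    assert match / total >= 0.90
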