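"""Generator correctness: determinism, twin-sharing structure, outlier plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twindelta.preprocess import compute_delta, mask_outliers
from twindelta.simulate import (
    ConfigurationError,
    SimConfig,
    TraitSpec,
    generate_cohort,
    inject_outliers,
)

from conftest import make_trait, pair_correlation, simulate_cohort, simulated_deltas


def test_seeded_determinism_byte_identical():
    cfg = SimConfig(n_mz_pairs=30, n_dz_pairs=25, traits=[make_trait()], seed=11)
    a = generate_cohort(cfg).to_csv(index=False)
    b = generate_cohort(cfg).to_csv(index=False)
    assert a == b
    c = generate_cohort(SimConfig(n_mz_pairs=30, n_dz_pairs=25, traits=[make_trait()], seed=12))
    assert c.to_csv(index=False) != a


def test_row_counts_ids_and_zygosity_labels():
    cfg = SimConfig(n_mz_pairs=7, n_dz_pairs=5, traits=[make_trait()], seed=3)
    table = generate_cohort(cfg)
    assert len(table) == 2 * (7 + 5) * 2
    assert set(table["zygosity"]) == {"MZ", "DZ"}
    assert table.groupby("pair_id")["twin_id"].nunique().eq(2).all()
    assert not table.duplicated(["twin_id", "time"]).any()
    assert (table.groupby("pair_id")["zygosity"].nunique() == 1).all()
    assert (table.groupby("pair_id")["age_baseline"].nunique() == 1).all()


@settings(max_examples=20, derandomize=True, deadline=None)
@given(n_mz=st.integers(0, 6), n_dz=st.integers(0, 6), seed=st.integers(0, 1000))
def test_row_count_property(n_mz, n_dz, seed):
    cfg = SimConfig(n_mz_pairs=n_mz, n_dz_pairs=n_dz, traits=[make_trait()], seed=seed)
    table = generate_cohort(cfg)
    assert len(table) == 4 * (n_mz + n_dz)
    assert table["twin_id"].nunique() == 2 * (n_mz + n_dz)


def test_independent_change_has_zero_pair_correlation():
    deltas = simulated_deltas(5000, (0.0, 0.0, 0.0, 1.0), seed=5)
    assert abs(pair_correlation(deltas, "MZ")) < 0.04
    assert abs(pair_correlation(deltas, "DZ")) < 0.04


def test_change_correlations_match_biometric_algebra():
    # a2=0.5, c2=0.2 -> rMZ = 0.70, rDZ = 0.45
    deltas = simulated_deltas(5000, (0.5, 0.2, 0.0, 0.3), seed=6)
    assert pair_correlation(deltas, "MZ") == pytest.approx(0.70, abs=0.03)
    assert pair_correlation(deltas, "DZ") == pytest.approx(0.45, abs=0.03)


def test_dominance_sharing_quarter_in_dz():
    # a2=0.2, d2=0.5 -> rMZ = 0.70, rDZ = 0.225
    deltas = simulated_deltas(5000, (0.2, 0.0, 0.5, 0.3), seed=7)
    assert pair_correlation(deltas, "MZ") == pytest.approx(0.70, abs=0.03)
    assert pair_correlation(deltas, "DZ") == pytest.approx(0.225, abs=0.03)


def test_change_variance_matches_total_sd():
    deltas = simulated_deltas(5000, (0.5, 0.2, 0.0, 0.3), seed=8, sd_change=0.7)
    assert np.var(deltas["delta"]) == pytest.approx(0.49, rel=0.05)


def test_level_and_change_effects_enter_time2():
    cfg = SimConfig(
        n_mz_pairs=2000,
        n_dz_pairs=0,
        traits=[make_trait(beta_time=0.5, beta_age=0.01)],
        follow_up_years=10.0,
        seed=9,
    )
    deltas = compute_delta(generate_cohort(cfg), "X")
    # mean change = beta_time + beta_age * follow_up
    assert deltas["delta"].mean() == pytest.approx(0.6, abs=0.05)


@pytest.mark.parametrize(
    "bad",
    [
        {"var_change": (0.5, 0.2, 0.2, 0.1)},  # c2 and d2 jointly nonzero
        {"var_change": (0.7, 0.0, 0.0, 0.2)},  # does not sum to 1
        {"var_change": (1.0, 0.0, 0.0, 0.0)},  # e2 = 0
        {"var_change": (-0.1, 0.0, 0.0, 1.1)},  # negative entry
    ],
)
def test_invalid_trait_config_raises_naming_trait(bad):
    spec = make_trait(**bad)
    cfg = SimConfig(n_mz_pairs=2, n_dz_pairs=2, traits=[spec], seed=0)
    with pytest.raises(ConfigurationError, match="X"):
        generate_cohort(cfg)


def test_invalid_cohort_config():
    with pytest.raises(ConfigurationError):
        generate_cohort(SimConfig(n_mz_pairs=-1, n_dz_pairs=0, traits=[], seed=0))
    with pytest.raises(ConfigurationError):
        generate_cohort(SimConfig(n_mz_pairs=1, n_dz_pairs=1, traits=[], prop_female=1.5, seed=0))


class TestInjectOutliers:
    def test_rate_zero_is_identity(self, small_cohort):
        spec = make_trait(outlier_rate=0.0)
        out, ids = inject_outliers(small_cohort, spec, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort)
        assert ids == []

    def test_bookkeeping_count(self):
        table = simulate_cohort(2500, (0.4, 0.0, 0.0, 0.6), seed=13, n_dz=0)  # 10,000 records
        spec = make_trait(outlier_rate=0.01, outlier_magnitude=6.0)
        out, ids = inject_outliers(table, spec, seed=2)
        assert len(ids) == 100
        changed = (out["X"] != table["X"]).sum()
        assert changed == len(ids)

    def test_low_magnitude_warns(self, small_cohort):
        spec = make_trait(outlier_rate=0.01, outlier_magnitude=2.0)
        with pytest.warns(UserWarning, match="3-SD"):
            inject_outliers(small_cohort, spec, seed=3)

    def test_injected_six_sd_outliers_all_masked(self):
        table = simulate_cohort(2500, (0.4, 0.0, 0.0, 0.6), seed=14)
        spec = make_trait(outlier_rate=0.01, outlier_magnitude=6.0)
        perturbed, ids = inject_outliers(table, spec, seed=4)
        _, masked = mask_outliers(perturbed, "X", k_sd=3.0)
        assert set(ids) <= set(masked)
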