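"""Shared fixtures and small data factories for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twindelta.simulate import SimConfig, TraitSpec, generate_cohort


def make_trait(
    var_change=(0.4, 0.0, 0.0, 0.6),
    var_level=(0.5, 0.0, 0.0, 0.5),
    beta_time=0.0,
    beta_age=0.0,
    beta_sex=0.0,
    sd_change=1.0,
    sd_level=1.0,
    lognormal=False,
    name="X",
    **kw,
) -> TraitSpec:
    return TraitSpec(
        name=name,
        var_level=var_level,
        var_change=var_change,
        total_sd_level=sd_level,
        total_sd_change=sd_change,
        beta_time=beta_time,
        beta_age=beta_age,
        beta_sex=beta_sex,
        lognormal=lognormal,
        **kw,
    )


def simulate_cohort(n_pairs, var_change, seed, n_dz=None, **trait_kw) -> pd.DataFrame:
    """One-trait cohort with n_pairs MZ and n_dz (default n_pairs) DZ pairs."""
    cfg = SimConfig(
        n_mz_pairs=n_pairs,
        n_dz_pairs=n_pairs if n_dz is None else n_dz,
        traits=[make_trait(var_change=var_change, **trait_kw)],
        seed=seed,
    )
    return generate_cohort(cfg)


def delta_frame(pairs_by_zyg: dict) -> pd.DataFrame:
    """Build a DeltaTable directly from {zygosity: [(d1, d2), ...]} pairs."""
    rows = []
    for zyg, pairs in pairs_by_zyg.items():
        for i, (d1, d2) in enumerate(pairs):
            for m, d in ((1, d1), (2, d2)):
                rows.append(
                    {
                        "pair_id": f"{zyg}{i:05d}",
                        "twin_id": f"{zyg}{i:05d}_{m}",
                        "zygosity": zyg,
                        "sex": m - 1,
                        "age_baseline": 40.0 + (i % 20),
                        "baseline_value": 0.0,
                        "delta": d,
                    }
                )
    return pd.DataFrame(rows)


def simulated_deltas(n_pairs, var_change, seed, **trait_kw) -> pd.DataFrame:
    """Deltas of a simulated one-trait cohort, no transform/masking."""
    from twindelta.preprocess import compute_delta

    table = simulate_cohort(n_pairs, var_change, seed, **trait_kw)
    return compute_delta(table, "X")


def pair_correlation(deltas: pd.DataFrame, zygosity: str) -> float:
    """Double-entry (intraclass) correlation of pair-ordered deltas."""
    from twindelta.preprocess import complete_pairs

    y = complete_pairs(deltas, zygosity)[["delta_1", "delta_2"]].to_numpy()
    dev = y - y.mean()
    return float(np.mean(dev[:, 0] * dev[:, 1]) / np.mean(dev**2))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Deterministic 80+80-pair cohort with one lognormal trait, reused across tests."""
    cfg = SimConfig(
        n_mz_pairs=80,
        n_dz_pairs=80,
        traits=[
            make_trait(name="X", var_change=(0.5, 0.0, 0.0, 0.5), beta_time=0.2),
            make_trait(
                name="L",
                var_change=(0.3, 0.2, 0.0, 0.5),
                beta_time=0.1,
                sd_level=0.3,
                sd_change=0.2,
                lognormal=True,
            ),
        ],
        seed=42,
    )
    return generate_cohort(cfg)
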