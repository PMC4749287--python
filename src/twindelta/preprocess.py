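"""Cleaning rules and Δphenotype construction.

Fixed pipeline order per trait: natural-log transform (if enabled) → single
3-SD outlier mask on the pooled (both occasions) transformed values →
within-individual difference Δ = value(time 2) − value(time 1).  The mask is
applied once, not iteratively, and missingness propagates into Δ.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "log_transform",
    "mask_outliers",
    "compute_delta",
    "preprocess_trait",
    "complete_pairs",
    "DELTA_COLUMNS",
]

DELTA_COLUMNS = ["pair_id", "twin_id", "zygosity", "sex", "age_baseline", "baseline_value", "delta"]


def log_transform(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Natural log of one trait column; missing values preserved.

    Raises ``ValueError`` naming the offending record if any non-missing value
    is ≤ 0.
    """
    values = table[trait]
    bad = values.notna() & (values <= 0)
    if bad.any():
        row = table.loc[bad.idxmax()]
        raise ValueError(
            f"log transform of {trait!r}: nonpositive value {row[trait]!r} "
            f"at twin_id={row['twin_id']!r}, time={row['time']!r}"
        )
    out = table.copy()
    out[trait] = np.log(values.astype(float))
    return out


def mask_outliers(
    table: pd.DataFrame, trait: str, k_sd: float = 3.0
) -> tuple[pd.DataFrame, list]:
    """Set values more than ``k_sd`` sample SDs from the pooled mean to missing.

    Mean and SD (ddof=1) are computed once over all non-missing values of the
    trait, both occasions pooled; the rule is applied in a single pass.
    Returns the masked copy and the ``(twin_id, time)`` ids that were masked.
    A zero SD masks nothing and emits a warning.
    """
    values = table[trait].astype(float)
    nonmiss = values.dropna()
    if len(nonmiss) < 2:
        raise ValueError(f"mask_outliers({trait!r}): need >= 2 non-missing values")
    mean = float(nonmiss.mean())
    sd = float(nonmiss.std(ddof=1))
    out = table.copy()
    if sd == 0.0:
        warnings.warn(f"{trait!r} has zero SD; no outlier masking applied", stacklevel=2)
        return out, []
    mask = values.notna() & ((values - mean).abs() > k_sd * sd)
    out.loc[mask, trait] = np.nan
    ids = list(zip(table.loc[mask, "twin_id"], table.loc[mask, "time"]))
    return out, ids


def compute_delta(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-individual change score with baseline value and pair metadata.

    delta = value(time 2) − value(time 1); missing at either occasion gives a
    missing delta.  One row per individual.
    """
    wide = table.pivot_table(
        index="twin_id", columns="time", values=trait, aggfunc="first", dropna=False
    )
    meta = (
        table[["twin_id", "pair_id", "zygosity", "sex", "age_baseline"]]
        .drop_duplicates("twin_id")
        .set_index("twin_id")
    )
    out = meta.copy()
    t1 = wide[1] if 1 in wide.columns else pd.Series(np.nan, index=wide.index)
    t2 = wide[2] if 2 in wide.columns else pd.Series(np.nan, index=wide.index)
    out["baseline_value"] = t1
    out["delta"] = t2 - t1
    out = out.reset_index().sort_values("twin_id", kind="stable").reset_index(drop=True)
    return out[DELTA_COLUMNS]


def preprocess_trait(
    table: pd.DataFrame, trait: str, log: bool = True, k_sd: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Full cleaning pipeline for one trait.

    Returns ``(cleaned cohort table, delta table, masked record ids)``.
    """
    cleaned = log_transform(table, trait) if log else table
    cleaned, masked = mask_outliers(cleaned, trait, k_sd=k_sd)
    return cleaned, compute_delta(cleaned, trait), masked


def complete_pairs(deltas: pd.DataFrame, zygosity: str | None = None) -> pd.DataFrame:
    """Pair-wide table keeping only pairs where both co-twins have a delta.

    Columns: ``pair_id, zygosity, delta_1, delta_2`` plus per-member
    ``sex_<m>, age_<m>, baseline_<m>``; member order follows twin_id sort.
    """
    d = deltas if zygosity is None else deltas[deltas["zygosity"] == zygosity]
    d = d.sort_values(["pair_id", "twin_id"], kind="stable")
    sizes = d.groupby("pair_id")["twin_id"].transform("size")
    d = d[sizes == 2]
    cols = [
        "pair_id", "zygosity", "delta_1", "delta_2",
        "sex_1", "sex_2", "age_1", "age_2", "baseline_1", "baseline_2",
    ]
    if d.empty:
        return pd.DataFrame(columns=cols)
    first = d.iloc[0::2].reset_index(drop=True)
    second = d.iloc[1::2].reset_index(drop=True)
    wide = pd.DataFrame(
        {
            "pair_id": first["pair_id"],
            "zygosity": first["zygosity"],
            "delta_1": first["delta"].to_numpy(dtype=float),
            "delta_2": second["delta"].to_numpy(dtype=float),
            "sex_1": first["sex"].to_numpy(),
            "sex_2": second["sex"].to_numpy(),
            "age_1": first["age_baseline"].to_numpy(dtype=float),
            "age_2": second["age_baseline"].to_numpy(dtype=float),
            "baseline_1": first["baseline_value"].to_numpy(dtype=float),
            "baseline_2": second["baseline_value"].to_numpy(dtype=float),
        }
    )
    keep = wide["delta_1"].notna() & wide["delta_2"].notna()
    return wide[keep].reset_index(drop=True)[cols]
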