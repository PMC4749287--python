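"""Synthetic twin-cohort generator with known genetic/environmental architecture.

Each trait is generated on an underlying normal scale from the classical
biometric model.  A latent score for component X ∈ {A, C, D, E} is built as a
mixture of a pair-shared and an individual standard-normal draw,

    score = sqrt(w) * shared + sqrt(1 - w) * individual,

where w is the expected cross-twin correlation of that component:
A: 1 (MZ) / 0.5 (DZ);  C: 1 / 1;  D: 1 / 0.25;  E: 0 / 0.  This reproduces the
classical covariance algebra exactly — within-pair correlation of the summed
deviation equals a²+c²+d² for MZ and ½a²+c²+¼d² for DZ pairs.  Separate,
independent component sets drive the baseline level and the longitudinal
change, so level and change can have different architectures.

The observation model is

    y(t) = mu + beta_age * age(t) + beta_sex * sex + beta_time * t
           + level_deviation + t * change_deviation,        t ∈ {0, 1}

with age(t) = baseline age + t * follow-up years, so the within-individual
change is beta_time + beta_age * follow_up + change_deviation.  Traits flagged
lognormal are exponentiated, which makes the downstream natural-log transform
recover the generative scale exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TraitSpec", "SimConfig", "generate_cohort", "inject_outliers", "COHORT_COLUMNS"]

#: fixed metadata columns of a cohort table; trait columns follow.
COHORT_COLUMNS = ["pair_id", "twin_id", "zygosity", "sex", "age_baseline", "time"]

# expected cross-twin correlation of each latent component, per zygosity
_SHARING = {
    "MZ": {"a": 1.0, "c": 1.0, "d": 1.0, "e": 0.0},
    "DZ": {"a": 0.5, "c": 1.0, "d": 0.25, "e": 0.0},
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class TraitSpec:
    """Generative description of one phenotype.

    ``var_level`` and ``var_change`` are (a2, c2, d2, e2) proportions for the
    baseline level and for the change component respectively; each must be a
    nonnegative vector summing to 1 with e2 > 0 and at most one of c2/d2
    nonzero (C and D are not jointly identifiable in a twin design, and the
    generator enforces the same restriction for clarity).
    """

    name: str
    mu_baseline: float = 0.0
    var_level: tuple = (0.5, 0.0, 0.0, 0.5)
    var_change: tuple = (0.4, 0.0, 0.0, 0.6)
    total_sd_level: float = 1.0
    total_sd_change: float = 1.0
    beta_time: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    lognormal: bool = False
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0

    def validate(self) -> None:
        for label, props in (("var_level", self.var_level), ("var_change", self.var_change)):
            props = tuple(float(p) for p in props)
            if len(props) != 4:
                raise ConfigurationError(
                    f"trait {self.name!r}: {label} must have 4 entries (a2, c2, d2, e2)"
                )
            if any(p < 0 for p in props):
                raise ConfigurationError(f"trait {self.name!r}: {label} has negative entries")
            if abs(sum(props) - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"trait {self.name!r}: {label} must sum to 1, got {sum(props):g}"
                )
            if props[1] > 0 and props[2] > 0:
                raise ConfigurationError(
                    f"trait {self.name!r}: {label} has both c2 and d2 nonzero"
                )
            if props[3] <= 0:
                raise ConfigurationError(f"trait {self.name!r}: {label} requires e2 > 0")
        if self.total_sd_level <= 0 or self.total_sd_change <= 0:
            raise ConfigurationError(f"trait {self.name!r}: total SDs must be positive")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ConfigurationError(f"trait {self.name!r}: outlier_rate must be in [0, 1)")


@dataclass
class SimConfig:
    """Design of a simulated two-occasion twin cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    traits: list = field(default_factory=list)
    age_range: tuple = (18.0, 67.0)
    prop_female: float = 0.5
    follow_up_years: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ConfigurationError("pair counts must be nonnegative")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must be in [0, 1]")
        lo, hi = self.age_range
        if lo > hi:
            raise ConfigurationError("age_range min must not exceed max")
        if self.follow_up_years < 0:
            raise ConfigurationError("follow_up_years must be nonnegative")
        for t in self.traits:
            t.validate()


def _component_scores(rng: np.random.Generator, n_pairs: int, weight: float) -> np.ndarray:
    """(n_pairs, 2) standard-normal scores with cross-twin correlation ``weight``."""
    shared = rng.standard_normal((n_pairs, 1))
    individual = rng.standard_normal((n_pairs, 2))
    return np.sqrt(weight) * shared + np.sqrt(1.0 - weight) * individual


def _deviations(
    rng: np.random.Generator, n_pairs: int, zygosity: str, props, total_sd: float
) -> np.ndarray:
    """Summed biometric deviation, (n_pairs, 2)."""
    out = np.zeros((n_pairs, 2))
    for prop, comp in zip(props, ("a", "c", "d", "e")):
        # draw even when prop == 0 so the RNG stream does not depend on the
        # architecture and configs differing only in proportions stay comparable
        scores = _component_scores(rng, n_pairs, _SHARING[zygosity][comp])
        if prop > 0:
            out += np.sqrt(prop) * total_sd * scores
    return out


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a long-format cohort table (one row per individual per occasion).

    Returns 2·(n_mz + n_dz)·2 rows with columns ``pair_id, twin_id, zygosity,
    sex, age_baseline, time`` followed by one column per trait.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    frames = []
    for zygosity, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        if n_pairs == 0:
            continue
        pair_ids = np.array([f"{zygosity}{i + 1:05d}" for i in range(n_pairs)])
        age = rng.uniform(lo, hi, size=n_pairs)  # twins share a birth date
        sex = (rng.random((n_pairs, 2)) < config.prop_female).astype(int)  # 1 = female

        values = {}
        for spec in config.traits:
            level = _deviations(rng, n_pairs, zygosity, spec.var_level, spec.total_sd_level)
            change = _deviations(rng, n_pairs, zygosity, spec.var_change, spec.total_sd_change)
            y1 = (
                spec.mu_baseline
                + spec.beta_age * age[:, None]
                + spec.beta_sex * sex
                + level
            )
            y2 = y1 + spec.beta_time + spec.beta_age * config.follow_up_years + change
            if spec.lognormal:
                y1, y2 = np.exp(y1), np.exp(y2)
            values[spec.name] = (y1, y2)

        base = pd.DataFrame(
            {
                "pair_id": np.repeat(pair_ids, 2),
                "twin_id": [f"{p}_{m + 1}" for p in pair_ids for m in range(2)],
                "zygosity": zygosity,
                "sex": sex.ravel(),
                "age_baseline": np.repeat(age, 2),
            }
        )
        for time, idx in ((1, 0), (2, 1)):
            block = base.copy()
            block["time"] = time
            for name, (y1, y2) in values.items():
                block[name] = (y1 if time == 1 else y2).ravel()
            frames.append(block)

    if not frames:
        cols = COHORT_COLUMNS + [t.name for t in config.traits]
        return pd.DataFrame(columns=cols)

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["pair_id", "twin_id", "time"], kind="stable").reset_index(drop=True)
    return table[COHORT_COLUMNS + [t.name for t in config.traits]]


def inject_outliers(
    table: pd.DataFrame, spec: TraitSpec, seed: int = 0
) -> tuple[pd.DataFrame, list]:
    """Displace a random fraction of one trait's records far from the mean.

    A fraction ``spec.outlier_rate`` of the non-missing records of
    ``spec.name`` is moved to mean ± ``spec.outlier_magnitude`` · SD (sign
    random), where mean and SD are computed before injection.  Returns the
    perturbed copy and the list of displaced ``(twin_id, time)`` record ids,
    so tests can check the 3-SD mask removes them.
    """
    if not 0.0 <= spec.outlier_rate < 1.0:
        raise ConfigurationError(f"trait {spec.name!r}: outlier_rate must be in [0, 1)")
    if spec.outlier_magnitude <= 3.0:
        warnings.warn(
            f"outlier_magnitude {spec.outlier_magnitude:g} <= 3: injected outliers "
            "may survive a 3-SD mask",
            stacklevel=2,
        )
    out = table.copy()
    if spec.outlier_rate == 0.0:
        return out, []

    rng = np.random.default_rng(seed)
    col = out[spec.name]
    eligible = np.flatnonzero(col.notna().to_numpy())
    n_out = int(round(spec.outlier_rate * eligible.size))
    if n_out == 0:
        return out, []
    chosen = rng.choice(eligible, size=n_out, replace=False)
    mean = float(col.iloc[eligible].mean())
    sd = float(col.iloc[eligible].std(ddof=1))
    signs = rng.choice([-1.0, 1.0], size=n_out)
    out.iloc[chosen, out.columns.get_loc(spec.name)] = mean + signs * spec.outlier_magnitude * sd
    ids = list(zip(out["twin_id"].iloc[chosen], out["time"].iloc[chosen]))
    return out, ids


def danish_like_config(seed: int = 0) -> SimConfig:
    """Cohort design emulating a large northern-European adult twin sample.

    226 MZ + 276 DZ complete pairs, baseline ages 18–67, ~54% female, 12-year
    follow-up, 12 log-normal metabolic traits.  The change-component
    architectures are moderate additive-genetic / unique-environment mixes
    typical of adult metabolic change (AE-like for most traits, CE-like for
    triglycerides and hip circumference).
    """
    return SimConfig(
        n_mz_pairs=226,
        n_dz_pairs=276,
        traits=_metabolic_traits(
            {
                "TC": (0.48, 0.0, 0.52),
                "TG": (0.0, 0.28, 0.72),
                "HDL": (0.44, 0.0, 0.56),
                "LDL": (0.49, 0.0, 0.51),
                "GLU": (0.39, 0.0, 0.61),
                "WT": (0.39, 0.0, 0.61),
                "BMI": (0.39, 0.0, 0.61),
                "WAIST": (0.40, 0.0, 0.60),
                "HIP": (0.0, 0.43, 0.57),
                "WHR": (0.45, 0.0, 0.55),
                "SBP": (0.36, 0.0, 0.64),
                "DBP": (0.47, 0.0, 0.53),
            }
        ),
        age_range=(18.0, 67.0),
        prop_female=0.54,
        follow_up_years=12.0,
        seed=seed,
    )


def chinese_like_config(seed: int = 0) -> SimConfig:
    """Cohort design emulating a smaller east-Asian adult twin sample.

    101 MZ + 80 DZ pairs, baseline ages 23–64, ~68% female, 7-year follow-up;
    change architectures lean AE for blood biochemistry and CE for body-mass
    traits.
    """
    return SimConfig(
        n_mz_pairs=101,
        n_dz_pairs=80,
        traits=_metabolic_traits(
            {
                "TC": (0.54, 0.0, 0.46),
                "TG": (0.59, 0.0, 0.41),
                "HDL": (0.0, 0.66, 0.34),
                "LDL": (0.54, 0.0, 0.46),
                "GLU": (0.58, 0.0, 0.42),
                "WT": (0.0, 0.36, 0.64),
                "BMI": (0.0, 0.31, 0.69),
                "WAIST": (0.0, 0.42, 0.58),
                "HIP": (0.0, 0.39, 0.61),
                "WHR": (0.0, 0.45, 0.55),
                "SBP": (0.28, 0.0, 0.72),
                "DBP": (0.0, 0.27, 0.73),
            }
        ),
        age_range=(23.0, 64.0),
        prop_female=0.68,
        follow_up_years=7.0,
        seed=seed,
    )


# (mu on log scale, sd_level, sd_change, beta_time) per metabolic trait
_TRAIT_SCALES = {
    "TC": (1.68, 0.18, 0.12, 0.02),
    "TG": (0.18, 0.45, 0.30, -0.03),
    "HDL": (0.42, 0.22, 0.13, 0.02),
    "LDL": (1.18, 0.25, 0.16, 0.02),
    "GLU": (1.56, 0.10, 0.07, 0.15),
    "WT": (4.28, 0.16, 0.06, 0.05),
    "BMI": (3.19, 0.14, 0.06, 0.05),
    "WAIST": (4.43, 0.12, 0.06, 0.05),
    "HIP": (4.57, 0.07, 0.04, 0.06),
    "WHR": (-0.14, 0.08, 0.05, -0.01),
    "SBP": (4.76, 0.10, 0.07, 0.06),
    "DBP": (4.22, 0.11, 0.08, 0.15),
}


def _metabolic_traits(ace_change: dict) -> list:
    """Build TraitSpec list; ``ace_change`` maps trait -> (a2, c2, e2) of change."""
    traits = []
    for name, (a2, c2, e2) in ace_change.items():
        mu, sd_lvl, sd_chg, b_time = _TRAIT_SCALES[name]
        traits.append(
            TraitSpec(
                name=name,
                mu_baseline=mu,
                var_level=(0.5, 0.1, 0.0, 0.4),
                var_change=(a2, c2, 0.0, e2),
                total_sd_level=sd_lvl,
                total_sd_change=sd_chg,
                beta_time=b_time,
                beta_age=0.002,
                beta_sex=-0.02,
                lognormal=True,
            )
        )
    return traits


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
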