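"""Kinship-structured Gaussian mixed model for mean longitudinal change.

Model for phenotype value y of individual i at occasion t ∈ {0, 1}:

    y_it = β0 + β1·age_i + β2·sex_i + β3·t + g_i + p_i + ε_it

with a genetic random effect g correlated 1.0 between MZ co-twins and 0.5
between DZ co-twins (variance σg²), an individual random intercept p linking
the two occasions of one person (σp²), and an independent residual ε (σe²).
Each twin pair contributes a block of up to 4 observations (2 co-twins × 2
occasions) with covariance

    V = σg²·K_g + σp²·K_p + σe²·I,

K_g the kinship pattern, K_p the per-person block pattern.  Fitting is full
maximum likelihood: the fixed effects are profiled out by GLS at each
variance evaluation and the variances are optimized on the log scale (which
enforces nonnegativity).  The test of mean change is the Wald statistic
β3 / SE(β3) against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedFit", "fit_longitudinal_mixed", "fixed_effect_residuals"]

_FIXED_EFFECTS = ("intercept", "age", "sex", "time")

_PENALTY = 1e12  # large finite objective for rejected variance points

# slot order within a pair block: (member 1, t1), (member 1, t2), (member 2, t1), (member 2, t2)
_KP4 = np.array(
    [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
)


def _kg4(r: float) -> np.ndarray:
    return np.array(
        [[1, 1, r, r], [1, 1, r, r], [r, r, 1, 1], [r, r, 1, 1]], dtype=float
    )


@dataclass
class MixedFit:
    """Result of fitting the longitudinal kinship mixed model for one trait."""

    trait: str
    beta: dict
    se: dict
    sigma2_g: float
    sigma2_p: float
    sigma2_e: float
    loglik: float
    p_time: float
    n_obs: int
    n_pairs: int
    converged: bool
    free: tuple = ("genetic", "individual", "residual")
    _beta_cov: np.ndarray = field(default=None, repr=False)


def _build_blocks(table: pd.DataFrame, trait: str):
    """Group observations into pair blocks keyed by (zygosity, slot pattern).

    Returns dict {(zygosity, pattern): (y (n,k), X (n,k,4))} and the total
    observation/pair counts.  A slot is one of the 4 canonical member×time
    positions; rows with a missing trait value are dropped.
    """
    d = table.loc[table[trait].notna(), ["pair_id", "twin_id", "zygosity", "sex",
                                         "age_baseline", "time", trait]]
    d = d.sort_values(["pair_id", "twin_id", "time"], kind="stable")
    if d.empty:
        return {}, 0, 0

    pair_code, pair_ids = pd.factorize(d["pair_id"], sort=True)
    first_twin = d.groupby("pair_id")["twin_id"].transform("min")
    member = (d["twin_id"].to_numpy() != first_twin.to_numpy()).astype(int)
    t = d["time"].to_numpy().astype(int) - 1
    slot = 2 * member + t

    n_total = len(pair_ids)
    y = np.full((n_total, 4), np.nan)
    x = np.zeros((n_total, 4, 4))
    y[pair_code, slot] = d[trait].to_numpy(dtype=float)
    x[pair_code, slot, 0] = 1.0
    x[pair_code, slot, 1] = d["age_baseline"].to_numpy(dtype=float)
    x[pair_code, slot, 2] = d["sex"].to_numpy(dtype=float)
    x[pair_code, slot, 3] = t.astype(float)
    zyg_per_pair = (
        d.drop_duplicates("pair_id").set_index("pair_id")["zygosity"].loc[pair_ids].to_numpy()
    )

    present_mat = ~np.isnan(y)
    groups: dict = {}
    n_obs = int(present_mat.sum())
    keys = [
        (z, tuple(bool(b) for b in row)) for z, row in zip(zyg_per_pair, present_mat)
    ]
    order: dict = {}
    for i, key in enumerate(keys):
        order.setdefault(key, []).append(i)
    for key, rows in order.items():
        idx = [i for i, p in enumerate(key[1]) if p]
        groups[key] = (y[np.ix_(rows, idx)], x[np.ix_(rows, idx)])
    return groups, n_obs, n_total


def _group_moments(blocks: dict) -> dict:
    """Per-group sufficient statistics (Σxᵀx, Σxᵀy, Σyyᵀ cross-slot moments).

    The covariance matrix is shared by all pairs of a (zygosity, pattern)
    group, so each likelihood evaluation needs only these moments — its cost
    is independent of the number of pairs.
    """
    moments = {}
    for key, (y, x) in blocks.items():
        moments[key] = {
            "n": y.shape[0],
            "cxx": np.einsum("nkp,nlq->klpq", x, x),
            "cxy": np.einsum("nkp,nl->klp", x, y),
            "cyy": np.einsum("nk,nl->kl", y, y),
        }
    return moments


def _profile_nll(variances: np.ndarray, moments: dict, n_obs: int):
    """Negative log-likelihood with GLS-profiled betas.

    Returns (nll, beta, beta_cov).  ``variances`` = (σg², σp², σe²).
    """
    sg, sp, se = variances
    xtwx = np.zeros((4, 4))
    xtwy = np.zeros(4)
    per_group = []
    logdet_total = 0.0
    for (zyg, present), mom in moments.items():
        idx = [i for i, p in enumerate(present) if p]
        r = 1.0 if zyg == "MZ" else 0.5
        v = (sg * _kg4(r) + sp * _KP4 + se * np.eye(4))[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(v)
        if sign <= 0:
            return np.inf, None, None
        vinv = np.linalg.inv(v)
        xtwx += np.einsum("kl,klpq->pq", vinv, mom["cxx"])
        xtwy += np.einsum("kl,klp->p", vinv, mom["cxy"])
        logdet_total += mom["n"] * logdet
        per_group.append((mom, vinv))
    try:
        beta_cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise ValueError("singular fixed-effect design (collinear columns)") from None
    beta = beta_cov @ xtwy
    quad = 0.0
    for mom, vinv in per_group:
        bxy = np.einsum("klp,p->kl", mom["cxy"], beta)
        bxxb = np.einsum("klpq,p,q->kl", mom["cxx"], beta, beta)
        resid_cross = mom["cyy"] - bxy - bxy.T + bxxb
        quad += float(np.sum(vinv * resid_cross))
    nll = 0.5 * (n_obs * np.log(2.0 * np.pi) + logdet_total + quad)
    return nll, beta, beta_cov


def fit_longitudinal_mixed(
    table: pd.DataFrame,
    trait: str,
    free: tuple = ("genetic", "individual", "residual"),
) -> MixedFit:
    """ML fit of the kinship mixed model for one (cleaned) trait.

    ``free`` selects which variance components are estimated; the others are
    fixed at 0 (the residual must always be free).  Raises on a singular
    design or if no optimizer start converges.
    """
    if "residual" not in free:
        raise ValueError("the residual variance must be free")
    blocks, n_obs, n_pairs = _build_blocks(table, trait)
    if n_pairs < 2:
        raise ValueError(f"fit_longitudinal_mixed({trait!r}): need >= 2 pairs with data")

    y_all = np.concatenate([y.ravel() for y, _ in blocks.values()])
    x_cols = np.concatenate([x.reshape(-1, 4) for _, x in blocks.values()])
    if np.linalg.matrix_rank(x_cols) < 4:
        raise ValueError(
            f"fit_longitudinal_mixed({trait!r}): singular design "
            "(a fixed-effect column is constant or collinear)"
        )
    var_y = max(float(np.var(y_all)), 1e-12)
    moments = _group_moments(blocks)

    comp_index = {"genetic": 0, "individual": 1, "residual": 2}
    free_idx = [comp_index[c] for c in ("genetic", "individual", "residual") if c in free]

    def unpack(theta):
        v = np.zeros(3)
        v[free_idx] = var_y * np.exp(theta)
        return v

    def objective(theta):
        try:
            nll, _, _ = _profile_nll(unpack(theta), moments, n_obs)
        except ValueError:
            # near-degenerate variance combinations can make the weighted
            # normal equations numerically singular; reject the point
            return _PENALTY
        # finite penalty keeps L-BFGS-B's finite differences well defined
        return min(nll, _PENALTY)

    k = len(free_idx)
    starts = [np.full(k, np.log(1.0 / 3.0)), np.full(k, -2.0), np.full(k, 0.0)]
    best = None
    fallback = None
    trace = []
    for theta0 in starts:
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=[(-25.0, 6.0)] * k,
            options={"maxiter": 500},
        )
        trace.append(f"start {theta0.tolist()} -> nll {res.fun:.6f}, success={res.success}")
        if res.success and (best is None or res.fun < best.fun):
            best = res
        if np.isfinite(res.fun) and (fallback is None or res.fun < fallback.fun):
            fallback = res
    if best is None and fallback is not None:
        # gradient-based line search can abort when the likelihood is
        # unbounded toward the variance floor (e.g. noise-free data); the
        # simplex method handles the boundary plateau
        res = optimize.minimize(
            objective,
            np.clip(fallback.x, -25.0, 6.0),
            method="Nelder-Mead",
            bounds=[(-25.0, 6.0)] * k,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        trace.append(f"simplex fallback -> nll {res.fun:.6f}, success={res.success}")
        if res.success and np.isfinite(res.fun):
            res.x = np.clip(res.x, -25.0, 6.0)
            best = res
    if best is None:
        raise RuntimeError(
            f"fit_longitudinal_mixed({trait!r}): no start converged:\n" + "\n".join(trace)
        )

    variances = unpack(best.x)
    nll, beta, beta_cov = _profile_nll(variances, moments, n_obs)
    se = np.sqrt(np.diag(beta_cov))
    z = beta[3] / se[3] if se[3] > 0 else np.inf
    p_time = float(2.0 * stats.norm.sf(abs(z)))
    return MixedFit(
        trait=trait,
        beta=dict(zip(_FIXED_EFFECTS, beta.tolist())),
        se=dict(zip(_FIXED_EFFECTS, se.tolist())),
        sigma2_g=float(variances[0]),
        sigma2_p=float(variances[1]),
        sigma2_e=float(variances[2]),
        loglik=float(-nll),
        p_time=p_time,
        n_obs=n_obs,
        n_pairs=n_pairs,
        converged=bool(best.success),
        free=tuple(free),
        _beta_cov=beta_cov,
    )


def plot_residual_scatter(table: pd.DataFrame, trait: str, fit: MixedFit, path) -> None:
    """Save a time-1 vs time-2 scatter of fixed-effect residuals (one point per
    individual, colored by sex), the standard visual check of longitudinal drift."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = fixed_effect_residuals(table, trait, fit)
    wide = res.pivot_table(index="twin_id", columns="time", values="residual")
    sex = res.drop_duplicates("twin_id").set_index("twin_id")["sex"].reindex(wide.index)
    fig, ax = plt.subplots(figsize=(4, 4))
    for code, color in ((0, "black"), (1, "red")):
        sub = wide[sex == code]
        ax.scatter(sub.get(1), sub.get(2), s=6, c=color, alpha=0.6)
    lim = np.nanmax(np.abs(wide.to_numpy())) * 1.05
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="grey")
    ax.set_xlabel(f"{trait} residual, time 1")
    ax.set_ylabel(f"{trait} residual, time 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fixed_effect_residuals(table: pd.DataFrame, trait: str, fit: MixedFit) -> pd.DataFrame:
    """Observed minus fixed-effect prediction, for time-1 vs time-2 scatter diagnostics."""
    d = table.loc[table[trait].notna()].copy()
    b = fit.beta
    pred = (
        b["intercept"]
        + b["age"] * d["age_baseline"]
        + b["sex"] * d["sex"]
        + b["time"] * (d["time"].astype(int) - 1)
    )
    d["residual"] = d[trait] - pred
    return d[["pair_id", "twin_id", "zygosity", "sex", "time", "residual"]]
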