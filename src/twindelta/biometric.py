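"""ACE/ADE variance decomposition of the change score with model selection.

The classical twin decomposition splits the phenotypic variance of Δ into
additive genetic (A), shared environmental (C), dominance genetic (D) and
unique environmental (E) parts.  With twins reared together C and D are not
jointly identifiable, so the two full models are ACE and ADE; nested
sub-models drop components (AE, CE, E; the DE model is biologically
implausible and never fitted).  Expected within-pair covariance of Δ:

    MZ: (a² + c² + d²) · Vtot        DZ: (½a² + c² + ¼d²) · Vtot

Fitting maximizes the bivariate-normal likelihood over MZ and DZ pairs
jointly, parameterized by path coefficients (component SDs, squared and
standardized for reporting), which enforces nonnegative components and makes
exact zeros attainable.  The mean model optionally adjusts for sex, baseline
age and baseline trait value; mean coefficients are profiled out by GLS at
each evaluation.  Model comparison uses the likelihood-ratio test against a
plain chi-square reference (no boundary mixture, a known conservative
choice) and the AIC = 2k − 2lnL; best-model selection prefers the most
parsimonious nested model whose LRT against the full model is
non-significant, with AIC breaking ties among equal-size candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import complete_pairs

__all__ = [
    "MODEL_COMPONENTS",
    "NESTED_MODELS",
    "VarianceComponents",
    "TwinModelFit",
    "SelectionResult",
    "expected_cov",
    "negloglik",
    "falconer_start",
    "fit_twin_model",
    "choose_full_model_icc",
    "choose_full_model_aic",
    "lrt",
    "aic",
    "select_best_model",
    "bootstrap_components_ci",
]

#: free path coefficients per model
MODEL_COMPONENTS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}

#: nested-model cascade fitted under each full model (DE is never fitted)
NESTED_MODELS = {"ACE": ("AE", "CE", "E"), "ADE": ("AE", "E")}

# within-pair covariance weight of each component, per zygosity
_COV_WEIGHT = {
    "MZ": {"a": 1.0, "c": 1.0, "d": 1.0, "e": 0.0},
    "DZ": {"a": 0.5, "c": 1.0, "d": 0.25, "e": 0.0},
}

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    """Standardized variance proportions; excluded paths are exactly 0."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0

    def as_dict(self) -> dict:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}

    def total(self) -> float:
        return self.a2 + self.c2 + self.d2 + self.e2


@dataclass
class TwinModelFit:
    model: str
    components: VarianceComponents
    total_var: float
    mean_coefs: dict
    loglik: float
    k: int
    aic: float
    n_pairs: dict = field(default_factory=dict)
    ci: dict | None = None
    converged: bool = True


@dataclass
class SelectionResult:
    full_model: str
    fits: dict
    lrt: dict
    best_model: str

    @property
    def best_fit(self) -> TwinModelFit:
        return self.fits[self.best_model]


def expected_cov(
    model: str, comps: VarianceComponents, total_var: float, zygosity: str
) -> np.ndarray:
    """2×2 expected covariance of a co-twin pair's deltas under ``model``."""
    allowed = MODEL_COMPONENTS[model]
    for name, value in comps.as_dict().items():
        if name[0] not in allowed and value != 0.0:
            raise ValueError(f"component {name} must be 0 under the {model} model")
    w = _COV_WEIGHT[zygosity]
    r = w["a"] * comps.a2 + w["c"] * comps.c2 + w["d"] * comps.d2
    off = r * total_var
    return np.array([[total_var, off], [off, total_var]])


def _pair_data(deltas: pd.DataFrame, covariates: bool):
    """{zygosity: (y (n,2), X (n,2,p))} from a delta table (complete pairs only)."""
    out = {}
    for zyg in ("MZ", "DZ"):
        wide = complete_pairs(deltas, zyg)
        if len(wide) == 0:
            continue
        y = wide[["delta_1", "delta_2"]].to_numpy(dtype=float)
        n = len(wide)
        if covariates:
            x = np.empty((n, 2, 4))
            for m in (0, 1):
                x[:, m, 0] = 1.0
                x[:, m, 1] = wide[f"sex_{m + 1}"].to_numpy(dtype=float)
                x[:, m, 2] = wide[f"age_{m + 1}"].to_numpy(dtype=float)
                x[:, m, 3] = wide[f"baseline_{m + 1}"].to_numpy(dtype=float)
            ok = np.isfinite(x).all(axis=(1, 2))
            y, x = y[ok], x[ok]
        else:
            x = np.ones((n, 2, 1))
        if len(y) > 0:
            out[zyg] = (y, x)
    return out


def _nll_blocks(data: dict, beta: np.ndarray, cov_by_zyg: dict) -> float:
    """Sum of −log bivariate-normal densities; +inf if any cov is not PD."""
    total = 0.0
    for zyg, (y, x) in data.items():
        v = cov_by_zyg[zyg]
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0 or v[0, 0] <= 0:
            return np.inf
        vinv = np.array([[v[1, 1], -v[0, 1]], [-v[1, 0], v[0, 0]]]) / det
        n, _, p = x.shape
        resid = y - (x.reshape(-1, p) @ beta).reshape(n, 2)
        quad = np.einsum("nk,kl,nl->", resid, vinv, resid)
        total += n * (_LOG_2PI + 0.5 * np.log(det)) + 0.5 * quad
    return float(total)


class _PairMoments:
    """Sufficient statistics of one zygosity group for the pair likelihood.

    The covariance is shared across pairs within a zygosity, so the profiled
    likelihood only needs the member-wise cross-moments Σxᵀx, Σxᵀy, Σy·y —
    each objective evaluation is then O(p²), independent of pair count.
    """

    __slots__ = ("n", "cxx", "cxy", "cyy")

    def __init__(self, y: np.ndarray, x: np.ndarray):
        self.n = len(y)
        self.cxx = {
            (m, mm): x[:, m, :].T @ x[:, mm, :] for m in (0, 1) for mm in (0, 1)
        }
        self.cxy = {
            (m, mm): x[:, m, :].T @ y[:, mm] for m in (0, 1) for mm in (0, 1)
        }
        self.cyy = {
            (m, mm): float(y[:, m] @ y[:, mm]) for m in (0, 1) for mm in (0, 1)
        }

    def resid_cross(self, beta: np.ndarray, m: int, mm: int) -> float:
        """Σ (y_m − x_m β)(y_mm − x_mm β) over pairs."""
        return float(
            self.cyy[(m, mm)]
            - beta @ self.cxy[(m, mm)]
            - beta @ self.cxy[(mm, m)]
            + beta @ self.cxx[(m, mm)] @ beta
        )


def _moment_nll(moments: dict, beta: np.ndarray, cov_by_zyg: dict) -> float:
    total = 0.0
    for zyg, mom in moments.items():
        v = cov_by_zyg[zyg]
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0 or v[0, 0] <= 0:
            return np.inf
        vinv = np.array([[v[1, 1], -v[0, 1]], [-v[1, 0], v[0, 0]]]) / det
        quad = sum(
            vinv[m, mm] * mom.resid_cross(beta, m, mm)
            for m in (0, 1)
            for mm in (0, 1)
        )
        total += mom.n * (_LOG_2PI + 0.5 * np.log(det)) + 0.5 * quad
    return float(total)


def _moment_gls(moments: dict, cov_by_zyg: dict):
    p = next(iter(moments.values())).cxx[(0, 0)].shape[0]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    for zyg, mom in moments.items():
        v = cov_by_zyg[zyg]
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0:
            return None
        vinv = np.array([[v[1, 1], -v[0, 1]], [-v[1, 0], v[0, 0]]]) / det
        for m in (0, 1):
            for mm in (0, 1):
                xtwx += vinv[m, mm] * mom.cxx[(m, mm)]
                xtwy += vinv[m, mm] * mom.cxy[(m, mm)]
    try:
        return np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return None


def negloglik(
    model: str,
    comps: VarianceComponents,
    total_var: float,
    data: dict,
    beta: np.ndarray | None = None,
) -> float:
    """Negative log-likelihood of pair-ordered deltas under a twin model.

    ``data`` maps zygosity to ``(y, X)`` as built by :func:`_pair_data`;
    ``beta`` defaults to a zero mean.  Non-positive-definite covariance
    returns +inf rather than raising, so optimizers can reject it.
    """
    cov = {zyg: expected_cov(model, comps, total_var, zyg) for zyg in data}
    if beta is None:
        p = next(iter(data.values()))[1].shape[2]
        beta = np.zeros(p)
    return _nll_blocks(data, np.asarray(beta, dtype=float), cov)


def falconer_start(rmz: float, rdz: float) -> VarianceComponents:
    """Moment-based starting proportions a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ.

    Each is clipped to [0, 1]; if a² + c² exceeds 0.95 the pair is scaled
    down so a positive unique-environment share always remains.
    """
    a2 = min(max(2.0 * (rmz - rdz), 0.0), 1.0)
    c2 = min(max(2.0 * rdz - rmz, 0.0), 1.0)
    s = a2 + c2
    if s > 0.95:
        a2 *= 0.95 / s
        c2 *= 0.95 / s
    return VarianceComponents(a2=a2, c2=c2, d2=0.0, e2=1.0 - a2 - c2)


def _profiled_objective(moments: dict, model: str):
    """Concentrated NLL over path coefficients with GLS-profiled mean."""
    comp_names = MODEL_COMPONENTS[model]

    def objective(paths: np.ndarray) -> float:
        var_parts = dict.fromkeys("acde", 0.0)
        for name, p in zip(comp_names, paths):
            var_parts[name] = p * p
        total = sum(var_parts.values())
        if total <= 0:
            return np.inf
        cov = {}
        for zyg in moments:
            w = _COV_WEIGHT[zyg]
            off = sum(w[c] * var_parts[c] for c in "acd")
            cov[zyg] = np.array([[total, off], [off, total]])
        beta = _moment_gls(moments, cov)
        if beta is None:
            return np.inf
        return _moment_nll(moments, beta, cov)

    return objective


def _sample_correlations(data: dict):
    """Crude double-entry correlations and pooled SD used for starting values."""
    corr = {}
    sds = []
    for zyg, (y, _) in data.items():
        d = y - y.mean()
        s2 = float(np.mean(d**2))
        corr[zyg] = float(np.mean(d[:, 0] * d[:, 1]) / s2) if s2 > 0 else 0.0
        sds.append(np.sqrt(s2))
    return corr.get("MZ", 0.0), corr.get("DZ", 0.0), float(np.mean(sds))


def fit_twin_model(
    deltas: pd.DataFrame,
    model: str,
    covariates: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> TwinModelFit:
    """ML fit of one biometric model to the pair-ordered deltas.

    Multi-start optimization over path coefficients: a Falconer moment start
    plus ``n_starts − 1`` seeded random restarts, keeping the best.  The free
    parameter count k is the number of mean coefficients plus the number of
    free paths.  Warns below 10 complete pairs per zygosity.
    """
    data = _pair_data(deltas, covariates)
    if not data:
        raise ValueError("no complete pairs")
    for zyg, (y, _) in data.items():
        if len(y) < 10:
            warnings.warn(f"only {len(y)} complete {zyg} pairs; fit may be unstable",
                          stacklevel=2)
    return _fit_arrays(data, model, covariates, n_starts, seed)


def _fit_arrays(
    data: dict, model: str, covariates: bool, n_starts: int, seed: int
) -> TwinModelFit:
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}")
    comp_names = MODEL_COMPONENTS[model]
    moments = {zyg: _PairMoments(y, x) for zyg, (y, x) in data.items()}
    m = len(comp_names)
    rmz, rdz, sd = _sample_correlations(data)
    sd = max(sd, 1e-8)

    start_props = falconer_start(rmz, rdz).as_dict()
    if model == "ADE":
        # reuse the additive share, seed dominance from the MZ/DZ excess
        d2 = min(max(4.0 * rmz - 8.0 * rdz, 0.0) / 4.0, start_props["a2"])
        start_props = {"a2": max(start_props["a2"] - d2, 0.0), "c2": 0.0, "d2": d2,
                       "e2": start_props["e2"] + start_props["c2"]}
    props0 = np.array([max(start_props[f"{c}2"], 0.01) for c in comp_names])
    props0 /= props0.sum()
    starts = [sd * np.sqrt(props0)]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        props = rng.dirichlet(np.ones(m))
        starts.append(sd * np.sqrt(np.maximum(props, 1e-4)))

    objective = _profiled_objective(moments, model)
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"fit_twin_model({model}): no optimizer start converged")

    paths = np.abs(best.x)
    var_parts = dict.fromkeys("acde", 0.0)
    for name, p in zip(comp_names, paths):
        var_parts[name] = p * p
    total = sum(var_parts.values())
    comps = VarianceComponents(**{f"{c}2": float(var_parts[c] / total) for c in "acde"})
    cov = {zyg: expected_cov(model, comps, total, zyg) for zyg in data}
    beta = _moment_gls(moments, cov)
    p_mean = next(iter(data.values()))[1].shape[2]
    coef_names = (
        ["intercept", "sex", "age", "baseline"] if covariates else ["intercept"]
    )
    k = p_mean + m
    loglik = -float(best.fun)
    return TwinModelFit(
        model=model,
        components=comps,
        total_var=float(total),
        mean_coefs=dict(zip(coef_names, beta.tolist())),
        loglik=loglik,
        k=k,
        aic=aic(loglik, k),
        n_pairs={zyg: len(y) for zyg, (y, _) in data.items()},
        converged=bool(best.success),
    )


def choose_full_model_icc(rmz: float, rdz: float) -> str:
    """ADE iff the MZ correlation is more than double the DZ correlation."""
    return "ADE" if rmz > 2.0 * rdz else "ACE"


def choose_full_model_aic(fit_ace: TwinModelFit, fit_ade: TwinModelFit) -> str:
    """Full model with the lower AIC; ties go to ACE."""
    return "ADE" if fit_ade.aic < fit_ace.aic else "ACE"


def lrt(fit_full: TwinModelFit, fit_nested: TwinModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model.

    X² = 2·(lnL_full − lnL_nested) floored at 0, df = Δk, p from the plain
    chi-square upper tail.  Warns if the nested log-likelihood exceeds the
    full one beyond tolerance (an optimizer failure).
    """
    if fit_nested.loglik > fit_full.loglik + 1e-6:
        warnings.warn(
            f"nested {fit_nested.model} log-likelihood exceeds full {fit_full.model}; "
            "consider refitting",
            stacklevel=2,
        )
    x2 = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    df = fit_full.k - fit_nested.k
    if df <= 0:
        raise ValueError("nested model must have fewer free parameters")
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k − 2lnL."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def select_best_model(
    full_fit: TwinModelFit, nested_fits: dict, alpha: float = 0.05
) -> SelectionResult:
    """Parsimony-first selection among a full model and its nested sub-models.

    Candidates are nested models whose LRT against the full model has
    p > alpha; the one with the fewest free parameters wins (AIC breaks ties
    among equal-k candidates).  If no nested model survives, the full model
    is selected.  A nested model may therefore be selected even when its AIC
    exceeds the full model's.
    """
    expected = set(NESTED_MODELS[full_fit.model])
    if set(nested_fits) != expected:
        raise ValueError(
            f"full model {full_fit.model} requires nested set {sorted(expected)}"
        )
    tests = {name: lrt(full_fit, fit) for name, fit in nested_fits.items()}
    candidates = [name for name, (_, _, p) in tests.items() if p > alpha]
    if not candidates:
        best = full_fit.model
    else:
        best = min(candidates, key=lambda n: (nested_fits[n].k, nested_fits[n].aic))
    fits = {full_fit.model: full_fit, **nested_fits}
    return SelectionResult(
        full_model=full_fit.model, fits=fits, lrt=tests, best_model=best
    )


def bootstrap_components_ci(
    deltas: pd.DataFrame,
    model: str,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    covariates: bool = True,
    n_starts: int = 2,
) -> dict:
    """Percentile bootstrap CIs for the standardized components of one model.

    Pairs are resampled with replacement within each zygosity; the model is
    refitted per replicate.  Non-converging replicates are dropped and
    counted (warning above 5%).  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    data = _pair_data(deltas, covariates)
    if not data:
        raise ValueError("no complete pairs")
    rng = np.random.default_rng(seed)
    draws = {c: [] for c in ("a2", "c2", "d2", "e2")}
    dropped = 0
    for _ in range(reps):
        resampled = {}
        for zyg, (y, x) in data.items():
            idx = rng.integers(0, len(y), size=len(y))
            resampled[zyg] = (y[idx], x[idx])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _fit_arrays(resampled, model, covariates, n_starts,
                                  int(rng.integers(2**31)))
        except (RuntimeError, ValueError):
            dropped += 1
            continue
        for c, v in fit.components.as_dict().items():
            draws[c].append(v)
    n_ok = reps - dropped
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    if dropped > 0.05 * reps:
        warnings.warn(f"{dropped}/{reps} bootstrap replicates dropped", stacklevel=2)
    alpha = 1.0 - level
    ci = {}
    for c in MODEL_COMPONENTS[model]:
        vals = np.asarray(draws[f"{c}2"])
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        ci[f"{c}2"] = (float(lo), float(hi))
    return ci
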