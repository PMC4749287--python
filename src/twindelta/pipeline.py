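"""End-to-end study pipeline: simulate/load → clean → mixed model → ICC → twin models.

Per trait, the stages run in a fixed order and failures are isolated: an
error in one trait is recorded in the report's error table and the remaining
traits still run.  All randomness flows from a single root seed through
per-trait, per-stage derived seeds, so a report is byte-reproducible from its
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .biometric import (
    NESTED_MODELS,
    bootstrap_components_ci,
    choose_full_model_aic,
    choose_full_model_icc,
    fit_twin_model,
    select_best_model,
)
from .icc import bootstrap_icc_ci, compare_icc, estimate_icc
from .mixed import fit_longitudinal_mixed
from .preprocess import complete_pairs, preprocess_trait
from .simulate import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "write_report", "load_report"]

logger = logging.getLogger("twindelta")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (cohort CSV) or ``sim`` (generator config)
    must be provided.  ``log_traits`` lists traits to natural-log transform
    ("all" applies it to every trait).
    """

    traits: list
    input_path: str | None = None
    sim: SimConfig | None = None
    log_traits: list | str = "all"
    sd_cut: float = 3.0
    alpha: float = 0.05
    bootstrap_reps: int = 200
    seed: int = 0
    icc_covariates: bool = False
    twin_covariates: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("provide exactly one of input_path or sim")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")
        if self.sd_cut <= 0:
            raise ValueError("sd_cut must be positive")

    def wants_log(self, trait: str) -> bool:
        if isinstance(self.log_traits, str):
            return self.log_traits == "all"
        return trait in self.log_traits


@dataclass
class StudyReport:
    traits: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _derived_seed(root: int, trait: str, stage: str) -> int:
    """Stable per-(trait, stage) seed below 2**31."""
    digest = hashlib.sha256(f"{root}:{trait}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "traits": list(config.traits),
        "input_path": config.input_path,
        "sim": None if config.sim is None else repr(config.sim),
        "log_traits": config.log_traits,
        "sd_cut": config.sd_cut,
        "alpha": config.alpha,
        "bootstrap_reps": config.bootstrap_reps,
        "seed": config.seed,
        "icc_covariates": config.icc_covariates,
        "twin_covariates": config.twin_covariates,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _descriptives(cleaned: pd.DataFrame, trait: str) -> dict:
    out = {}
    for time in (1, 2):
        vals = cleaned.loc[cleaned["time"] == time, trait].dropna()
        if len(vals) == 0:
            out[f"time{time}"] = {"mean": None, "p2_5": None, "p97_5": None, "n": 0}
            continue
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[f"time{time}"] = {
            "mean": float(vals.mean()),
            "p2_5": float(lo),
            "p97_5": float(hi),
            "n": int(len(vals)),
        }
    return out


def _run_trait(table: pd.DataFrame, trait: str, config: PipelineConfig) -> dict:
    cleaned, deltas, masked = preprocess_trait(
        table, trait, log=config.wants_log(trait), k_sd=config.sd_cut
    )
    result: dict = {
        "trait": trait,
        "n_masked": len(masked),
        "descriptives": _descriptives(cleaned, trait),
    }

    mixed = fit_longitudinal_mixed(cleaned, trait)
    result["mixed"] = {
        "beta": mixed.beta,
        "se": mixed.se,
        "sigma2_g": mixed.sigma2_g,
        "sigma2_p": mixed.sigma2_p,
        "sigma2_e": mixed.sigma2_e,
        "loglik": mixed.loglik,
        "p_time": mixed.p_time,
        "n_obs": mixed.n_obs,
        "n_pairs": mixed.n_pairs,
    }

    n_pairs = {zyg: len(complete_pairs(deltas, zyg)) for zyg in ("MZ", "DZ")}
    if min(n_pairs.values()) < 3:
        reason = f"insufficient complete pairs (MZ={n_pairs['MZ']}, DZ={n_pairs['DZ']})"
        logger.info("trait %s: skipping ICC/twin stages: %s", trait, reason)
        result["skipped"] = reason
        return result

    icc_block = {}
    for zyg in ("MZ", "DZ"):
        est = estimate_icc(deltas, zyg, covariates=config.icc_covariates)
        lo, hi = bootstrap_icc_ci(
            deltas,
            zyg,
            reps=config.bootstrap_reps,
            seed=_derived_seed(config.seed, trait, f"icc_ci_{zyg}"),
            covariates=config.icc_covariates,
        )
        icc_block[zyg] = {
            "icc": est.icc,
            "sigma2_s": est.sigma2_s,
            "sigma2_e": est.sigma2_e,
            "n_pairs": est.n_pairs,
            "ci_low": lo,
            "ci_high": hi,
        }
    rmz, rdz = icc_block["MZ"]["icc"], icc_block["DZ"]["icc"]
    icc_block["mz_gt_2dz"] = bool(rmz > 2.0 * rdz)
    icc_block["p_mz_eq_dz"] = compare_icc(
        deltas,
        reps=config.bootstrap_reps,
        seed=_derived_seed(config.seed, trait, "icc_compare"),
        covariates=config.icc_covariates,
    )
    result["icc"] = icc_block

    fits = {}
    for model in ("ACE", "ADE"):
        fits[model] = fit_twin_model(
            deltas,
            model,
            covariates=config.twin_covariates,
            seed=_derived_seed(config.seed, trait, f"fit_{model}"),
        )
    full_by_icc = choose_full_model_icc(rmz, rdz)
    full_model = choose_full_model_aic(fits["ACE"], fits["ADE"])
    nested = {
        name: fit_twin_model(
            deltas,
            name,
            covariates=config.twin_covariates,
            seed=_derived_seed(config.seed, trait, f"fit_{name}"),
        )
        for name in NESTED_MODELS[full_model]
    }
    selection = select_best_model(fits[full_model], nested, alpha=config.alpha)
    ci = bootstrap_components_ci(
        deltas,
        selection.best_model,
        reps=config.bootstrap_reps,
        seed=_derived_seed(config.seed, trait, "boot_components"),
        covariates=config.twin_covariates,
    )
    ci = {comp: [lo, hi] for comp, (lo, hi) in ci.items()}  # JSON-stable form

    all_fits = {**fits, **nested}
    result["twin"] = {
        "full_model_icc_rule": full_by_icc,
        "full_model": full_model,
        "best_model": selection.best_model,
        "fits": {
            name: {
                "components": f.components.as_dict(),
                "total_var": f.total_var,
                "mean_coefs": f.mean_coefs,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
            }
            for name, f in all_fits.items()
        },
        "lrt": {
            name: {"x2": x2, "df": df, "p": p}
            for name, (x2, df, p) in selection.lrt.items()
        },
        "best_ci": ci,
    }
    return result


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run every stage for every configured trait; deterministic given the seed."""
    config.validate()
    if config.sim is not None:
        table = generate_cohort(config.sim)
    else:
        table = pd.read_csv(config.input_path)

    available = [c for c in table.columns if c not in
                 ("pair_id", "twin_id", "zygosity", "sex", "age_baseline", "time")]
    report = StudyReport()
    report.provenance = {
        "version": _version,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_rows": int(len(table)),
    }
    for trait in config.traits:
        if trait not in table.columns:
            raise KeyError(
                f"unknown trait {trait!r}; available columns: {available}"
            )
    for trait in config.traits:
        try:
            report.traits[trait] = _run_trait(table, trait, config)
        except Exception as exc:  # per-trait isolation
            logger.exception("trait %s failed", trait)
            report.errors.append({"trait": trait, "error": f"{type(exc).__name__}: {exc}"})
    return report


def _fmt(value, digits=6):
    if value is None:
        return ""
    return f"{value:.{digits}f}"


def _table_change(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, r in report.traits.items():
        d = r["descriptives"]
        rows.append(
            {
                "trait": trait,
                "mean_t1": _fmt(d["time1"]["mean"]),
                "range_t1": f"{_fmt(d['time1']['p2_5'], 4)}-{_fmt(d['time1']['p97_5'], 4)}",
                "mean_t2": _fmt(d["time2"]["mean"]),
                "range_t2": f"{_fmt(d['time2']['p2_5'], 4)}-{_fmt(d['time2']['p97_5'], 4)}",
                "p_change": f"{r['mixed']['p_time']:.3e}",
            }
        )
    cols = ["trait", "mean_t1", "range_t1", "mean_t2", "range_t2", "p_change"]
    return pd.DataFrame(rows, columns=cols)


def _table_icc(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, r in report.traits.items():
        if "icc" not in r:
            continue
        i = r["icc"]
        rows.append(
            {
                "trait": trait,
                "icc_mz": f"{i['MZ']['icc']:.2f}",
                "ci_mz": f"{i['MZ']['ci_low']:.2f}-{i['MZ']['ci_high']:.2f}",
                "icc_dz": f"{i['DZ']['icc']:.2f}",
                "ci_dz": f"{i['DZ']['ci_low']:.2f}-{i['DZ']['ci_high']:.2f}",
                "mz_gt_2dz": int(i["mz_gt_2dz"]),
                "p_mz_eq_dz": f"{i['p_mz_eq_dz']:.3f}",
            }
        )
    cols = ["trait", "icc_mz", "ci_mz", "icc_dz", "ci_dz", "mz_gt_2dz", "p_mz_eq_dz"]
    return pd.DataFrame(rows, columns=cols)


def _nonshared(model: str, comps: dict) -> float:
    return comps["c2"] if model in ("ACE", "CE") else comps["d2"]


def _table_full(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, r in report.traits.items():
        if "twin" not in r:
            continue
        t = r["twin"]
        full = t["full_model"]
        f = t["fits"][full]
        best = t["best_model"]
        b = t["fits"][best]
        test = t["lrt"].get(best)
        rows.append(
            {
                "trait": trait,
                "full_model": full,
                "full_model_icc_rule": t["full_model_icc_rule"],
                "A": f"{f['components']['a2']:.2f}",
                "C_or_D": f"{_nonshared(full, f['components']):.2f}",
                "E": f"{f['components']['e2']:.2f}",
                "aic_full": f"{f['aic']:.2f}",
                "best_model": best,
                "aic_best": f"{b['aic']:.2f}",
                "x2": "" if test is None else f"{test['x2']:.2f}",
                "p": "" if test is None else f"{test['p']:.2f}",
            }
        )
    cols = ["trait", "full_model", "full_model_icc_rule", "A", "C_or_D", "E",
            "aic_full", "best_model", "aic_best", "x2", "p"]
    return pd.DataFrame(rows, columns=cols)


def _table_best(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, r in report.traits.items():
        if "twin" not in r:
            continue
        t = r["twin"]
        best = t["best_model"]
        comps = t["fits"][best]["components"]
        ci = t["best_ci"]

        def fmt_ci(comp):
            if comp not in ci:
                return ""
            lo, hi = ci[comp]
            return f"{lo:.2f}-{hi:.2f}"

        rows.append(
            {
                "trait": trait,
                "best_model": best,
                "A": f"{comps['a2']:.2f}" if "a2" in ci else "",
                "A_ci": fmt_ci("a2"),
                "C_or_D": (
                    f"{_nonshared(best, comps):.2f}" if ("c2" in ci or "d2" in ci) else ""
                ),
                "C_or_D_ci": fmt_ci("c2") or fmt_ci("d2"),
                "E": f"{comps['e2']:.2f}",
                "E_ci": fmt_ci("e2"),
            }
        )
    cols = ["trait", "best_model", "A", "A_ci", "C_or_D", "C_or_D_ci", "E", "E_ci"]
    return pd.DataFrame(rows, columns=cols)


def _table_aic(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, r in report.traits.items():
        if "twin" not in r:
            continue
        t = r["twin"]
        row = {"trait": trait}
        for model in ("ACE", "ADE", "AE", "CE", "E"):
            fit = t["fits"].get(model)
            row[model] = "" if fit is None else f"{fit['aic']:.2f}"
        row["best_model"] = t["best_model"]
        rows.append(row)
    cols = ["trait", "ACE", "ADE", "AE", "CE", "E", "best_model"]
    return pd.DataFrame(rows, columns=cols)


def write_report(report: StudyReport, outdir) -> dict:
    """Serialize the report: one CSV per table family, a JSON bundle, a log.

    Numbers are rounded only at CSV serialization (2 decimals for variance
    proportions); the JSON bundle keeps full precision and round-trips the
    in-memory values exactly.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "change_tests.csv": _table_change(report),
        "icc.csv": _table_icc(report),
        "full_models.csv": _table_full(report),
        "best_models.csv": _table_best(report),
        "model_aic.csv": _table_aic(report),
        "errors.csv": pd.DataFrame(report.errors, columns=["trait", "error"]),
    }
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = str(path)

    bundle = {"provenance": report.provenance, "traits": report.traits,
              "errors": report.errors}
    json_path = out / "report.json"
    json_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    paths["report.json"] = str(json_path)

    log_path = out / "run.log"
    lines = [
        f"twindelta {report.provenance.get('version')}",
        f"seed {report.provenance.get('seed')}",
        f"config_hash {report.provenance.get('config_hash')}",
        f"traits analyzed: {', '.join(report.traits) or '(none)'}",
        f"errors: {len(report.errors)}",
    ]
    for trait, r in report.traits.items():
        if "skipped" in r:
            lines.append(f"  {trait}: skipped ICC/twin stages ({r['skipped']})")
    log_path.write_text("\n".join(lines) + "\n")
    paths["run.log"] = str(log_path)
    return paths


def load_report(json_path) -> StudyReport:
    """Reload a JSON bundle written by :func:`write_report`."""
    with open(json_path) as fh:
        bundle = json.load(fh)
    return StudyReport(
        traits=bundle["traits"], errors=bundle["errors"], provenance=bundle["provenance"]
    )
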