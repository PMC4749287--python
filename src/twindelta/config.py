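"""YAML configuration loading for the simulator and the pipeline."""

from __future__ import annotations

import yaml

from .pipeline import PipelineConfig
from .simulate import SimConfig, TraitSpec

__all__ = ["sim_config_from_dict", "load_sim_config", "load_pipeline_config"]


def sim_config_from_dict(data: dict) -> SimConfig:
    traits = [TraitSpec(**t) for t in data.get("traits", [])]
    for t in traits:
        t.var_level = tuple(t.var_level)
        t.var_change = tuple(t.var_change)
    kwargs = {k: v for k, v in data.items() if k != "traits"}
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    config = SimConfig(traits=traits, **kwargs)
    config.validate()
    return config


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "simulate" in data:
        data = data["simulate"]
    return sim_config_from_dict(data)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a pipeline config; either ``input`` (CSV path) or ``simulate`` block."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    sim = sim_config_from_dict(data["simulate"]) if "simulate" in data else None
    config = PipelineConfig(
        traits=data["traits"],
        input_path=data.get("input"),
        sim=sim,
        log_traits=data.get("log_traits", "all"),
        sd_cut=float(data.get("sd_cut", 3.0)),
        alpha=float(data.get("alpha", 0.05)),
        bootstrap_reps=int(data.get("bootstrap_reps", 200)),
        seed=int(data.get("seed", 0)),
        icc_covariates=bool(data.get("icc_covariates", False)),
        twin_covariates=bool(data.get("twin_covariates", True)),
    )
    config.validate()
    return config
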