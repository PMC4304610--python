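"""Packaged default configuration: risk functions, exposure factors,
threshold registry and validation fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec
from .exposure import ExposureModel
from .moe import ToxThreshold
from .synthetic import AgentGenerator, reconstruct_sparse_vector

__all__ = [
    "spec_from_config",
    "load_risk_functions",
    "load_exposure_factors",
    "load_thresholds",
    "load_agent_generators",
    "default_exposure_models",
    "load_recovery_table",
    "load_method_comparison_pairs",
]


def _data_path(name: str):
    return resources.files("eliqrisk.data").joinpath(name)


def _load_yaml(path_or_name) -> dict:
    if isinstance(path_or_name, (str, Path)) and Path(path_or_name).exists():
        text = Path(path_or_name).read_text()
    else:
        text = _data_path(str(path_or_name)).read_text()
    return yaml.safe_load(text)


def spec_from_config(d: dict, unit: str = "") -> DistributionSpec:
    """Build a DistributionSpec from its config-dialect dict.

    In addition to explicit ``params``, empirical specs may give
    ``resample_data: {zeros: k, values: [...]}`` or a ``reconstruct:``
    block solved by :func:`~eliqrisk.synthetic.reconstruct_sparse_vector`.
    """
    d = dict(d)
    d.setdefault("unit", unit)
    if "resample_data" in d:
        rd = d.pop("resample_data")
        d["params"] = [0.0] * int(rd.get("zeros", 0)) + list(rd["values"])
    elif "reconstruct" in d:
        r = d.pop("reconstruct")
        d["params"] = reconstruct_sparse_vector(
            int(r["n"]), int(r["n_positive"]), r["mean"], r["sd"], r["lo"], r["hi"]
        ).tolist()
    return DistributionSpec.from_dict(d)


def load_risk_functions(path=None) -> Dict[str, dict]:
    """Per-agent concentration risk functions with units and incidences."""
    raw = _load_yaml(path or "risk_functions.yaml")
    out = {}
    for agent, entry in raw["agents"].items():
        out[agent] = {
            "unit": entry["unit"],
            "incidence": float(entry["incidence"]),
            "summary": entry.get("summary", {}),
            "spec": spec_from_config(entry["risk_function"], unit=entry["unit"]),
        }
    return out


def load_exposure_factors(path=None) -> Dict[str, DistributionSpec]:
    raw = _load_yaml(path or "exposure_factors.yaml")
    return {name: spec_from_config(cfg) for name, cfg in raw.items()}


def load_thresholds(path=None) -> Dict[str, ToxThreshold]:
    raw = _load_yaml(path or "thresholds.yaml")
    return {
        agent: ToxThreshold(
            agent=agent,
            value=float(cfg["value"]),
            endpoint_type=cfg["endpoint_type"],
            endpoint_source=cfg["endpoint_source"],
            secondary_value=(
                float(cfg["secondary_value"]) if "secondary_value" in cfg else None
            ),
            secondary_type=cfg.get("secondary_type", ""),
            reference=cfg.get("reference", ""),
        )
        for agent, cfg in raw.items()
    }


def load_agent_generators(path=None) -> Dict[str, AgentGenerator]:
    """Synthetic-table generators: one (incidence, spec) pair per agent.

    For parametric agents the generator draws positive concentrations from
    the agent's fitted risk function; for empirical agents it resamples the
    positive measurements only (incidence handles the zeros).
    """
    out = {}
    for agent, entry in load_risk_functions(path).items():
        spec = entry["spec"]
        if spec.family == "empirical_resample":
            positives = tuple(p for p in spec.params if p > 0)
            spec = DistributionSpec("empirical_resample", positives, unit=spec.unit)
        out[agent] = AgentGenerator(
            incidence=entry["incidence"], spec=spec, unit=entry["unit"]
        )
    return out


def default_exposure_models(
    risk_path=None, factors_path=None
) -> Dict[str, ExposureModel]:
    """One ExposureModel per agent from the packaged defaults."""
    factors = load_exposure_factors(factors_path)
    models = {}
    for agent, entry in load_risk_functions(risk_path).items():
        models[agent] = ExposureModel(
            agent=agent,
            concentration=entry["spec"],
            concentration_unit=entry["unit"],
            liquid_amount_per_day=factors["liquid_amount_per_day"],
            vaporization_percentage=factors["vaporization_percentage"],
            bodyweight=factors["bodyweight"],
        )
    return models


def load_recovery_table(path=None) -> pd.DataFrame:
    src = path or _data_path("nicotine_recovery.csv")
    with resources.as_file(src) if path is None else _noop(src) as p:
        return pd.read_csv(p)


class _noop:
    def __init__(self, v):
        self.v = v

    def __enter__(self):
        return self.v

    def __exit__(self, *a):
        return False


def load_method_comparison_pairs(path=None) -> List[Tuple[Optional[float], Optional[float]]]:
    """Paired NMR/HPLC nicotine results; 'n.d.' parsed as None."""
    src = path or _data_path("nmr_hplc_nicotine.csv")
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, dtype=str)

    def parse(v):
        v = str(v).strip()
        return None if v.lower() in ("n.d.", "nd", "nan", "") else float(v)

    return [
        (parse(a), parse(b))
        for a, b in zip(df["nmr_mg_per_ml"], df["hplc_mg_per_ml"])
    ]
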