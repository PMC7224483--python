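"""YAML run configuration: loading, validation, hashing.

One config file with sections ``population``, ``facilities``, ``weights``,
``engine`` and ``experiment`` drives the whole pipeline; the packaged
default reproduces the headline analysis. Unknown keys are rejected by
name so typos fail loudly, and the config hash (SHA-256 of the
canonical-JSON form) is stable under key reordering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .choice import WeightModel
from .engine import SimulationConfig
from .facilities import build_facility_model, load_default_coords, load_hospitals
from .population import DensityModel, IncomeModel, PopulationSpec

__all__ = [
    "ConfigError",
    "default_config_dict",
    "load_config_dict",
    "build_simulation_config",
    "load_config",
    "experiment_settings",
    "config_hash",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_SECTIONS = ("population", "facilities", "weights", "engine", "experiment")
_KEYS = {
    "population": {
        "n_agents", "gender_split", "education_probs", "wealth_probs",
        "age_probs", "income", "density", "seed",
    },
    "income": {"median", "q25", "q75"},
    "density": {"side", "cluster_center", "cluster_sigma", "cluster_weight"},
    "facilities": {"table", "coords"},
    "weights": {"gamma", "delta", "lam", "alpha_home"},
    "engine": {"dose", "batch_size", "n_runs", "master_seed", "money_form"},
    "experiment": {
        "anchors", "dose_grid", "sweep_n_runs", "sweep_batch_size",
        "sweep_statistic", "plateau_epsilon", "subgroup_dose",
        "calibration_tolerance",
    },
}


def _check_keys(name: str, mapping: dict) -> dict:
    unknown = set(mapping) - _KEYS[name]
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}"
        )
    return mapping


def default_config_dict() -> dict:
    """The packaged default configuration as a plain dict."""
    path = resources.files("surgesim.data").joinpath("default_config.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_config_dict(path=None) -> dict:
    """Load a YAML config (packaged default if ``path`` is None)."""
    if path is None:
        cfg = default_config_dict()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    # missing sections fall back to the packaged defaults
    base = default_config_dict()
    for s in _SECTIONS:
        merged = dict(base.get(s, {}))
        merged.update(cfg.get(s) or {})
        cfg[s] = merged
    return cfg


def _population_spec(section: dict) -> PopulationSpec:
    section = _check_keys("population", section)
    inc = _check_keys("income", section.get("income", {}))
    den = _check_keys("density", section.get("density", {}))
    income = IncomeModel.fit(
        median=inc.get("median", 554_986.0),
        q25=inc.get("q25", 341_936.0),
        q75=inc.get("q75", 842_990.0),
    )
    density = DensityModel(
        side=den.get("side", 60.0),
        cluster_center=tuple(den.get("cluster_center", (10.0, 12.0))),
        cluster_sigma=den.get("cluster_sigma", 6.0),
        cluster_weight=den.get("cluster_weight", 0.65),
    )
    return PopulationSpec(
        n_agents=int(section.get("n_agents", 100_000)),
        gender_split=float(section.get("gender_split", 0.5)),
        education_probs=tuple(section.get("education_probs", (0.53422, 0.16642, 0.29936))),
        wealth_probs=tuple(section.get("wealth_probs", (0.20131, 0.19959, 0.19937, 0.20052, 0.19921))),
        age_probs=tuple(section.get("age_probs", (0.33261, 0.08264, 0.17547, 0.40928))),
        income_model=income,
        density_model=density,
        seed=int(section.get("seed", 0)),
    )


def _weight_model(section: dict) -> WeightModel:
    section = _check_keys("weights", section)

    def pair(name, default):
        v = section.get(name, default)
        if np.shape(v) != (2,):
            raise ConfigError(f"weights.{name} must be a [mean, sd] pair")
        return (float(v[0]), float(v[1]))

    return WeightModel(
        gamma=pair("gamma", (1.5, 0.3)),
        delta=pair("delta", (0.06, 0.015)),
        lam=pair("lam", (2.0, 0.4)),
        alpha_home=pair("alpha_home", (0.5, 0.3)),
    )


def build_simulation_config(cfg: dict) -> SimulationConfig:
    """Assemble a SimulationConfig from a validated config dict."""
    fac = _check_keys("facilities", cfg.get("facilities", {}))
    records = load_hospitals(fac.get("table"))
    if fac.get("coords") is None:
        coords = load_default_coords()
    else:
        coords = (
            pd.read_csv(fac["coords"])
            .rename(columns={"Hospital ID": "hospital_id"})
            .set_index("hospital_id")
        )
    eng = _check_keys("engine", cfg.get("engine", {}))
    return SimulationConfig(
        population=_population_spec(cfg.get("population", {})),
        facilities=build_facility_model(records, coords=coords),
        weights=_weight_model(cfg.get("weights", {})),
        dose=float(eng.get("dose", 0.0)),
        batch_size=int(eng.get("batch_size", 20_000)),
        n_runs=int(eng.get("n_runs", 50)),
        master_seed=int(eng.get("master_seed", 0)),
        money_form=str(eng.get("money_form", "capped_share")),
    )


def load_config(path=None) -> SimulationConfig:
    """One-step: YAML path (or packaged default) -> SimulationConfig."""
    return build_simulation_config(load_config_dict(path))


def experiment_settings(cfg: dict) -> dict:
    """Validated ``experiment`` section with defaults filled in."""
    exp = _check_keys("experiment", dict(cfg.get("experiment", {})))
    grid = exp.get("dose_grid", {"start": 0, "stop": 1_000_000, "step": 10_000})
    doses = tuple(
        float(d)
        for d in np.arange(grid["start"], grid["stop"] + grid["step"] // 2, grid["step"])
    )
    return {
        "anchors": tuple(
            (float(d), float(r))
            for d, r in exp.get("anchors", ((0, 0.566), (280_000, 0.300)))
        ),
        "dose_grid": doses,
        "sweep_n_runs": int(exp.get("sweep_n_runs", 10)),
        "sweep_batch_size": int(exp.get("sweep_batch_size", 5_000)),
        "sweep_statistic": str(exp.get("sweep_statistic", "expected")),
        "plateau_epsilon": float(exp.get("plateau_epsilon", 1e-9)),
        "subgroup_dose": float(exp.get("subgroup_dose", 280_000)),
        "calibration_tolerance": float(exp.get("calibration_tolerance", 0.015)),
    }


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical JSON form (key order independent)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
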