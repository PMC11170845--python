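"""Declarative run configuration (YAML/JSON) for the full pipeline."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: every pipeline stage reads its settings (and seed) from this one tree
DEFAULT_CONFIG: dict = {
    "seeds": {
        "data": 1,
        "bootstrap": 101,
        "vpc": 202,
        "pta": 303,
    },
    "data": {
        "path": None,          # read this CSV instead of simulating
        "dv_unit": "mmol/L",
        "n_subjects": 51,
    },
    "model": {
        "residual": "additive",
        "baseline": "data",
        "ref_CCR": 51.0,
        "ref_BMI": 51.0,
    },
    "estimation": {
        "maxfev": 4000,
        "compute_se": True,
    },
    "scm": {
        "run": True,
        "forward_alpha": 0.01,
        "backward_alpha": 0.001,
        # candidate covariates; continuous ones are centered on the dataset
        # median unless a reference is given here
        "continuous": ["CCR", "BMI", "age", "albumin", "calcium"],
        "categorical": ["furosemide", "labetalol", "nifedipine", "ADR"],
    },
    "bootstrap": {"run": True, "B": 200},
    "vpc": {"run": True, "n_sim": 500},
    "pta": {
        "run": True,
        "n": 1000,
        "ccr_levels": [140.0, 175.0, 213.0],
        "bmi_levels": [27.0, 29.0, 33.0],
        "window_mmol": [2.0, 3.5],
        # optional custom regimens, e.g.
        #   regimens: {slow_load: [{start: 0, grams: 5, duration_h: 1},
        #                          {start: 1, grams: 10, duration_h: 8}]}
        # default: the four standard loading/maintenance combinations
        "regimens": None,
    },
    "plots": False,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, updated by the YAML file at ``path``, then by ``overrides``."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
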