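"""Run configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

import copy
from typing import Any

import yaml

from .formula import ElementBounds
from .matching import MatchConfig
from .simulate import SimConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


#: Neutral-mass corrections: M = mz + shift. The mobile phase's ammonium
#: is unlabeled, so an ammonium adduct carries no labeling shift and only
#: the neutral-mass arithmetic changes.
ADDUCT_SHIFTS = {
    "[M-H]-": +1.007276466812,
    "[M+H]+": -1.007276466812,
    "[M+NH4]+": -(1.007276466812 + 17.02654910112),  # proton + NH3
}

DEFAULTS: dict[str, Any] = {
    "filter": {"min_snr": 5.0, "mz_min": 70.0, "mz_max": 1000.0},
    "match": {
        "mz_tol_ppm": 5.0,
        "rt_tol_min": 0.5,
        "intensity_ratio_lo": 0.2,
        "intensity_ratio_hi": 5.0,
        "c_max": 40,
        "n_max": 10,
        "adduct_neg": "[M-H]-",
        "adduct_pos": "[M+H]+",
    },
    "bounds": {
        "c": [0, 50],
        "h": [0, 80],
        "n": [0, 20],
        "o": [0, 20],
        "p": [0, 4],
        "s": [0, 4],
        "rdbe": [0.0, 25.0],
        "hc_ratio": [0.1, 6.0],
    },
    "decompose": {"tol_ppm": 5.0},
    "annotation": {
        "mass_tol_ppm": 5.0,
        "rt_tol_min": 0.5,
        "ms2_threshold": 0.7,
        "frag_tol_mz": 0.01,
    },
    "merge": {"rt_tol_min": 0.5},
    "simulate": {
        "n_compounds": 1000,
        "ppm_noise_sd": 2.0,
        "rt_jitter_sd": 0.05,
        "dropout": 0.10,
        "decoy_density": 1.0,
        "neg_frac": 0.67,
        "esi_only_frac": 0.55,
        "apci_only_frac": 0.35,
        "lib_rt_frac": 0.6,
        "lib_ms2_frac": 0.6,
        "query_ms2_frac": 0.7,
        "seed": 0,
    },
    "log_level": "INFO",
}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {where} must be a mapping")
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Return the full config dict: defaults overlaid with the YAML file
    at ``path`` (if given). Unknown keys raise :class:`ConfigError`."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping")
    cfg = _merge_strict(DEFAULTS, user)
    for key in ("adduct_neg", "adduct_pos"):
        if cfg["match"][key] not in ADDUCT_SHIFTS:
            raise ConfigError(
                f"match.{key}: unknown adduct {cfg['match'][key]!r}; "
                f"supported: {sorted(ADDUCT_SHIFTS)}"
            )
    return cfg


def default_config_yaml() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def match_config(cfg: dict[str, Any]) -> MatchConfig:
    m = cfg["match"]
    return MatchConfig(
        mz_tol_ppm=float(m["mz_tol_ppm"]),
        rt_tol=float(m["rt_tol_min"]),
        intensity_ratio_bounds=(float(m["intensity_ratio_lo"]), float(m["intensity_ratio_hi"])),
        c_max=int(m["c_max"]),
        n_max=int(m["n_max"]),
    )


def element_bounds(cfg: dict[str, Any]) -> ElementBounds:
    b = cfg["bounds"]
    return ElementBounds(
        c=tuple(b["c"]), h=tuple(b["h"]), n=tuple(b["n"]),
        o=tuple(b["o"]), p=tuple(b["p"]), s=tuple(b["s"]),
        rdbe_range=tuple(b["rdbe"]), hc_ratio_range=tuple(b["hc_ratio"]),
    )


def sim_config(cfg: dict[str, Any], seed: int | None = None) -> SimConfig:
    s = dict(cfg["simulate"])
    if seed is not None:
        s["seed"] = seed
    return SimConfig(**s)
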