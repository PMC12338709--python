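"""Default quantification configuration and config-file loading.

All physical constants and relaxation times live here (or in a user
config file), never hard-coded inside the numerical operations.  Water
densities and the molar concentration of pure water are the standard
literature values used in water-referenced MRS quantification; the
compartment water T1/T2 and metabolite relaxation times are 3 T
literature values and can be overridden per study.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

#: Default quantification configuration.  Times in seconds; acquisition
#: times accepted in ms (``te_ms``/``tr_ms``) and converted explicitly.
DEFAULT_QUANT_CONFIG: dict[str, Any] = {
    "acquisition": {"te_ms": 35.0, "tr_ms": 2000.0},
    "water_relaxation": {
        "gm": {"t1_s": 1.331, "t2_s": 0.110},
        "wm": {"t1_s": 0.832, "t2_s": 0.0799},
        "csf": {"t1_s": 4.163, "t2_s": 0.503},
    },
    "metabolite_relaxation": {
        "tCr": {"t1_s": 1.35, "t2_s": 0.166},
    },
    "densities": {"gm": 0.78, "wm": 0.65, "csf": 0.97},
    "h2o_molar": 55.51,  # mol/L
}


def default_quant_config() -> dict[str, Any]:
    """Return a deep copy of the default quantification config."""
    return copy.deepcopy(DEFAULT_QUANT_CONFIG)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML config file and merge it over the defaults.

    Top-level and second-level keys present in the file override the
    defaults; everything else keeps its default value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        user = json.loads(text)
    else:
        user = yaml.safe_load(text)
    if not isinstance(user, dict):
        raise ValueError(f"config file must contain a mapping: {path}")
    cfg = default_quant_config()
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a config dict, for provenance lines."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
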