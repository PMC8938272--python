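"""Pipeline configuration: defaults, validation and hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any

DEFAULTS: dict[str, Any] = {
    "outcome": "orr",
    "level": "species",
    "seed": 0,
    "n_perm": 999,
    "alpha": 0.05,
    "min_methods": {"species": 3, "KO": 6, "EC": 6},
    "fdr_gate": 0.2,
    "library_cutoff": 1000,
    "min_prevalence": 0.1,
    "ml": {"folds": 5, "repeats": 100, "min_nonzero": 5},
    "cutoff": {"species": 1e-4, "KO": 1e-6, "EC": 1e-6},
    "pseudocount": {"species": 1e-5, "KO": 1e-9, "EC": 1e-9},
    "paths": {"tables": None, "metadata": None, "out": "results"},
    "simulation": {},
}

_TYPES = {
    "outcome": str, "level": str, "seed": int, "n_perm": int, "alpha": float,
    "min_methods": dict, "fdr_gate": float, "library_cutoff": int,
    "min_prevalence": float, "ml": dict, "cutoff": dict, "pseudocount": dict,
    "paths": dict, "simulation": dict,
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(config: dict | None) -> dict:
    """Fill defaults and validate; all problems are reported together."""
    config = config or {}
    errors: list[str] = []
    out = copy.deepcopy(DEFAULTS)
    for key, value in config.items():
        if key not in DEFAULTS:
            errors.append(f"unknown config key {key!r}")
            continue
        expected = _TYPES[key]
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            errors.append(f"config key {key!r}: expected {expected.__name__}, "
                          f"got {type(value).__name__}")
            continue
        if isinstance(value, dict):
            out[key].update(value)
        else:
            out[key] = value
    if isinstance(out["outcome"], str) and out["outcome"] not in ("orr", "pfs12"):
        errors.append(f"outcome must be 'orr' or 'pfs12', got {out['outcome']!r}")
    if any(v <= 0 for v in out["min_methods"].values()):
        errors.append("min_methods thresholds must be positive")
    if not (0 < out["alpha"] < 1):
        errors.append("alpha must lie in (0, 1)")
    if out["n_perm"] < 1:
        errors.append("n_perm must be positive")
    for block in ("cutoff", "pseudocount"):
        if any(v <= 0 for v in out[block].values()):
            errors.append(f"{block} values must be positive")
    if errors:
        raise ConfigError(errors)
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of the normalized configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
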