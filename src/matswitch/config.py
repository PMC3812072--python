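"""Structured run configuration for the command line.

A flat YAML file with optional sections; unknown keys are rejected so a
typo never silently falls back to a default.  Example::

    strain: h09
    generations: 30
    capacity: 10000
    seed: 7
    founder: Pu
    params:
      attempt_success: 0.85
      imprint_efficiency: 1.0
      model_variant: competition
      weights:
        SRE2: {P: {"swi6+": 0.2}}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .choice import ChoiceParams, default_params
from .region import Allele, Enhancer

__all__ = ["RunConfig", "load_run_config", "apply_param_overrides"]

_TOP_KEYS = {
    "strain", "generations", "capacity", "seed", "founder", "out", "params",
    "n_replicates", "n_cells", "noise_cv", "method", "f_true",
}
_PARAM_KEYS = {
    "attempt_success", "rpc_loss_success", "imprint_efficiency",
    "model_variant", "spreading_preference", "lethal_on_failure", "weights",
}


@dataclass
class RunConfig:
    """Everything a CLI subcommand needs, with explicit seeding."""

    strain: Optional[str] = None
    generations: int = 30
    capacity: int = 10_000
    seed: Optional[int] = None
    founder: str = "Pu"
    out: Optional[str] = None
    n_replicates: int = 9
    n_cells: int = 500
    noise_cv: float = 0.15
    method: str = "microscopy"
    f_true: Optional[float] = None
    params: ChoiceParams = field(default_factory=default_params)

    def digest(self) -> str:
        """Stable hash of the configuration, for log provenance."""
        d = dataclasses.asdict(self)
        d["params"] = json.loads(self.params.to_json())
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def apply_param_overrides(base: ChoiceParams, overrides: dict) -> ChoiceParams:
    """Apply a nested override mapping onto a parameter set."""
    unknown = set(overrides) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)} (valid: {sorted(_PARAM_KEYS)})")
    kwargs = {k: v for k, v in overrides.items() if k != "weights"}
    weights = dict(base.weights)
    for enh_name, by_cell in (overrides.get("weights") or {}).items():
        enh = Enhancer(str(enh_name).upper())
        for cell_name, by_col in by_cell.items():
            cell = Allele(str(cell_name).upper())
            for col, val in by_col.items():
                if col not in ("swi6+", "swi6del"):
                    raise ValueError(f"unknown chromatin column {col!r}")
                weights[(enh, cell, col == "swi6+")] = float(val)
    return dataclasses.replace(base, weights=weights, **kwargs)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)} (valid: {sorted(_TOP_KEYS)})")
    params = apply_param_overrides(default_params(), raw.pop("params", {}) or {})
    return RunConfig(params=params, **raw)
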