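"""Pipeline configuration: defaults, validation, canonical serialization.

The config is a flat key: value YAML document plus an ``inputs`` mapping of
named file paths. Validation reports every problem at once and echoes the
canonical form with defaults injected; the manifest hash is the SHA-256 of
that canonical serialization.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, NamedTuple

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "anchortf_out",
    "anchor": "ANCHOR",
    "simulate": True,
    "run_network": True,
    # promoter / anchored-scan parameters
    "promoter_upstream": 1500,
    "promoter_downstream": 300,
    "inter_binding_distance": 100,
    "rel_score_threshold": 0.9,
    "min_ic_bits": 8.0,
    "z_threshold": 10.0,
    "background": "shuffle",
    # ABC parameters
    "abc_window": 5_000_000,
    "abc_threshold": 0.01,
    "hic_resolution": 5000,
    "hic_gamma": 0.87,
    "hic_pseudocount": 0.3,
    "n_strongest": 15000,
    "peak_width": 500,
    # gene selection
    "soft_power": 10,
    "min_module_size": 30,
    "cut_height_frac": 0.95,
    "max_missing_frac": 0.2,
    "downreg_fold": 2.0,
    "alpha": 0.05,
    "fdr": 0.05,
    # network
    "n_shells": 4,
    "min_links": 2,
    "inputs": {},
}

INPUT_KEYS = {
    "expression", "sample_times", "genome", "gene_table", "motifs",
    "atac", "h3k27ac", "hic", "target_sets", "interactions",
    "promoters_bed", "enhancers_bed",
}

_RANGES: dict[str, tuple[float, float]] = {
    "promoter_upstream": (0, 1e9),
    "promoter_downstream": (0, 1e9),
    "inter_binding_distance": (1, 1e9),
    "rel_score_threshold": (1e-9, 1.0),
    "min_ic_bits": (0, 64),
    "z_threshold": (0, 1e9),
    "abc_window": (1, 1e12),
    "abc_threshold": (0, 1),
    "hic_resolution": (1, 1e9),
    "hic_gamma": (0, 10),
    "hic_pseudocount": (0, 1e9),
    "n_strongest": (1, 1e9),
    "peak_width": (50, 1e9),
    "soft_power": (1, 100),
    "min_module_size": (1, 1e9),
    "cut_height_frac": (1e-9, 1.0),
    "max_missing_frac": (0, 1),
    "downreg_fold": (1e-9, 1e9),
    "alpha": (0, 1),
    "fdr": (0, 1),
    "n_shells": (2, 1e6),
    "min_links": (1, 1e6),
}


class ValidatedConfig(NamedTuple):
    config: dict[str, Any]
    errors: list[str]


def validate_config(source: str | Path | dict) -> ValidatedConfig:
    """Validate a config path/dict; return canonical config and all errors."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
        if not isinstance(raw, dict):
            return ValidatedConfig({}, ["config root must be a mapping"])
    errors: list[str] = []
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, value in raw.items():
        if key == "inputs":
            if not isinstance(value, dict):
                errors.append("inputs must be a mapping of name -> path")
                continue
            for name, path in value.items():
                if name not in INPUT_KEYS:
                    errors.append(f"unknown input {name!r}")
                else:
                    cfg["inputs"][name] = str(path)
            continue
        if key not in DEFAULTS:
            errors.append(f"unknown key {key!r}")
            continue
        cfg[key] = value
    for key, (lo, hi) in _RANGES.items():
        v = cfg[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or not lo <= v <= hi:
            errors.append(f"{key} must be a number in [{lo:g}, {hi:g}]; got {v!r}")
    if cfg["background"] not in ("shuffle", "outside", "regions"):
        errors.append(f"background must be shuffle|outside|regions; got {cfg['background']!r}")
    if not isinstance(cfg["seed"], int) or isinstance(cfg["seed"], bool):
        errors.append("seed must be an integer")
    for name, path in cfg["inputs"].items():
        if not Path(path).exists():
            errors.append(f"input {name!r}: file not found: {path}")
    if not cfg["simulate"]:
        required = {"genome", "gene_table", "motifs"}
        missing = required - set(cfg["inputs"])
        if missing:
            errors.append(f"simulate=false requires inputs: {sorted(missing)}")
    return ValidatedConfig(cfg, errors)


def canonical_yaml(cfg: dict[str, Any]) -> str:
    return yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(canonical_yaml(cfg).encode()).hexdigest()
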