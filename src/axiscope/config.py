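"""Run configuration: flat per-module sections, strict key validation.

A config file is YAML with one section per stage; every key has a default
taken from the owning module, unknown keys are rejected before any stage
runs, and the fully resolved copy is written next to every output so runs
are self-describing.
"""
from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict[str, dict] = {
    "run": {
        "seed": 0,
        "out": "axiscope_out",
        "log_level": "INFO",
    },
    "axis": {
        "cap_d": 200,
        "cap_v": 100,
        "flip": False,
    },
    "profile": {
        "n_bins": 50,
        "span": 0.75,
        "degree": 2,
        "n_grid": 100,
        "features": [],
        "module_file": None,
    },
    "qc": {
        "mode": "spots",
        "min_genes": 500,
        "min_support": None,   # 15 for cells, 5 for spots when unset
        "max_mito_pct": 25.0,
        "mito_prefix": "MT-",
    },
    "coloc": {
        "method": "pearson",
        "major_rule": "threshold",
        "r_min": 0.3,
        "top_k": 10,
        "min_variance": 1e-12,
    },
    "simulate": {
        "preset": "w8-section",
        "n_spots": 2000,
        "ellipse_a": 1.0,
        "ellipse_b": 1.5,
        "dorsal_frac": 0.2,
        "ventral_frac": 0.2,
        "rotation_deg": 0.0,
        "library_size_mean": 1.0,
        "library_size_cv": 0.3,
        "noise_conc": 50.0,
        "age": None,
    },
}


def resolve_config(
    path: str | Path | None = None,
    overrides: dict[str, dict] | None = None,
) -> dict[str, dict]:
    """Merge defaults <- config file <- overrides, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    for source_name, source in (
        ("config file", _load_file(path)),
        ("overrides", overrides or {}),
    ):
        for section, entries in source.items():
            if section not in cfg:
                raise ConfigError(
                    f"{source_name}: unknown section {section!r} "
                    f"(known: {sorted(cfg)})"
                )
            if not isinstance(entries, dict):
                raise ConfigError(f"{source_name}: section {section!r} must be a mapping")
            for key, value in entries.items():
                if key not in cfg[section]:
                    raise ConfigError(
                        f"{source_name}: unknown key {section}.{key} "
                        f"(known: {sorted(cfg[section])})"
                    )
                if value is not None:
                    cfg[section][key] = value
    return cfg


def _load_file(path) -> dict:
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    return raw


def write_resolved(cfg: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(json.dumps(cfg, indent=2))
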