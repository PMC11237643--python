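"""Run configuration: defaults, YAML overrides, and snapshots.

Every CLI run records the full effective configuration in its output so a
fingerprint report is reproducible from the report alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .normalization import DEFAULT_MIN_SAMPLE_READS, DEFAULT_MIN_TOTAL_COUNT, FilterPolicy


def default_config() -> dict:
    return {
        "filter": {
            "min_sample_reads": {
                k.lower(): v for k, v in DEFAULT_MIN_SAMPLE_READS.items()
            },
            "min_prevalence_fraction": 0.5,
            "min_total_count": DEFAULT_MIN_TOTAL_COUNT,
        },
        "tmm": {"trim_m": 0.30, "trim_a": 0.05},
        "breakpoint": {"h": 0.01, "min_segment": 2, "max_breaks": 5},
        "supervised": {"fraction": 0.10, "n_trees": 500, "noise_z": 2.0},
        "validation": {
            "folds": 10,
            "repeats": 5,
            "train_fraction": 0.5,
            "n_trees": 100,
        },
        "gate": {"max_rmse": 0.8, "min_variance_explained": 0.60,
                 "combination": "OR"},
        "unsupervised": {"k_min": 2, "k_max": 12, "alpha": 0.05, "n_init": 10},
    }


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, deep-merged with a YAML override file if given."""
    config = default_config()
    if path is not None:
        with open(path) as handle:
            override = yaml.safe_load(handle) or {}
        if not isinstance(override, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        _deep_update(config, override)
    return config


def filter_policy_from_config(config: dict) -> FilterPolicy:
    section = config["filter"]
    return FilterPolicy(
        min_sample_reads={
            k.upper(): v for k, v in section["min_sample_reads"].items()
        },
        min_prevalence_fraction=section["min_prevalence_fraction"],
        min_total_count=section["min_total_count"],
    )
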