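"""Run configuration: defaults, YAML overlay, CLI overlay, provenance echo.

Precedence is defaults < config file < explicit command-line flags. Every
artifact-producing command writes its fully resolved configuration next to
its outputs so a run is reproducible from the echo alone. A single user
seed deterministically derives per-component seeds (data generation, fold
split, network initialization, bootstrap) as seed*7919 + k mod 2^31.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "label_policy": "strict",
    "blacklist": [],
    "reference_allele": "HLA-B*35:01",
    "windows": [[50, 84], [140, 179]],
    "embedding": {
        "ngram": 1, "window": 5, "dim": 5, "epochs": 5,
        "learning_rate": 0.025, "negative": 5,
    },
    "model": {
        "peptide_repr": "gram1", "mhc_repr": "sequence",
        "mhc_entry": "fully_connected", "gru_units": 64,
        "mhc_fc_units": 256, "mhc_gru_units": 32, "head_fc_units": 256,
        "pep_dim": 5, "mhc_token_dim": 8, "dropout_fc_out": 0.4,
        "dropout_gru_in": 0.4, "dropout_gru_recurrent": 0.3,
        "learning_rate": 3e-3, "batch_size": 128, "max_epochs": 40,
        "patience": 5, "val_fraction": 0.2,
    },
    "evaluation": {"bootstrap": 100, "bootstrap_frac": 0.8},
    "simulate": {"alleles": 8, "records": 5000, "noise": 0.05,
                 "positive_fraction": 0.5},
}


def derive_seed(seed: int, component: int) -> int:
    return (int(seed) * 7919 + component) % (2 ** 31)


def _merge(base: dict, overlay: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in overlay.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"key {here!r} expects a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            if base[key] is not None and value is not None and \
                    not isinstance(value, type(base[key])) and \
                    not (isinstance(base[key], float) and isinstance(value, int)):
                raise TypeError(
                    f"key {here!r} expects {type(base[key]).__name__}, "
                    f"got {type(value).__name__}")
            out[key] = value
    return out


@dataclass
class RunConfig:
    settings: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))
    source_path: str | None = None

    def __getitem__(self, key):
        return self.settings[key]

    def overlay(self, updates: dict) -> "RunConfig":
        return RunConfig(_merge(self.settings, updates), self.source_path)

    def echo(self, out_path) -> None:
        """Write the resolved config with a provenance block."""
        from . import __version__
        payload = {
            "settings": self.settings,
            "provenance": {
                "package_version": __version__,
                "config_hash": hashlib.sha256(
                    json.dumps(self.settings, sort_keys=True).encode()
                ).hexdigest()[:16],
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "config_file": self.source_path,
            },
        }
        with open(out_path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path=None) -> RunConfig:
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        overlay = yaml.safe_load(fh) or {}
    if not isinstance(overlay, dict):
        raise TypeError(f"config file {path} must contain a mapping")
    cfg = cfg.overlay(overlay)
    cfg.source_path = str(path)
    return cfg
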