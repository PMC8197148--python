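"""Flat dotted-key pipeline configuration with YAML file and env overrides.

Precedence: built-in defaults < config file < ``HISTOSTACK_*`` environment
variables (dots become double underscores, e.g. ``HISTOSTACK_GLCM__LEVELS``)
< explicit command-line flags.  Unknown keys are rejected up front.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "patch_size": 50,
    "mode": "full",  # full | standalone:<FAMILY> | fusion:<FAM+FAM+...>
    "synth.n_per_class": 200,
    "synth.class0_smoothness": 3.0,
    "synth.class1_grain": 1.5,
    "synth.contrast_gap": 50.0,
    "synth.base_color": [210, 170, 220],
    "descriptors.orb.nfeatures": 500,
    "glcm.levels": 64,
    "glcm.distance": 1,
    "glcm.log_base": 2.0,
    "stack.roster": ["XGB", "AB", "GB", "RF", "ET", "MLP"],
    "stack.meta": "GB",
    "stack.tau": 0.95,
    "stack.test_fraction": 0.2,
    "stack.hard_labels": False,
    "blankspace.white_thr": 240,
    "blankspace.black_thr": 15,
}

ENV_PREFIX = "HISTOSTACK_"


class ConfigError(ValueError):
    """Unknown or malformed configuration key/value."""


def _coerce(key: str, raw: Any) -> Any:
    default = DEFAULTS[key]
    if isinstance(raw, str) and not isinstance(default, str):
        if isinstance(default, bool):
            return raw.lower() in ("1", "true", "yes")
        if isinstance(default, int):
            return int(raw)
        if isinstance(default, float):
            return float(raw)
        if isinstance(default, list):
            return [x.strip() for x in raw.split(",")]
    return raw


class PipelineConfig:
    """Validated flat key-value configuration."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        self._values = dict(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: Mapping[str, Any]) -> None:
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        for key, value in overrides.items():
            self._values[key] = _coerce(key, value)

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    def families(self) -> tuple[str, ...]:
        """Feature families implied by ``mode``."""
        from .fusion import ALL_FAMILIES

        mode = self._values["mode"]
        if mode == "full":
            return ALL_FAMILIES
        kind, _, arg = mode.partition(":")
        fams = tuple(f.strip().upper() for f in arg.split("+") if f.strip())
        if kind not in ("standalone", "fusion") or not fams:
            raise ConfigError(f"malformed mode {mode!r}")
        if kind == "standalone" and len(fams) != 1:
            raise ConfigError("standalone mode takes exactly one family")
        bad = [f for f in fams if f not in ALL_FAMILIES]
        if bad:
            raise ConfigError(f"unknown families in mode: {bad}")
        return fams

    @classmethod
    def load(cls, path: str | Path | None = None, cli_overrides: Mapping[str, Any] | None = None
             ) -> "PipelineConfig":
        cfg = cls()
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(data, dict):
                raise ConfigError(f"config file {path} must hold a flat mapping")
            cfg.update(data)
        env = {
            key[len(ENV_PREFIX):].lower().replace("__", "."): value
            for key, value in os.environ.items()
            if key.startswith(ENV_PREFIX)
        }
        if env:
            cfg.update(env)
        if cli_overrides:
            cfg.update({k: v for k, v in cli_overrides.items() if v is not None})
        return cfg
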