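"""Layered run configuration: packaged defaults, optional TOML file,
environment-variable overrides (AQUAPOT_SECTION_KEY=value)."""

from __future__ import annotations

import os
import tomllib
from typing import Any

DEFAULTS: dict[str, dict[str, Any]] = {
    "site": {"latitude": 36.8, "altitude": 1489.0, "station_id": "53810"},
    "et0": {"albedo": 0.23, "angstrom_a": 0.25, "angstrom_b": 0.50},
    "soil": {"initial_condition": "fc", "ke": 1.10, "z_min": 0.20},
    "crop": {"dm_fraction": 0.11, "cc_star_policy": "micro_advective"},
    "run": {"seed": 0, "log_level": "WARNING"},
}

ENV_PREFIX = "AQUAPOT"


def _coerce(value: str, like: Any) -> Any:
    if isinstance(like, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(like, int) and not isinstance(like, bool):
        return int(value)
    if isinstance(like, float):
        return float(value)
    return value


def load_config(path: str | None = None, env: dict | None = None) -> dict:
    """Defaults, overlaid by a TOML file, overlaid by environment variables."""
    cfg = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for sec, vals in user.items():
            cfg.setdefault(sec, {}).update(vals)
    env = os.environ if env is None else env
    for sec, vals in cfg.items():
        for key, default in vals.items():
            ev = env.get(f"{ENV_PREFIX}_{sec.upper()}_{key.upper()}")
            if ev is not None:
                vals[key] = _coerce(ev, default)
    return cfg


def format_config(cfg: dict) -> str:
    lines = []
    for sec in sorted(cfg):
        lines.append(f"[{sec}]")
        for key in sorted(cfg[sec]):
            val = cfg[sec][key]
            rendered = f'"{val}"' if isinstance(val, str) else val
            lines.append(f"{key} = {rendered}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
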