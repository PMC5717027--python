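"""YAML configuration with schema checking.

Each CLI command validates its configuration against a flat schema
{key: (type, default)}; a sentinel default marks required keys.  All
offending keys are reported together in one :class:`ConfigError`.
"""

from __future__ import annotations

import yaml

from .errors import ConfigError

REQUIRED = object()


def load_config(path) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def validate(cfg: dict, schema: dict, where: str = "config") -> dict:
    """Fill defaults and coerce types; collect every offending key."""
    bad: list[str] = []
    out: dict = {}
    for key, (typ, default) in schema.items():
        if key not in cfg or cfg[key] is None:
            if default is REQUIRED:
                bad.append(f"{key} (missing)")
            else:
                out[key] = default
            continue
        val = cfg[key]
        try:
            if typ is float:
                val = float(val)
            elif typ is int:
                iv = int(val)
                if iv != float(val):
                    raise ValueError
                val = iv
            elif typ is str:
                val = str(val)
            elif typ is bool and not isinstance(val, bool):
                raise ValueError
        except (TypeError, ValueError):
            bad.append(f"{key} (expected {typ.__name__}, got {val!r})")
            continue
        out[key] = val
    unknown = sorted(set(cfg) - set(schema))
    if unknown:
        bad.extend(f"{k} (unknown key)" for k in unknown)
    if bad:
        raise ConfigError(f"invalid {where}: " + "; ".join(bad), keys=bad)
    return out
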