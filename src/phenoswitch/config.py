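"""Structured JSON configuration and tabular output.

A run is described by a JSON object with (up to) three blocks::

    {
      "strategy": {"strategy": "responsive", "m1": 4, "m2": 0.2,
                   "d1": 0.2, "d2": 0.2},
      "env": {"s1": 0.2, "s2": 0.1},
      "method": {"n_steps": 20000, "n_reps": 8, "seed": 1}
    }

Strategy kinds: ``responsive | preliminary | stochastic | sleepless |
convex | general``; matrices are serialized row-major.  Command-line
flags override file values.  Validation errors always name the
offending field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .environment import EnvironmentParams
from .strategies import (
    StrategyPair,
    make_convex_combination,
    make_general,
    make_preliminary,
    make_responsive,
    make_sleepless,
    make_stochastic,
)

__all__ = [
    "ConfigError",
    "strategy_from_config",
    "env_from_config",
    "parse_config",
    "strategy_to_config",
    "write_results",
]


class ConfigError(ValueError):
    """A malformed or incomplete configuration."""


def _require(d: dict, key: str, context: str):
    if key not in d:
        raise ConfigError(f"missing required field '{key}' in {context}")
    return d[key]


def env_from_config(d: dict) -> EnvironmentParams:
    s1 = _require(d, "s1", "environment config")
    s2 = _require(d, "s2", "environment config")
    try:
        return EnvironmentParams(float(s1), float(s2))
    except ValueError as exc:
        raise ConfigError(f"invalid environment parameters: {exc}") from exc


def strategy_from_config(d: dict) -> StrategyPair:
    kind = _require(d, "strategy", "strategy config")
    ctx = f"'{kind}' strategy config"
    try:
        if kind in ("responsive", "preliminary", "sleepless"):
            maker = {
                "responsive": make_responsive,
                "preliminary": make_preliminary,
                "sleepless": make_sleepless,
            }[kind]
            return maker(
                float(_require(d, "m1", ctx)),
                float(_require(d, "m2", ctx)),
                float(d.get("d1", 0.2)),
                float(d.get("d2", 0.2)),
            )
        if kind == "stochastic":
            m_a = float(_require(d, "m_a", ctx))
            m_d = float(_require(d, "m_d", ctx))
            w1 = float(_require(d, "w1", ctx))
            w2 = float(_require(d, "w2", ctx))
            # absent death probabilities default to the zero-determinant
            # choice 1 - w_e - d_e = w_e m_d/m_a (exact-formula regime)
            d1 = float(d["d1"]) if "d1" in d else 1.0 - w1 - w1 * m_d / m_a
            d2 = float(d["d2"]) if "d2" in d else 1.0 - w2 - w2 * m_d / m_a
            return make_stochastic(
                m_a, m_d, float(_require(d, "alpha", ctx)), w1, w2, d1, d2
            )
        if kind == "convex":
            return make_convex_combination(
                strategy_from_config(_require(d, "pre", ctx)),
                strategy_from_config(_require(d, "res", ctx)),
                float(_require(d, "q1", ctx)),
                float(_require(d, "q2", ctx)),
                label=d.get("label"),
            )
        if kind == "general":
            return make_general(
                np.array(_require(d, "M1", ctx), dtype=float),
                np.array(_require(d, "M2", ctx), dtype=float),
                label=d.get("label", "general"),
            )
    except ConfigError:
        raise
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"invalid {ctx}: {exc}") from exc
    raise ConfigError(
        f"unknown strategy kind '{kind}'; expected responsive, preliminary, "
        "stochastic, sleepless, convex or general"
    )


def strategy_to_config(pair: StrategyPair) -> dict:
    """Serialize a strategy back to a config dict (round-trippable)."""
    if pair.kind in ("responsive", "preliminary", "sleepless", "stochastic"):
        return {"strategy": pair.kind, **pair.params}
    return {
        "strategy": "general",
        "M1": pair.M1.tolist(),
        "M2": pair.M2.tolist(),
        "label": pair.label,
    }


def parse_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
) -> dict:
    """Load a JSON config file and apply flag overrides (flags win).

    Returns the merged raw dict; block parsing is done by
    :func:`env_from_config` / :func:`strategy_from_config`.
    """
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file {path} is not valid JSON: {exc}") from exc
        if not isinstance(cfg, dict):
            raise ConfigError(f"config file {path} must contain a JSON object")
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        block, _, leaf = key.partition(".")
        if leaf:
            cfg.setdefault(block, {})[leaf] = val
        else:
            cfg[key] = val
    return cfg


def _round12(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    return obj


def write_results(
    results,
    path: str | Path,
    format: str = "json",
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write results as CSV or JSON with a reproducibility metadata block.

    Floats are emitted at 12 significant digits; the metadata records
    the package version, the seed, and a hash of the resolved config,
    so a repeated run with the same config is byte-identical in its
    data section.
    """
    path = Path(path)
    cfg_hash = (
        hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
        if config is not None
        else None
    )
    meta = {"version": __version__, "seed": seed, "config_hash": cfg_hash}
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        with open(path, "w") as fh:
            fh.write(f"# phenoswitch {meta['version']} seed={seed} config={cfg_hash}\n")
            results.to_csv(fh, index=False, float_format="%.12g")
    elif format == "json":
        if isinstance(results, pd.DataFrame):
            results = results.to_dict(orient="records")
        payload = {"metadata": meta, "results": _round12(results)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ConfigError(f"unknown output format '{format}'; use csv or json")
    return path
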