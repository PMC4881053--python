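"""Single-file configuration: every pipeline threshold under a named key.

A YAML mapping with two optional sections, ``alignment`` and ``simulation``,
whose keys are the field names of :class:`rgevo.core_io.AlignParams` and
:class:`rgevo.synthetic_data.SimulationConfig`. Omitted keys keep the
defaults (the published thresholds: protein e-value 1e-10, genome e-value
1e-5, CIP > 60, <= 8 intervening genes, Ka/Ks bins at 0.25/0.8/1.0).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .core_io import AlignParams
from .synthetic_data import SimulationConfig


def load_config(path) -> tuple[AlignParams, SimulationConfig]:
    """Read a YAML config file into (AlignParams, SimulationConfig)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"alignment", "simulation"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return (_build(AlignParams, raw.get("alignment") or {}),
            _build(SimulationConfig, raw.get("simulation") or {}))


def _build(cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls) if f.init
             and not f.name.startswith("_")}
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**overrides)


def dump_defaults(path) -> str:
    """Write the full default configuration with every named threshold."""
    out = {}
    for section, cls in (("alignment", AlignParams),
                         ("simulation", SimulationConfig)):
        out[section] = {
            f.name: getattr(cls(), f.name)
            for f in dataclasses.fields(cls)
            if f.init and not f.name.startswith("_")
            and isinstance(getattr(cls(), f.name), (int, float, str, bool))
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
    return str(path)
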