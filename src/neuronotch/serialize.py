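"""Spec serialization (YAML/JSON) and filter export (CSV).

Specs are plain frozen dataclasses; they serialize to flat mappings with a
``type`` discriminator and round-trip losslessly. Designed channels export
their poles/zeros/gain and their discretized second-order sections as CSV
for verification in external tools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .channel import DigitalChannel, NonlinearitySpec
from .errors import InvalidSpecificationError
from .sensing import SensingSpec
from .stages import GainStageSpec, LowpassSpec, NotchSpec, PreampSpec
from .synth import LFPSpec, NoiseModel, StimulusSpec

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "export_sos_csv",
    "export_zpk_csv",
]

_SPEC_TYPES = {
    cls.__name__: cls
    for cls in (
        PreampSpec, NotchSpec, LowpassSpec, GainStageSpec, NonlinearitySpec,
        StimulusSpec, LFPSpec, NoiseModel, SensingSpec,
    )
}


def _plain(value):
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def spec_to_dict(spec) -> dict:
    """Serialize a spec dataclass to a plain mapping with a type tag."""
    name = type(spec).__name__
    if name not in _SPEC_TYPES:
        raise InvalidSpecificationError(f"{name} is not a serializable spec")
    out = {"type": name}
    for f in dataclasses.fields(spec):
        if f.name.startswith("_"):
            continue
        out[f.name] = _plain(getattr(spec, f.name))
    return out


def spec_from_dict(data: dict):
    """Reconstruct a spec from :func:`spec_to_dict` output (validates)."""
    data = dict(data)
    name = data.pop("type", None)
    cls = _SPEC_TYPES.get(name)
    if cls is None:
        raise InvalidSpecificationError(f"unknown spec type {name!r}")
    fields = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
    unknown = set(data) - fields
    if unknown:
        raise InvalidSpecificationError(
            f"unknown fields for {name}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def save_spec(path: str | Path, spec) -> None:
    """Write a spec as YAML (``.yaml``/``.yml``) or JSON (``.json``)."""
    path = Path(path)
    data = spec_to_dict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise InvalidSpecificationError(f"unsupported extension {path.suffix!r}")


def load_spec(path: str | Path):
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return spec_from_dict(data)


def export_sos_csv(channel: DigitalChannel, path: str | Path) -> None:
    """Write second-order sections, one per row: b0,b1,b2,a0,a1,a2."""
    rows = ["b0,b1,b2,a0,a1,a2"]
    for sec in channel.sos:
        rows.append(",".join(f"{v:.17g}" for v in sec))
    Path(path).write_text("\n".join(rows) + "\n")


def export_zpk_csv(model, path: str | Path) -> None:
    """Write the cascade's zeros/poles/gain: kind,real,imag rows."""
    z, p, k = model.zpk()
    rows = ["kind,real,imag"]
    rows += [f"zero,{v.real:.17g},{v.imag:.17g}" for v in z]
    rows += [f"pole,{v.real:.17g},{v.imag:.17g}" for v in p]
    rows.append(f"gain,{k:.17g},0")
    Path(path).write_text("\n".join(rows) + "\n")
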