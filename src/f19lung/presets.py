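"""Shipped gas and protocol presets.

Every measured relaxation row and every acquisition protocol of the study is
available by name so pipelines can be assembled without retyping constants.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .signal_model import AcquisitionProtocol, GasSpecies

__all__ = ["load_gases", "load_protocols", "load_reference_snr", "gas", "protocol"]


def _read_yaml(name: str, path: str | Path | None = None) -> dict[str, Any]:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("f19lung").joinpath("data", name)
    with ref.open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_gases(path: str | None = None) -> dict[str, GasSpecies]:
    """All gas presets, keyed by name (e.g. ``"ofcb-invivo"``)."""
    raw = _read_yaml("gases.yaml", path)
    return {
        name: GasSpecies(
            name=name,
            n_equivalent_f=entry["n_equivalent_f"],
            t1_ms=entry["t1_ms"],
            t2star_ms=entry["t2star_ms"],
            condition=entry.get("condition", "pure"),
            peaks=tuple(tuple(p) for p in entry.get("peaks", [])),
        )
        for name, entry in raw.items()
    }


@lru_cache(maxsize=None)
def load_protocols(path: str | None = None) -> dict[str, AcquisitionProtocol]:
    """All acquisition-protocol presets, keyed by name."""
    raw = _read_yaml("protocols.yaml", path)
    out = {}
    for name, entry in raw.items():
        kwargs = dict(entry)
        for key in ("matrix", "fov_mm"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        out[name] = AcquisitionProtocol(name=name, **kwargs)
    return out


@lru_cache(maxsize=None)
def load_reference_snr() -> dict[str, Any]:
    """Reported SNR values from the original study (for report commands)."""
    return _read_yaml("reference_snr.yaml")


def gas(name: str) -> GasSpecies:
    """Look up a single gas preset by name."""
    gases = load_gases()
    if name not in gases:
        raise KeyError(f"unknown gas preset {name!r}; available: {sorted(gases)}")
    return gases[name]


def protocol(name: str) -> AcquisitionProtocol:
    """Look up a single protocol preset by name."""
    protos = load_protocols()
    if name not in protos:
        raise KeyError(f"unknown protocol preset {name!r}; available: {sorted(protos)}")
    return protos[name]
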