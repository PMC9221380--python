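"""Configuration files, fixtures and run manifests.

YAML/JSON configuration files map directly onto the parameter
dataclasses; omitted fields fall back to the shipped defaults and
unknown keys are rejected by name.  A top-level ``kind`` selects the
object to build (``network``, ``neuron``, ``diffusion``, ``girk``,
``release``, ``geometry``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

from .geometry import CloudCalibration
from .params import (DiffusionParams, GIRKParams, NeuronParams,
                     ParameterError, ReleaseParams, StimulusProtocol)

__all__ = [
    "load_config",
    "save_config",
    "make_fixtures",
    "RunManifest",
    "ConfigError",
]


class ConfigError(ParameterError):
    """Schema violation in a configuration file."""


_SIMPLE_KINDS = {
    "neuron": NeuronParams,
    "diffusion": DiffusionParams,
    "girk": GIRKParams,
    "release": ReleaseParams,
    "geometry": CloudCalibration,
}


def _from_dict(cls, data: dict, context: str = ""):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}{context}")
    cleaned = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        cleaned[k] = v
    try:
        return cls(**cleaned)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _network_from_dict(data: dict):
    from .network import NetworkConfig, Wire
    allowed = {"neurons", "protocols", "wires", "gap_junctions",
               "duration_ms", "dt_ms", "sample_dt_ms", "seed", "noise",
               "girk", "release", "diffusion"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} for network")
    kw = {}
    if "neurons" in data:
        kw["neurons"] = [_from_dict(NeuronParams, d or {}, " (neurons)")
                         for d in data["neurons"]]
    if "protocols" in data:
        kw["protocols"] = [StimulusProtocol(steps=tuple(map(tuple, steps)))
                           for steps in data["protocols"]]
    if "wires" in data:
        kw["wires"] = [_from_dict(Wire, d, " (wires)") for d in data["wires"]]
    if "gap_junctions" in data:
        kw["gap_junctions"] = [tuple(g) for g in data["gap_junctions"]]
    for key in ("duration_ms", "dt_ms", "sample_dt_ms", "seed", "noise"):
        if key in data:
            kw[key] = data[key]
    for key, cls in (("girk", GIRKParams), ("release", ReleaseParams),
                     ("diffusion", DiffusionParams)):
        if key in data:
            kw[key] = _from_dict(cls, data[key] or {}, f" ({key})")
    return NetworkConfig(**kw)


def load_config(path):
    """Load a YAML/JSON config into fully-resolved parameter objects.

    An empty body (or empty section) resolves to the shipped defaults.
    """
    import yaml
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kind = data.pop("kind", "network")
    if kind == "network":
        return _network_from_dict(data)
    if kind in _SIMPLE_KINDS:
        return _from_dict(_SIMPLE_KINDS[kind], data, f" (kind={kind})")
    raise ConfigError(f"unknown config kind {kind!r}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


def save_config(obj, path):
    """Serialize a parameter object back to YAML (round-trip safe)."""
    import yaml
    from .network import NetworkConfig
    if isinstance(obj, NetworkConfig):
        from .network import _describe
        data = {"kind": "network", **_describe(obj)}
        data.pop("duration_ms", None)
        data["duration_ms"] = obj.duration_ms
    else:
        kind = next((k for k, cls in _SIMPLE_KINDS.items()
                     if isinstance(obj, cls)), None)
        if kind is None:
            raise ConfigError(f"cannot serialize {type(obj).__name__}")
        data = {"kind": kind, **_to_plain(obj)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Deterministic bundle of small inputs exercising every module.

    Contains a network configuration per interaction scenario (with a
    fixed, pre-calibrated step amplitude so the bundle needs no
    simulation to build), a synthetic 289-cell nucleus, a template AP
    trace and a diffusion grid specification.
    """
    import numpy as np
    from .geometry import generate_lc_cloud
    from .network import (autoinhibition_scenario, dendro_somatic_pair,
                          volume_scenario)

    amp = 33.0   # near the calibrated ~20 Hz step drive
    t = np.arange(0.0, 400.0, 0.1)
    template = -60.0 + 90.0 * np.exp(-0.5 * ((t - 200.0) / 0.7) ** 2) \
        - 12.0 * np.exp(-np.maximum(t - 201.5, 0.0) / 60.0) * (t > 201.5)
    return {
        "seed": seed,
        "dendro_somatic": dendro_somatic_pair(amp, seed=seed),
        "autoinhibition": autoinhibition_scenario(amp, seed=seed + 1),
        "volume": volume_scenario(amp, seed=seed + 2,
                                  duration_ms=9000.0,
                                  onsets_ms=(1000.0, 4000.0)),
        "cloud": generate_lc_cloud(289, seed=seed),
        "ap_template_t_ms": t,
        "ap_template_mv": template,
        "diffusion_grid": {
            "r_um": np.arange(5.0, 51.0, 2.5),
            "t_ms": np.arange(50.0, 1001.0, 25.0),
        },
    }


@dataclass
class RunManifest:
    """Provenance record written beside every CLI run."""

    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)   # filename -> sha256
    software: dict = field(default_factory=dict)

    @classmethod
    def create(cls, config_hash: str, seed: int) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config_hash, seed=seed,
                   software={"lcnet": __version__,
                             "python": platform.python_version()})

    def add_file(self, path):
        p = Path(path)
        self.outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def verify(self, directory) -> bool:
        d = Path(directory)
        return all(
            hashlib.sha256((d / name).read_bytes()).hexdigest() == digest
            for name, digest in self.outputs.items())
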