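"""Run configuration: a flat, validated view of every experiment,
transport and geometry parameter, round-trippable through YAML.

Defaults are the study conditions: 500 nanoparticles in a 3.5 um water
box, 10 labeled, 1 kBq initial activity, 10 eV tracking/production cuts,
1 nm maximum step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .transport import TransportConfig

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    isotope: str = "Ra-223"
    a0_bq: float = 1000.0
    n_np: int = 500
    n_labeled: int = 10
    box_nm: float = 3500.0
    sd_list_nm: tuple[float, ...] = (0.0, 1.0, 10.0, 25.0, 50.0)
    large_sd_phantom_nm: float = 100_000.0
    n_histories: int = 2000
    n_batches: int = 8
    seed: int = 0
    transport: TransportConfig = field(default_factory=TransportConfig)

    def __post_init__(self):
        if self.n_np < 1 or self.n_labeled < 0 or self.n_labeled > self.n_np:
            raise ConfigError("bad nanoparticle counts")
        if self.a0_bq < 0:
            raise ConfigError("a0_bq must be non-negative")
        if any(sd < 0 for sd in self.sd_list_nm):
            raise ConfigError("sd_list_nm: separation distances must be >= 0")
        if self.box_nm <= 0:
            raise ConfigError("box_nm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sd_list_nm"] = list(self.sd_list_nm)
        return d

    def digest(self) -> str:
        """Stable SHA-256 over the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "transport" in data and data["transport"] is not None:
            tdata = dict(data["transport"])
            tknown = {f.name for f in fields(TransportConfig)}
            tunknown = set(tdata) - tknown
            if tunknown:
                raise ConfigError(
                    f"unknown transport config keys: {sorted(tunknown)}")
            try:
                data["transport"] = TransportConfig(**tdata)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"transport: {exc}") from exc
        if "sd_list_nm" in data and data["sd_list_nm"] is not None:
            data["sd_list_nm"] = tuple(float(x) for x in data["sd_list_nm"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; empty file = defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
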