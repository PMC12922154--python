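"""Run configuration: serializable settings shared by the CLI and library.

A :class:`RunConfig` collects everything a run depends on - input paths and
column mapping, amplitude unit, screen geometry, AOIs, bandwidths, grid and
normalization settings, the log base of the divergence, and the seed - and
is written as JSON next to every set of outputs, so any run can be
reproduced bit-for-bit from its resolved config file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io import AOI, AmplitudeUnit, ConfigurationError, ScreenGeometry

__all__ = ["RunConfig", "load_config_file"]


def load_config_file(path) -> dict:
    """Read a JSON or YAML config file into a plain dict (by extension;
    unknown extensions are tried as YAML, which is a JSON superset)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data


@dataclass
class RunConfig:
    input: str | None = None
    column_map: dict = field(
        default_factory=lambda: {"direction": "direction_deg", "amplitude": "amplitude"}
    )
    unit: str = AmplitudeUnit.PX.value
    delimiter: str | None = None
    geometry: dict | None = None
    aois: list = field(default_factory=list)
    nu: float | None = None  # None = plug-in rule
    h: float | None = None  # None = Silverman's rule
    h_theta_deg: float | None = None  # None = circular-variance match to nu
    theta_step_deg: float = 1.0
    r_max: float | None = None
    r_steps: int = 200
    normalization: str = "polar_area"
    log_base: float = 2.0
    seed: int = 0
    outdir: str = "."
    clockwise: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = load_config_file(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def geometry_obj(self) -> ScreenGeometry | None:
        return ScreenGeometry.from_dict(self.geometry) if self.geometry else None

    def aoi_objs(self) -> list[AOI]:
        return [AOI.from_dict(a) for a in self.aois]

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
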