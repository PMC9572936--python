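"""Layered run configuration.

All regulation-driven constants (tolerances, point thresholds, the 1.64
multiplier, linearity and stability limits) live in one auditable place,
with a defaults < file < command-line override order.  Every report records
the configuration hash and master seed, so identical inputs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantify import DilutionModel
from .simulate import NoiseModel

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Complete parameterisation of a screening / validation run."""

    ppm_tol: float = 5.0               # precursor mass accuracy (ppm)
    rt_tol_frac: float = 0.025         # RT tolerance, fraction of expected RT
    frag_tol: float = 0.05             # fragment match tolerance (Th)
    min_fragments: int = 2
    ip_required_authorized: float = 4.0
    ip_required_unauthorized: float = 5.0
    z_factor: float = 1.64             # T / Fm quantile multiplier
    r2_min: float = 0.999              # calibration linearity floor
    yx_tol: float = 0.20               # intercept/slope stability band
    alpha: float = 0.05                # ruggedness t-test level
    dilution: DilutionModel = field(default_factory=DilutionModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol_frac", "frag_tol", "z_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r2_min", "yx_tol", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"]["species_response_scale"] = dict(
            self.noise.species_response_scale
        )
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for report audit trails."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and overrides.

    The YAML file may set any top-level field, plus nested ``dilution`` and
    ``noise`` mappings.  Keyword overrides win over the file.
    """
    data: dict = {}
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update(overrides)
    dilution = data.pop("dilution", None)
    noise = data.pop("noise", None)
    kwargs = dict(data)
    if dilution is not None:
        kwargs["dilution"] = (
            dilution if isinstance(dilution, DilutionModel)
            else DilutionModel(**dilution)
        )
    if noise is not None:
        kwargs["noise"] = (
            noise if isinstance(noise, NoiseModel) else NoiseModel(**noise)
        )
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)
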