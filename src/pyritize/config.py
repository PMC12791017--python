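"""Run configuration: one serializable object binding every knob.

All defaults are visible (``show`` / the CLI ``show-config`` command)
so no silent constants exist; a run's config hash is recorded in every
output artifact for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .params import KineticParams
from .solver import SolverOptions

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    kinetics: KineticParams = field(default_factory=KineticParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    alpha_eps0: float = 70.2  # permil, equilibrium fractionation at 0 C
    alpha_slope: float = 0.17  # permil per deg C
    diffusivity_coeffs: dict = field(
        default_factory=lambda: {"sulfate": [4.88, 0.232], "sulfide": [10.4, 0.273]}
    )
    r_vcdt: float = 0.0441626
    seed: int = 0
    grid_column_map: dict = field(default_factory=dict)  # external-grid schema

    def to_dict(self) -> dict:
        return {
            "kinetics": asdict(self.kinetics),
            "solver": asdict(self.solver),
            "alpha_eps0": self.alpha_eps0,
            "alpha_slope": self.alpha_slope,
            "diffusivity_coeffs": self.diffusivity_coeffs,
            "r_vcdt": self.r_vcdt,
            "seed": self.seed,
            "grid_column_map": self.grid_column_map,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kin = KineticParams(**data.pop("kinetics", {}))
        slv = SolverOptions(**data.pop("solver", {}))
        return cls(kinetics=kin, solver=slv, **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def alpha_coeffs(self) -> tuple[float, float]:
        return (self.alpha_eps0, self.alpha_slope)

    def hash(self) -> str:
        return config_hash(self.to_dict())

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config_hash": self.hash(),
            "seed": self.seed,
            "version": __version__,
        }


def config_hash(config: dict) -> str:
    """Stable sha256 of a canonical-JSON config representation."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
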