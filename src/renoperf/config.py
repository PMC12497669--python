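"""Run configuration: strict YAML schema over the package's settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .kinetic import PARAM_NAMES, SevenCompParams
from .fitting import FitConfig
from .signalmodel import AcquisitionSpec
from .synthetic import GroundTruthCenters

__all__ = ["RunConfig", "NoiseConfig"]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise injection settings: arterial CNR target, AIF inclusion."""

    cnr: float = 150.0
    include_aif: bool = True

    def __post_init__(self) -> None:
        if self.cnr <= 0:
            raise ValueError("cnr must be > 0")


_SECTIONS = {"acquisition", "fit", "noise", "centers", "seed", "log_level"}
_ACQ_KEYS = {"dt", "duration", "baseline_window", "hematocrit"}
_FIT_KEYS = {
    "n_starts",
    "regularization_weight",
    "max_iterations",
    "convergence_tolerance",
    "fixed_params",
}
_NOISE_KEYS = {"cnr", "include_aif"}
_CENTER_KEYS = set(PARAM_NAMES) | {"rel_sd"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable round-trip."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    centers: GroundTruthCenters = field(default_factory=GroundTruthCenters)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "acquisition": asdict(self.acquisition),
            "fit": {
                "n_starts": self.fit.n_starts,
                "regularization_weight": self.fit.regularization_weight,
                "max_iterations": self.fit.max_iterations,
                "convergence_tolerance": self.fit.convergence_tolerance,
                "fixed_params": dict(self.fit.fixed_params),
            },
            "noise": asdict(self.noise),
            "centers": {**self.centers.centers.to_dict(), "rel_sd": self.centers.rel_sd},
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        _check_keys(d, _SECTIONS, "top level")
        acq_d = dict(d.get("acquisition", {}))
        _check_keys(acq_d, _ACQ_KEYS, "acquisition")
        fit_d = dict(d.get("fit", {}))
        _check_keys(fit_d, _FIT_KEYS, "fit")
        noise_d = dict(d.get("noise", {}))
        _check_keys(noise_d, _NOISE_KEYS, "noise")
        cen_d = dict(d.get("centers", {}))
        _check_keys(cen_d, _CENTER_KEYS, "centers")
        rel_sd = cen_d.pop("rel_sd", 0.20)
        defaults = GroundTruthCenters().centers.to_dict()
        centers = GroundTruthCenters(
            centers=SevenCompParams(**{**defaults, **cen_d}), rel_sd=rel_sd
        )
        return RunConfig(
            acquisition=AcquisitionSpec(**acq_d),
            fit=FitConfig(**fit_d),
            noise=NoiseConfig(**noise_d),
            centers=centers,
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return RunConfig.from_dict(d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
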