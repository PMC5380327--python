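"""JSON run configuration with strict schema validation.

A :class:`RunConfig` ties the pipeline stages together: a mandatory
seed, the simulation block (construct, pulling protocol, noise model),
the analysis thresholds and the kinetics settings.  Unknown keys are
rejected so typos fail loudly.  All randomness of a run derives from
the single seed through per-stage spawned streams.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .curves import AnalysisSettings
from .models import BellParams
from .presets import PRESETS
from .simulate import ConstructSpec, DomainSpec, NoiseModel, PullingProtocol

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BellConfig(_Strict):
    k_u0: float = Field(gt=0)
    x_u: float = Field(gt=0)
    temperature: float = Field(default=298.0, gt=0)

    def build(self) -> BellParams:
        return BellParams(self.k_u0, self.x_u, self.temperature)


class DomainConfig(_Strict):
    name: str
    n_residues: int = Field(ge=1)
    folded_NC: float = Field(ge=0)
    unfolded_contour: float = Field(gt=0)
    kinetics: BellConfig

    def build(self) -> DomainSpec:
        return DomainSpec(
            self.name, self.n_residues, self.folded_NC,
            self.unfolded_contour, self.kinetics.build(),
        )


class ConstructConfig(_Strict):
    preset: str | None = None
    domains: list[DomainConfig] | None = None
    linker_contour: float = Field(default=15.0, ge=0)
    persistence_length: float = Field(default=0.3, gt=0)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.preset is None) == (self.domains is None):
            raise ValueError("specify exactly one of 'preset' or 'domains'")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}"
            )
        return self

    def build(self) -> ConstructSpec:
        if self.preset is not None:
            base = PRESETS[self.preset]()
            return ConstructSpec(
                base.domains, self.linker_contour, self.persistence_length
            )
        return ConstructSpec(
            tuple(d.build() for d in self.domains),
            self.linker_contour,
            self.persistence_length,
        )


class ProtocolConfig(_Strict):
    speed: float = Field(default=1000.0, gt=0)
    ramp_length: float = Field(default=1000.0, gt=0)
    sample_interval: float | None = Field(default=None, gt=0)
    cantilever_k_N_m: float = Field(default=0.15, gt=0)
    temperature: float = Field(default=298.0, gt=0)

    def build(self) -> PullingProtocol:
        return PullingProtocol(
            speed=self.speed,
            ramp_length=self.ramp_length,
            sample_interval=self.sample_interval,
            cantilever_k=self.cantilever_k_N_m * 1000.0,
            temperature=self.temperature,
        )


class NoiseConfig(_Strict):
    force_noise_sd: float = Field(default=8.0, ge=0)
    baseline_drift: float = Field(default=0.0, ge=0)
    adhesion_amplitude: float = Field(default=120.0, ge=0)
    adhesion_range: float = Field(default=20.0, ge=0)
    tether_kinetics: BellConfig = Field(
        default_factory=lambda: BellConfig(k_u0=1e-6, x_u=0.1)
    )
    pickup_probability: float = Field(default=0.03, ge=0, le=1)
    gfp_misfold_probability: float = Field(default=0.5, ge=0, le=1)

    def build(self) -> NoiseModel:
        return NoiseModel(
            force_noise_sd=self.force_noise_sd,
            baseline_drift=self.baseline_drift,
            adhesion_amplitude=self.adhesion_amplitude,
            adhesion_range=self.adhesion_range,
            tether_kinetics=self.tether_kinetics.build(),
            pickup_probability=self.pickup_probability,
            gfp_misfold_probability=self.gfp_misfold_probability,
        )


class SimulationConfig(_Strict):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    # "construct" in JSON; suffixed here to avoid pydantic's method name
    construct_spec: ConstructConfig = Field(
        default_factory=lambda: ConstructConfig(preset="rii8"),
        alias="construct",
    )
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    n_ramps: int = Field(default=2000, ge=1)


class AnalysisConfig(_Strict):
    min_force: float = Field(default=50.0, gt=0)
    min_drop: float = Field(default=50.0, gt=0)
    min_separation: float = Field(default=10.0, gt=0)
    min_peaks: int = Field(default=5, ge=1)
    tail_fraction: float = Field(default=0.1, gt=0, lt=1)
    min_window_points: int = Field(default=8, ge=3)
    gfp_band: tuple[float, float] = (60.0, 90.0)
    gfp_force_max: float = Field(default=150.0, gt=0)
    adhesion_cutoff: float = Field(default=25.0, ge=0)

    def build(self) -> AnalysisSettings:
        return AnalysisSettings(
            min_force=self.min_force,
            min_drop=self.min_drop,
            min_separation=self.min_separation,
            min_peaks=self.min_peaks,
            tail_fraction=self.tail_fraction,
            min_window_points=self.min_window_points,
            gfp_band=self.gfp_band,
            gfp_force_max=self.gfp_force_max,
            adhesion_cutoff=self.adhesion_cutoff,
        )


class KineticsConfig(_Strict):
    estimator: str = Field(default="mode", pattern="^(mean|mode)$")
    label: str = "RII"


class RunConfig(_Strict):
    seed: int
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonicalised configuration."""
    canon = json.dumps(config.model_dump(by_alias=True), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
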