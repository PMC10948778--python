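"""Structured run configuration with schema validation.

A run config is a YAML document with blocks for the photophysical model,
beam geometry, pulse scheme, scenario/noise settings, and fit
specification. Validation (via pydantic, unknown keys rejected) happens
before any computation; rates are given in s⁻¹ to match the library API,
while result files report µs⁻¹.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .constants import (
    K10_DEFAULT,
    KOX_TYR,
    KRED0_TYR,
    KT_DEFAULT,
    SIGMA_TYR_CM2,
)
from .forward import BeamProfile, PulseScheme
from .fitting import FitSpec
from .photophysics import RateConstants, StateModel
from .synthetic import NoiseModel

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    topology: Literal["two_state", "four_state"] = "two_state"
    k10_per_s: float = K10_DEFAULT
    k_isc_per_s: float = 0.0
    k_t_per_s: float = KT_DEFAULT
    k_ox_per_s: float = KOX_TYR
    k_red_per_s: float = KRED0_TYR
    sigma_cm2: float = SIGMA_TYR_CM2
    kox_eff_per_s: Optional[float] = None

    def to_rates(self) -> RateConstants:
        return RateConstants(
            k10=self.k10_per_s,
            k_isc=self.k_isc_per_s,
            k_t=self.k_t_per_s,
            k_ox=self.k_ox_per_s,
            k_red=self.k_red_per_s,
            sigma=self.sigma_cm2,
        )

    def to_model(self) -> StateModel:
        return StateModel(
            topology=self.topology, rates=self.to_rates(),
            kox_eff=self.kox_eff_per_s,
        )


class BeamBlock(_Strict):
    omega0_nm: float = 400.0
    z0_nm: Optional[float] = None
    cef_omega_nm: Optional[float] = None
    cef_z_nm: Optional[float] = None
    geometry: Literal["radial_2d", "gaussian_3d", "top_hat"] = "radial_2d"

    def to_beam(self) -> BeamProfile:
        return BeamProfile(
            omega0=self.omega0_nm, z0=self.z0_nm, cef_omega=self.cef_omega_nm,
            cef_z=self.cef_z_nm, geometry=self.geometry,
        )


class SchemeBlock(_Strict):
    eta: float = 0.01
    w0_s: float = 5e-8
    w_min_s: float = 1e-7
    w_max_s: float = 1e-2
    n_w: int = Field(default=30, ge=2)

    def to_scheme(self) -> PulseScheme:
        return PulseScheme(w=self.w_max_s, eta=self.eta, M=1, w0=self.w0_s)


class ScenarioBlock(_Strict):
    name: Literal["fig2a_intensity_series", "fig2b_naac_titration", "fig3a_cam"]
    counts_at_unity: float = 1e5
    dark_rate: float = 100.0
    bleach_per_step: float = 0.002
    poisson: bool = True

    def to_noise(self, seed: int = 0) -> NoiseModel:
        return NoiseModel(
            counts_at_unity=self.counts_at_unity,
            dark_rate=self.dark_rate,
            bleach_per_step=self.bleach_per_step,
            seed=seed,
            poisson=self.poisson,
        )


class FitBlock(_Strict):
    k_ox_role: Literal["global", "per_curve", "fixed"] = "global"
    k_red_role: Literal["global", "per_curve", "fixed"] = "per_curve"
    k_ox_bounds_per_s: tuple[float, float] = (1e2, 1e10)
    k_red_bounds_per_s: tuple[float, float] = (1e0, 1e7)
    k_ox_init_per_s: float = 1e7
    k_red_init_per_s: float = 1e3
    weighting: Literal["sem", "uniform"] = "sem"
    multistart: int = Field(default=5, ge=1)

    def to_spec(self, beam: BeamProfile, sigma: float, k10: float,
                seed: int = 0) -> FitSpec:
        return FitSpec(
            roles={"k_ox": self.k_ox_role, "k_red": self.k_red_role},
            bounds={
                "k_ox": tuple(self.k_ox_bounds_per_s),
                "k_red": tuple(self.k_red_bounds_per_s),
            },
            initial={"k_ox": self.k_ox_init_per_s, "k_red": self.k_red_init_per_s},
            sigma=sigma, k10=k10, weighting=self.weighting,
            multistart=self.multistart, seed=seed, beam=beam,
        )


class RunConfig(_Strict):
    model: ModelBlock = Field(default_factory=ModelBlock)
    beam: BeamBlock = Field(default_factory=BeamBlock)
    scheme: SchemeBlock = Field(default_factory=SchemeBlock)
    scenario: Optional[ScenarioBlock] = None
    fit: FitBlock = Field(default_factory=FitBlock)
    seed: int = 0
    outdir: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the validated configuration (provenance)."""
    canon = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
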