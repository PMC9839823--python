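"""Validated configuration schema (YAML/TOML) for 1D and 2D runs."""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from rdgrow.kinetics import GrowthLaw, KineticsSpec
from rdgrow.sim1d import EpochSchedule, InitialConditionSpec, Sim1DConfig
from rdgrow.sim2d import DomainSpec2D, Sim2DConfig

__all__ = [
    "SimulationConfig",
    "load_config",
    "dump_config",
    "register_growth_rate",
]

# registry for named custom growth rates (used by presets whose S has no
# closed form in the schema enum)
_GROWTH_RATES: dict[str, tuple[Callable, Optional[Callable]]] = {}


def register_growth_rate(name: str, rate: Callable, grad: Optional[Callable] = None):
    _GROWTH_RATES[name] = (rate, grad)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    name: Literal[
        "schnakenberg", "gierer_meinhardt", "fitzhugh_nagumo", "logistic", "bistable"
    ]
    params: dict[str, float] = Field(default_factory=dict)

    def build(self) -> KineticsSpec:
        n = 1 if self.name in ("logistic", "bistable") else 2
        return KineticsSpec(self.name, dict(self.params), n_species=n)


class GrowthConfig(_Strict):
    form: Literal[
        "constant",
        "linear",
        "thresholded_tanh",
        "quadratic_ratio",
        "difference",
        "registered",
    ]
    params: dict[str, float] = Field(default_factory=dict)
    species: int = 0
    use_abs: bool = False
    rate_name: Optional[str] = None  # for form="registered"

    @model_validator(mode="after")
    def _check(self):
        if self.form == "registered":
            if self.rate_name is None:
                raise ValueError("registered growth law requires rate_name")
            if self.rate_name not in _GROWTH_RATES:
                raise ValueError(f"unknown registered growth rate {self.rate_name!r}")
        return self

    def build(self) -> GrowthLaw:
        if self.form == "registered":
            rate, grad = _GROWTH_RATES[self.rate_name]
            return GrowthLaw(
                "custom",
                dict(self.params),
                rate=lambda t, u, _r=rate, _p=self.params: _r(t, u, _p),
                grad=(lambda t, u, _g=grad, _p=self.params: _g(t, u, _p)) if grad else None,
                species=self.species,
            )
        return GrowthLaw(
            self.form, dict(self.params), species=self.species, use_abs=self.use_abs
        )


class ICConfig(_Strict):
    mode: Literal["noisy_equilibrium", "tanh_front"] = "noisy_equilibrium"
    noise_variance: float = 1e-2
    seed: int  # mandatory: every run is seeded

    def build(self) -> InitialConditionSpec:
        return InitialConditionSpec(
            mode=self.mode, noise_variance=self.noise_variance, seed=self.seed
        )


class EpochConfig(_Strict):
    epoch_length: Optional[float] = None
    trigger_ratio: float = 2.0
    interpolation: Literal["pchip", "cubic", "linear"] = "pchip"

    def build(self) -> EpochSchedule:
        return EpochSchedule(self.epoch_length, self.trigger_ratio, self.interpolation)


class DomainConfig(_Strict):
    # 1D
    L: Optional[float] = None
    n_nodes: int = 400
    # 2D
    shape: Optional[Literal["disk", "dumbbell", "star", "polygon"]] = None
    h: float = 0.1
    radius: float = 3.0
    lobes: int = 5
    amplitude: float = 0.3
    vertices: Optional[list] = None

    def build_2d(self) -> DomainSpec2D:
        return DomainSpec2D(
            shape=self.shape,
            h=self.h,
            radius=self.radius,
            lobes=self.lobes,
            amplitude=self.amplitude,
            vertices=self.vertices,
        )


class ToleranceConfig(_Strict):
    rtol: float = 1e-11  # 1D time-integration tolerances
    atol: float = 1e-11
    newton_tol: float = 1e-9  # 2D implicit-step tolerance
    dt_init: float = 0.1
    dt_max: float = 1.0
    cfl: float = 0.2


class SimulationConfig(_Strict):
    """Top-level run description; embeds every resolved default and the seed."""

    dimensionality: Literal[1, 2]
    kinetics: KineticsConfig
    growth: GrowthConfig
    D: list[float]
    domain: DomainConfig
    ic: ICConfig
    t_final: float
    tolerances: ToleranceConfig = Field(default_factory=ToleranceConfig)
    epochs: EpochConfig = Field(default_factory=EpochConfig)
    snapshot_times: Optional[list[float]] = None
    n_snapshots: int = 21
    stop_length_max: Optional[float] = None
    stop_length_min: Optional[float] = None
    fidelity: Literal["paper_exact", "paper_approximate", "user"] = "user"
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        m = 1 if self.kinetics.name in ("logistic", "bistable") else 2
        if len(self.D) != m:
            raise ValueError(f"D must have {m} entries for {self.kinetics.name}")
        if self.dimensionality == 1 and self.domain.L is None:
            raise ValueError("1D runs require domain.L")
        if self.dimensionality == 2 and self.domain.shape is None:
            raise ValueError("2D runs require domain.shape")
        return self

    def build_1d(self) -> Sim1DConfig:
        if self.dimensionality != 1:
            raise ValueError("not a 1D configuration")
        return Sim1DConfig(
            kinetics=self.kinetics.build(),
            growth=self.growth.build(),
            D=list(self.D),
            L=self.domain.L,
            n_nodes=self.domain.n_nodes,
            t_final=self.t_final,
            ic=self.ic.build(),
            epochs=self.epochs.build(),
            snapshot_times=self.snapshot_times,
            n_snapshots=self.n_snapshots,
            rtol=self.tolerances.rtol,
            atol=self.tolerances.atol,
            stop_length_max=self.stop_length_max,
            stop_length_min=self.stop_length_min,
        )

    def build_2d(self) -> Sim2DConfig:
        if self.dimensionality != 2:
            raise ValueError("not a 2D configuration")
        return Sim2DConfig(
            domain=self.domain.build_2d(),
            kinetics=self.kinetics.build(),
            growth=self.growth.build(),
            D=list(self.D),
            t_final=self.t_final,
            ic_mode="noisy_equilibrium",
            noise_variance=self.ic.noise_variance,
            seed=self.ic.seed,
            dt_init=self.tolerances.dt_init,
            dt_max=self.tolerances.dt_max,
            cfl=self.tolerances.cfl,
            newton_tol=self.tolerances.newton_tol,
            n_snapshots=self.n_snapshots,
            snapshot_times=self.snapshot_times,
        )


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML (or TOML) configuration document."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    return SimulationConfig.model_validate(data)


def dump_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=True)
    )
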