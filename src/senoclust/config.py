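"""Structured simulation configuration with YAML round-tripping.

Every number printed in the model description (the J matrix, temperature,
neighborhood order, field rates, cycle statistics, target volumes and
asperities, grid size) is a named default here, never hard-coded in the
simulation loop. The unmodified defaults reproduce the published full-scale
scenario (200 x 200 x 50 grid, 48 body domains, 20 tumor cells); the
``reduced()`` constructor gives the scaled-down scenario used by the test
suite, and ``plate()`` a senescent-free proliferation scenario for
division statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional

import yaml

from .cycle import CycleParams
from .field import ScalarField
from .init_lattice import InitConfig
from .lattice import DEFAULT_J, EnergyParams, j_matrix


def _default_j_dict() -> dict:
    return {f"{a}-{b}": v for (a, b), v in DEFAULT_J.items()}


@dataclass
class GridConfig:
    lx: int = 200
    ly: int = 200
    lz: int = 50
    spacing: float = 1.0  # um per lattice unit

    @property
    def shape(self):
        return (self.lx, self.ly, self.lz)


@dataclass
class EnergyConfig:
    j: dict = dc_field(default_factory=_default_j_dict)
    lambda_v: float = 2.0
    lambda_p: float = 0.1
    mu: float = -350.0
    temperature: float = 100.0
    neighborhood_order: int = 2

    def to_params(self) -> EnergyParams:
        pairs = {tuple(k.split("-")): v for k, v in self.j.items()}
        return EnergyParams(
            J=j_matrix(pairs),
            lambda_V=self.lambda_v,
            lambda_P=self.lambda_p,
            mu=self.mu,
            T=self.temperature,
            neighborhood_order=self.neighborhood_order,
        )


@dataclass
class FieldConfig:
    enabled: bool = True
    p: float = 2.0  # production rate at the core, um^-3 s^-1
    d: float = 0.02  # decay rate, s^-1
    diffusion: float = 2.0  # um^2 s^-1
    burn_in: float = 300.0  # field-only pre-equilibration, s

    def to_field(self, shape, spacing: float) -> ScalarField:
        return ScalarField(shape, p=self.p, d=self.d, D=self.diffusion, spacing=spacing)


@dataclass
class CycleConfig:
    tau_r_mean: float = 5000.0
    tau_r_sd: float = 1000.0
    rounding_amplitude: float = 110.0
    rounding_tau_tt: float = 100.0
    rounding_tau_tm: float = 500.0
    #: the simulation default is the weakening variant (substrate release
    #: during mitotic rounding); see docs/methods.md
    rounding_sign: str = "weakening"
    mu_rounding_boost: float = 1.0

    def to_params(self) -> CycleParams:
        return CycleParams(
            tau_r_mean=self.tau_r_mean,
            tau_r_sd=self.tau_r_sd,
            rounding_amplitude=self.rounding_amplitude,
            rounding_tau_tt=self.rounding_tau_tt,
            rounding_tau_tm=self.rounding_tau_tm,
            rounding_sign=self.rounding_sign,
            mu_rounding_boost=self.mu_rounding_boost,
        )


@dataclass
class InitSection:
    layout: str = "senescent"
    n_body: int = 48
    n_tumor: int = 20
    core_volume: float = 1800.0
    body_volume: float = 600.0
    tumor_volume: float = 400.0
    asperity_core: float = 0.8
    asperity_body: float = 0.8
    asperity_tumor: float = 1.4
    body_thickness: Optional[int] = None

    def to_init(self, grid: GridConfig) -> InitConfig:
        return InitConfig(
            grid=grid.shape,
            spacing=grid.spacing,
            layout=self.layout,
            n_body=self.n_body,
            n_tumor=self.n_tumor,
            core_volume=self.core_volume,
            body_volume=self.body_volume,
            tumor_volume=self.tumor_volume,
            asperity_core=self.asperity_core,
            asperity_body=self.asperity_body,
            asperity_tumor=self.asperity_tumor,
            body_thickness=self.body_thickness,
        )


@dataclass
class RunConfig:
    n_mcs: int = 8800
    seed: int = 0
    track_every: int = 20  # MCS between centroid log rows
    metrics_every: int = 200
    snapshot_every: int = 0  # 0 = no snapshots
    #: stop early once this many inter-division intervals are available from
    #: fully matured cohorts (clocks started >= interval_maturity seconds
    #: before the stop time, so no censoring of long cycles biases the mean)
    stop_after_intervals: Optional[int] = None
    #: cohort maturity horizon, s (~ mean + 3 sd of the cycle length)
    interval_maturity: float = 8000.0


@dataclass
class SimConfig:
    grid: GridConfig = dc_field(default_factory=GridConfig)
    energy: EnergyConfig = dc_field(default_factory=EnergyConfig)
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    cycle: CycleConfig = dc_field(default_factory=CycleConfig)
    init: InitSection = dc_field(default_factory=InitSection)
    run: RunConfig = dc_field(default_factory=RunConfig)

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        return cls(
            grid=build(GridConfig, d.get("grid", {})),
            energy=build(EnergyConfig, d.get("energy", {})),
            field=build(FieldConfig, d.get("field", {})),
            cycle=build(CycleConfig, d.get("cycle", {})),
            init=build(InitSection, d.get("init", {})),
            run=build(RunConfig, d.get("run", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # ---------------------------------------------------------- scenarios
    @classmethod
    def reduced(cls, seed: int = 0, n_mcs: int = 3000) -> "SimConfig":
        """Scaled-down cluster scenario: 60x60x20 grid, 12 body wedges,
        6 tumor cells."""
        cfg = cls()
        cfg.grid = GridConfig(lx=60, ly=60, lz=20)
        cfg.init.n_body = 12
        cfg.init.n_tumor = 6
        cfg.run = RunConfig(n_mcs=n_mcs, seed=seed)
        return cfg

    @classmethod
    def plate(
        cls,
        seed: int = 0,
        n_tumor: int = 64,
        grid=(96, 96, 12),
        n_mcs: int = 25000,
        stop_after_intervals: Optional[int] = None,
    ) -> "SimConfig":
        """Senescent-free proliferation scenario for division statistics."""
        cfg = cls()
        cfg.grid = GridConfig(lx=grid[0], ly=grid[1], lz=grid[2])
        cfg.init = InitSection(layout="plate", n_body=0, n_tumor=n_tumor)
        cfg.field = FieldConfig(enabled=False)
        cfg.run = RunConfig(
            n_mcs=n_mcs,
            seed=seed,
            track_every=100,
            metrics_every=0,
            stop_after_intervals=stop_after_intervals,
        )
        return cfg
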