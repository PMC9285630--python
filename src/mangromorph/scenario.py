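"""Computational domains, tidal/SLR forcing, and the scenario factorial.

Three idealized open-coast profiles (micro-, meso- and macro-tidal) share
an 18 km cross-shore span but differ in slope and in seaward/landward
end elevations; forcing is a single semidiurnal (M2) constituent plus an
optional sea-level-rise ramp at the seaward boundary, optional small
boundary waves, and a constant boundary suspended sediment concentration.
The full study matrix is 3 tidal systems x 3 sediment supplies x 2 wave
settings x 4 sea-level cases = 72 scenarios.

Coordinate convention: x increases landward; cell 0 touches the seaward
open boundary; bed elevations are relative to initial mean sea level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .vegetation import VegConstants

__all__ = [
    "Grid1D",
    "TidalForcing",
    "SLRScenario",
    "MudConstants",
    "NumericsConfig",
    "ScenarioConfig",
    "TIDAL_SYSTEMS",
    "build_initial_bathymetry",
    "boundary_water_level",
    "enumerate_scenarios",
    "make_scenario",
    "scaled_scenario",
]

SECONDS_PER_YEAR = 365.25 * 24 * 3600.0
M2_PERIOD_HOURS = 12.42

#: tidal system -> (nominal slope, seaward elev [m], landward elev [m], tidal range [m])
TIDAL_SYSTEMS: dict[str, tuple[float, float, float, float]] = {
    "micro": (0.00025, -2.5, 2.0, 1.0),
    "meso": (0.0005, -5.0, 4.0, 3.0),
    "macro": (0.001, -10.0, 8.0, 5.0),
}

#: SLR scenario name -> total rise [m] over the 100-year horizon
SLR_RISES: dict[str, float] = {"none": 0.0, "slow": 0.29, "medium": 0.55, "fast": 1.10}


@dataclass(frozen=True)
class Grid1D:
    n_cells: int
    cell_size: float  # m
    bed_elevation: np.ndarray  # m, per cell, relative to initial MSL

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("grid needs at least 2 cells")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if len(self.bed_elevation) != self.n_cells:
            raise ValueError("bed_elevation length mismatch")

    @property
    def cell_center_x(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.cell_size

    @property
    def length(self) -> float:
        return self.n_cells * self.cell_size


def build_initial_bathymetry(tidal_system: str, n_cells: int = 360,
                             cell_size: float = 50.0) -> Grid1D:
    """Linear initial profile for one of the three tidal systems.

    The bed runs from the system's seaward end elevation at the seaward
    edge (x = 0) to its landward end elevation at the landward edge
    (x = domain length); cell values are sampled at cell centers.
    """
    try:
        slope, z_sea, z_land, _ = TIDAL_SYSTEMS[tidal_system]
    except KeyError:
        raise ValueError(
            f"unknown tidal system {tidal_system!r}; expected one of "
            f"{sorted(TIDAL_SYSTEMS)}"
        ) from None
    length = n_cells * cell_size
    x = (np.arange(n_cells) + 0.5) * cell_size
    bed = z_sea + (z_land - z_sea) * x / length
    return Grid1D(n_cells=n_cells, cell_size=cell_size, bed_elevation=bed)


@dataclass(frozen=True)
class SLRScenario:
    """Sea-level-rise ramp applied after the spin-up phase.

    ``trajectory_shape``: "quadratic" (accelerating, zero initial rate,
    emulating RCP-style acceleration) or "linear".
    """

    name: str = "none"
    total_rise: float = 0.0   # m over the horizon
    horizon: float = 100.0    # years
    trajectory_shape: str = "quadratic"

    @classmethod
    def from_name(cls, name: str, shape: str = "quadratic") -> "SLRScenario":
        if name not in SLR_RISES:
            raise ValueError(f"unknown SLR scenario {name!r}")
        return cls(name=name, total_rise=SLR_RISES[name], horizon=100.0,
                   trajectory_shape=shape)

    def offset(self, years_since_start: float) -> float:
        """Mean-level offset [m] at a time (years) after SLR switch-on."""
        t = min(max(years_since_start, 0.0), self.horizon)
        frac = t / self.horizon
        if self.trajectory_shape == "quadratic":
            return self.total_rise * frac * frac
        if self.trajectory_shape == "linear":
            return self.total_rise * frac
        raise ValueError(f"unknown trajectory shape {self.trajectory_shape!r}")


@dataclass(frozen=True)
class TidalForcing:
    tidal_range: float                 # m
    tidal_period: float = M2_PERIOD_HOURS * 3600.0  # s

    def level(self, t: float, mean_offset: float = 0.0) -> float:
        """Boundary water level [m] at hydrodynamic time t [s]."""
        return mean_offset + 0.5 * self.tidal_range * math.sin(
            2.0 * math.pi * t / self.tidal_period
        )


def boundary_water_level(t_hydro: float, tide: TidalForcing, slr: SLRScenario,
                         morfac: float = 30.0,
                         years_spinup: float = 150.0) -> float:
    """Seaward boundary level [m]: M2 sinusoid on top of the SLR offset.

    ``t_hydro`` is hydrodynamic time [s]; morphological time is
    t_hydro * morfac, and the SLR ramp starts at the end of spin-up
    (morphological years).
    """
    t_morph_years = t_hydro * morfac / SECONDS_PER_YEAR
    offset = slr.offset(t_morph_years - years_spinup)
    return tide.level(t_hydro, mean_offset=offset)


@dataclass(frozen=True)
class MudConstants:
    """Cohesive-sediment exchange constants (Partheniades-Krone)."""

    tau_cr_erosion: float = 0.2       # N/m^2
    tau_cr_deposition: float = 1000.0  # N/m^2 (deposition effectively always on)
    erosion_rate: float = 1e-4        # kg/m^2/s
    settling_velocity: float = 5e-4   # m/s
    dry_bulk_density: float = 500.0   # kg/m^3
    diffusivity: float = 1.0          # m^2/s


@dataclass(frozen=True)
class NumericsConfig:
    """Solver knobs for the hydrodynamic/transport schemes."""

    dt_hydro: float = 30.0       # s (0.5 min)
    theta: float = 1.0           # semi-implicit weight
    drying_threshold: float = 0.05  # m; also the "inundated" depth for hydroperiod
    rho_water: float = 1000.0    # kg/m^3
    include_advection: bool = True
    shear_partition: str = "total"   # or "bed"
    wave_update_every: int = 10  # hydro steps between wave-field refreshes
    sample_every: int = 10       # hydro steps between statistic samples
    breaker_gamma: float = 0.73
    roller_beta: float = 0.10
    shear_combine: str = "linear"    # or "mean" (Soulsby mean-stress)


@dataclass
class ScenarioConfig:
    """Complete, self-contained description of one simulation."""

    name: str
    tidal_system: str
    n_cells: int = 360
    cell_size: float = 50.0
    ssc_boundary: float = 0.030       # kg/m^3 (30 mg/L)
    waves_on: bool = False
    wave_height_boundary: float = 0.05  # m
    wave_period: float = 1.0          # s
    slr_name: str = "none"
    slr_shape: str = "quadratic"
    slr_total_rise: float | None = None   # m; overrides the named 100-yr rise
    slr_horizon: float | None = None      # years; defaults to years_slr
    years_spinup: float = 150.0
    years_slr: float = 100.0
    morfac: float = 30.0
    seed: int = 0
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    mud: MudConstants = field(default_factory=MudConstants)
    vegetation: VegConstants = field(default_factory=VegConstants)
    vegetation_on: bool = True

    def __post_init__(self):
        if self.tidal_system not in TIDAL_SYSTEMS:
            raise ValueError(f"unknown tidal system {self.tidal_system!r}")
        if self.morfac < 1:
            raise ValueError("morfac must be >= 1")
        if self.numerics.dt_hydro <= 0:
            raise ValueError("dt_hydro must be positive")

    @property
    def tidal_range(self) -> float:
        return TIDAL_SYSTEMS[self.tidal_system][3]

    @property
    def years_total(self) -> float:
        return self.years_spinup + self.years_slr

    def grid(self) -> Grid1D:
        return build_initial_bathymetry(self.tidal_system, self.n_cells,
                                        self.cell_size)

    def tide(self) -> TidalForcing:
        return TidalForcing(tidal_range=self.tidal_range)

    def slr(self) -> SLRScenario:
        if self.slr_total_rise is None:
            return SLRScenario.from_name(self.slr_name, self.slr_shape)
        horizon = self.slr_horizon if self.slr_horizon is not None else self.years_slr
        return SLRScenario(name=self.slr_name, total_rise=self.slr_total_rise,
                           horizon=horizon, trajectory_shape=self.slr_shape)

    # -- flat key-value (YAML) round trip ----------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["vegetation"]["p_window"] = list(self.vegetation.p_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["numerics"] = NumericsConfig(**d.get("numerics", {}))
        d["mud"] = MudConstants(**d.get("mud", {}))
        veg = dict(d.get("vegetation", {}))
        if "p_window" in veg:
            veg["p_window"] = tuple(veg["p_window"])
        d["vegetation"] = VegConstants(**veg)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_scenario(tidal_system: str, ssc_mg_l: float, waves_on: bool,
                  slr_name: str, **overrides) -> ScenarioConfig:
    """Build one named scenario of the study matrix."""
    name = "{}_ssc{:02.0f}_{}_{}".format(
        tidal_system, ssc_mg_l, "waves" if waves_on else "nowaves", slr_name
    )
    return ScenarioConfig(
        name=name,
        tidal_system=tidal_system,
        ssc_boundary=ssc_mg_l / 1000.0,
        waves_on=waves_on,
        slr_name=slr_name,
        **overrides,
    )


def enumerate_scenarios(**overrides) -> list[ScenarioConfig]:
    """The full 72-member factorial: 3 tidal systems x 3 boundary SSC
    (10/30/50 mg/L) x 2 wave settings x 4 sea-level cases."""
    out = []
    for system in TIDAL_SYSTEMS:
        for ssc in (10.0, 30.0, 50.0):
            for waves in (False, True):
                for slr in SLR_RISES:
                    out.append(make_scenario(system, ssc, waves, slr, **overrides))
    return out


def scaled_scenario(tidal_system: str, ssc_mg_l: float = 30.0,
                    waves_on: bool = False, slr_name: str = "none",
                    n_cells: int = 90, years_spinup: float = 20.0,
                    years_slr: float = 0.0, slr_total_rise: float | None = None,
                    slr_shape: str = "linear", dt_hydro: float = 120.0,
                    **overrides) -> ScenarioConfig:
    """Reduced-scale scenario for tests and desk-scale studies.

    Keeps the 18 km span and end elevations of the full profiles on a
    coarser grid (default 90 cells of 200 m), a larger hydrodynamic step
    (2 min; the semi-implicit scheme remains stable), advection off on
    the coarse grid, and shorter morphological durations.
    ``slr_total_rise`` overrides the named scenario's 100-yr rise so
    rate-equivalent short ramps can be prescribed (horizon = years_slr).
    """
    cell_size = 18000.0 / n_cells
    numerics = overrides.pop(
        "numerics",
        NumericsConfig(dt_hydro=dt_hydro, include_advection=False),
    )
    return make_scenario(
        tidal_system, ssc_mg_l, waves_on, slr_name,
        n_cells=n_cells, cell_size=cell_size,
        years_spinup=years_spinup, years_slr=years_slr,
        slr_shape=slr_shape, numerics=numerics,
        slr_total_rise=slr_total_rise, **overrides,
    )
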