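"""Coupling scheduler: continuous hydro-morphodynamics, monthly ecology.

The morphological clock runs MORFAC times faster than the hydrodynamic
clock. Each ecological step (one morphological month) integrates tides,
waves and mud transport with the vegetation-derived roughness frozen,
then updates the forest: colonization at the first step of each year,
growth every step, mortality at the twelfth; the refreshed roughness
feeds the next month. The sea-level ramp switches on after the spin-up
phase (morphological years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydro import (HydroState, RoughnessField, bed_shear_current,
                    relative_hydroperiod, shear_percentile, step_hydro)
from .mud import SedState, step_transport
from .scenario import SECONDS_PER_YEAR, ScenarioConfig
from .vegetation import (CohortCell, colonize, competition, evaluate_mortality,
                         fitness, grow_cohort, roughness_from_vegetation,
                         stagnation_flag)
from .waves import WaveField, combine_shear, solve_wave_field

__all__ = ["RunArchive", "run_scenario", "resume", "ecological_statistics"]


@dataclass
class RunArchive:
    """Time-stamped history of one simulation plus the resume checkpoint.

    Gridded annual snapshots (bed, vegetation summaries) drive the
    metrics module; the checkpoint carries the exact end-of-run state so
    a resumed run continues bit-identically.
    """

    config: ScenarioConfig
    years: list = field(default_factory=list)          # morphological years
    bed: list = field(default_factory=list)            # (n,) per snapshot
    veg_count: list = field(default_factory=list)      # live stems per cell
    veg_max_diameter: list = field(default_factory=list)
    hydroperiod: list = field(default_factory=list)    # last-month P per cell
    mean_offset: list = field(default_factory=list)    # SLR offset [m]
    mass_balance: list = field(default_factory=list)   # per-year ledger dicts
    cohort_rows: list = field(default_factory=list)    # (year, cell, D, count, stress)
    checkpoint: dict | None = None
    failed: bool = False
    failure_info: str | None = None

    # -- convenience accessors ---------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.config.grid().cell_center_x

    def bed_array(self) -> np.ndarray:
        return np.asarray(self.bed)

    def veg_count_array(self) -> np.ndarray:
        return np.asarray(self.veg_count)

    def years_array(self) -> np.ndarray:
        return np.asarray(self.years, dtype=float)

    def cohort_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cohort_rows,
            columns=["year", "cell", "diameter", "height", "count",
                     "stress_years", "stagnant"],
        )

    def high_water_level(self, year: float) -> float:
        """HWL = SLR offset at that year + tidal amplitude."""
        idx = int(np.argmin(np.abs(self.years_array() - year)))
        return self.mean_offset[idx] + 0.5 * self.config.tidal_range

    def snapshot_at(self, year: float) -> int:
        yrs = self.years_array()
        idx = int(np.argmin(np.abs(yrs - year)))
        return idx


def ecological_statistics(depth_samples: np.ndarray, tau_samples: np.ndarray,
                          bed: np.ndarray, low_water: float,
                          drying_threshold: float = 0.05):
    """Per-cell monthly statistics for the vegetation model.

    Returns (P, stagnant flags); ``tau_samples`` is returned untouched as
    the running series for the annual 90th-percentile stress (kept by the
    caller). ``low_water`` is the seaward low-water level of the month.
    """
    if depth_samples.shape[0] == 0:
        raise ValueError("no hydrodynamic samples in ecological step")
    P = relative_hydroperiod(depth_samples, drying_threshold)
    always_wet = np.all(depth_samples > drying_threshold, axis=0)
    stagnant = always_wet & (bed > low_water)
    return P, stagnant


def _veg_roughness(cells: list[CohortCell], depth_ref: np.ndarray,
                   cfg: ScenarioConfig) -> RoughnessField:
    """Roughness field from the cohort state, frozen for one month.

    The Baptist mapping depends on water depth; it is evaluated at the
    previous month's mean wet depth per cell (clamped to a small minimum
    so emergent canopies are treated as emergent).
    """
    k = cfg.vegetation
    n = len(cells)
    rough = RoughnessField.bare(n, k.chezy_bare)
    for i, cell in enumerate(cells):
        if cell.cohorts:
            h_ref = max(float(depth_ref[i]), 0.01)
            cn, lam = roughness_from_vegetation(cell, h_ref, k)
            rough.chezy[i] = cn
            rough.resistance[i] = lam
    return rough


def _integrate_month(cfg: ScenarioConfig, hydro: HydroState, sed: SedState,
                     rough: RoughnessField, step0: int, n_steps: int,
                     slr_offset_fn) -> dict:
    """Integrate hydrodynamics + waves + mud over one ecological month.

    ``step0`` is the global hydro step counter (defines absolute time);
    ``slr_offset_fn(t_morph_years)`` returns the mean-level offset.
    Returns sampled statistics for the ecology update.
    """
    num = cfg.numerics
    dt = num.dt_hydro
    dx = cfg.cell_size
    tide = cfg.tide()
    morfac = cfg.morfac
    n = cfg.n_cells

    n_samp = n_steps // num.sample_every + 1
    depth_samples = np.empty((n_samp, n), dtype=float)
    tau_samples = np.empty((n_samp, n), dtype=float)
    boundary_levels = np.empty(n_samp, dtype=float)
    isamp = 0

    tau_w = np.zeros(n)
    fx = np.zeros(n)
    tau_cw = np.zeros(n)

    for istep in range(n_steps):
        t = (step0 + istep) * dt
        t_morph_years = t * morfac / SECONDS_PER_YEAR
        offset = slr_offset_fn(t_morph_years)
        eta_b = tide.level(t, mean_offset=offset)

        if cfg.waves_on and istep % num.wave_update_every == 0:
            wf = solve_wave_field(hydro.depth(), dx, cfg.wave_height_boundary,
                                  cfg.wave_period, num)
            tau_w = wf.tau_w
            fx = wf.radiation_force

        hydro = step_hydro(hydro, rough, eta_b, dt, dx, num,
                           wave_force=fx if cfg.waves_on else None)
        tau_c = bed_shear_current(hydro, rough, num,
                                  chezy_bare=cfg.vegetation.chezy_bare)
        tau_cw = combine_shear(tau_c, tau_w, num.shear_combine) \
            if cfg.waves_on else tau_c

        step_transport(sed, hydro, tau_cw, cfg.ssc_boundary, dt, dx,
                       cfg.mud, morfac=morfac, numerics=num)

        if istep % num.sample_every == 0:
            depth_samples[isamp] = hydro.depth()
            tau_samples[isamp] = tau_cw
            boundary_levels[isamp] = eta_b
            isamp += 1

    return {
        "depth": depth_samples[:isamp],
        "tau": tau_samples[:isamp],
        "low_water": float(boundary_levels[:isamp].min()),
        "offset_end": offset,
    }


def _snapshot(archive: RunArchive, year: float, hydro: HydroState,
              cells: list[CohortCell], P: np.ndarray, offset: float,
              sed: SedState) -> None:
    archive.years.append(year)
    archive.bed.append(hydro.bed.copy())
    archive.veg_count.append(
        np.array([c.total_count() for c in cells], dtype=float))
    archive.veg_max_diameter.append(
        np.array([max((co.diameter for co in c.cohorts), default=0.0)
                  for c in cells]))
    archive.hydroperiod.append(np.asarray(P, dtype=float).copy())
    archive.mean_offset.append(float(offset))
    archive.mass_balance.append({
        "bed_volume_change": sed.ledger.bed_volume_change,
        "boundary_import": sed.ledger.boundary_import,
        "clipped_mass": sed.ledger.clipped_mass,
        "clipped_water_volume": hydro.clipped_volume,
    })
    for i, cell in enumerate(cells):
        for co in cell.cohorts:
            archive.cohort_rows.append(
                (year, i, co.diameter, co.height, co.count, co.stress_years,
                 bool(cell.stagnant)))


def run_scenario(cfg: ScenarioConfig, years: float | None = None,
                 progress: bool = False) -> RunArchive:
    """Run one scenario for ``years`` morphological years (default: the
    configured spin-up + SLR duration). Returns the archive; on solver
    failure the archive is truncated at the failure time and flagged."""
    total_years = cfg.years_total if years is None else years
    archive = RunArchive(config=cfg)
    state = _fresh_state(cfg)
    try:
        _advance(cfg, archive, state, int(round(total_years)), progress)
    except FloatingPointError as err:
        archive.failed = True
        archive.failure_info = str(err)
    return archive


def _fresh_state(cfg: ScenarioConfig) -> dict:
    grid = cfg.grid()
    hydro = HydroState.at_rest(grid, level=0.0)
    sed = SedState.zero(cfg.n_cells)
    cells = [CohortCell() for _ in range(cfg.n_cells)]
    return {
        "hydro": hydro,
        "sed": sed,
        "cells": cells,
        "global_step": 0,
        "year": 0,
        "prev_tau90": None,          # previous year's 90th-pct shear per cell
        "tau_year": [],              # running monthly tau sample blocks
        "depth_ref": hydro.depth(),  # reference depth for roughness
        "last_P": np.zeros(cfg.n_cells),
    }


def _advance(cfg: ScenarioConfig, archive: RunArchive, state: dict,
             n_years: int, progress: bool = False) -> None:
    num = cfg.numerics
    slr = cfg.slr()
    month_hydro_seconds = SECONDS_PER_YEAR / 12.0 / cfg.morfac
    steps_per_month = max(int(round(month_hydro_seconds / num.dt_hydro)), 1)

    def slr_offset(t_morph_years: float) -> float:
        return slr.offset(t_morph_years - cfg.years_spinup)

    hydro: HydroState = state["hydro"]
    sed: SedState = state["sed"]
    cells: list[CohortCell] = state["cells"]
    k = cfg.vegetation

    if not archive.years:  # initial snapshot
        _snapshot(archive, state["year"], hydro, cells, state["last_P"],
                  slr_offset(state["year"]), sed)

    end_year = state["year"] + n_years
    while state["year"] < end_year:
        sed.ledger.reset()
        for month in range(1, 13):
            rough = _veg_roughness(cells, state["depth_ref"], cfg) \
                if cfg.vegetation_on else RoughnessField.bare(
                    cfg.n_cells, k.chezy_bare)
            stats = _integrate_month(cfg, hydro, sed, rough,
                                     state["global_step"], steps_per_month,
                                     slr_offset)
            state["global_step"] += steps_per_month
            P, stagnant = ecological_statistics(
                stats["depth"], stats["tau"], hydro.bed, stats["low_water"],
                num.drying_threshold)
            state["tau_year"].append(stats["tau"])
            state["last_P"] = P
            state["depth_ref"] = stats["depth"].mean(axis=0)

            if not cfg.vegetation_on:
                continue
            f = fitness(P, k)
            for i, cell in enumerate(cells):
                cell.stagnant = bool(stagnant[i]) if cell.cohorts else False
            if month == 1:
                if state["prev_tau90"] is None:
                    tau90 = shear_percentile(stats["tau"], 90.0)
                else:
                    tau90 = state["prev_tau90"]
                for i in range(cfg.n_cells):
                    cells[i] = colonize(cells[i], float(P[i]), float(tau90[i]), k)
            for i, cell in enumerate(cells):
                if not cell.cohorts or cell.stagnant:
                    continue
                C = competition(cell.biomass(k), k)
                cell.cohorts = [grow_cohort(co, float(f[i]), C, k)
                                for co in cell.cohorts]
            if month == 12:
                for i, cell in enumerate(cells):
                    if not cell.cohorts:
                        continue
                    C = competition(cell.biomass(k), k)
                    cells[i] = evaluate_mortality(cell, float(f[i]), C, k)

        tau_year = np.concatenate(state["tau_year"], axis=0)
        state["prev_tau90"] = shear_percentile(tau_year, 90.0)
        state["tau_year"] = []
        state["year"] += 1
        _snapshot(archive, state["year"], hydro, cells, state["last_P"],
                  slr_offset(state["year"]), sed)
        if progress:
            ncov = int(np.sum(archive.veg_count[-1] > 0))
            print(f"year {state['year']:4d}  vegetated cells {ncov:4d}  "
                  f"offset {archive.mean_offset[-1]:.3f} m")

    archive.checkpoint = _make_checkpoint(cfg, state)


def _make_checkpoint(cfg: ScenarioConfig, state: dict) -> dict:
    cells = state["cells"]
    return {
        "config": cfg.to_dict(),
        "year": state["year"],
        "global_step": state["global_step"],
        "eta": state["hydro"].eta.copy(),
        "u": state["hydro"].u.copy(),
        "bed": state["hydro"].bed.copy(),
        "hc": state["sed"].hc.copy(),
        "clipped_volume": state["hydro"].clipped_volume,
        "prev_tau90": None if state["prev_tau90"] is None
        else np.asarray(state["prev_tau90"]).copy(),
        "depth_ref": np.asarray(state["depth_ref"]).copy(),
        "last_P": np.asarray(state["last_P"]).copy(),
        "cohorts": [
            [(co.diameter, co.count, co.stress_years) for co in cell.cohorts]
            for cell in cells
        ],
        "stagnant": [cell.stagnant for cell in cells],
    }


def resume(archive: RunArchive, extra_years: float) -> RunArchive:
    """Continue a completed run for ``extra_years`` more morphological
    years, bit-identically to an unbroken run of the combined length.

    Refuses truncated (failed) archives and archives whose stored
    configuration no longer matches their checkpoint.
    """
    if archive.failed:
        raise ValueError(
            f"cannot resume a truncated archive (failure: {archive.failure_info})")
    if archive.checkpoint is None:
        raise ValueError("archive has no checkpoint")
    cfg = archive.config
    if archive.checkpoint["config"] != cfg.to_dict():
        raise ValueError("archive config does not match checkpoint; refusing")

    from .vegetation import Cohort  # local import to avoid cycle noise
    ck = archive.checkpoint
    hydro = HydroState(eta=ck["eta"].copy(), u=ck["u"].copy(),
                       bed=ck["bed"].copy(),
                       clipped_volume=ck["clipped_volume"])
    sed = SedState(hc=ck["hc"].copy())
    cells = []
    for cohort_list, stag in zip(ck["cohorts"], ck["stagnant"]):
        cell = CohortCell(
            cohorts=[Cohort(diameter=d, count=cnt, stress_years=int(s))
                     for d, cnt, s in cohort_list],
            stagnant=bool(stag),
        )
        cells.append(cell)
    state = {
        "hydro": hydro,
        "sed": sed,
        "cells": cells,
        "global_step": int(ck["global_step"]),
        "year": int(ck["year"]),
        "prev_tau90": None if ck["prev_tau90"] is None else ck["prev_tau90"].copy(),
        "tau_year": [],
        "depth_ref": ck["depth_ref"].copy(),
        "last_P": ck["last_P"].copy(),
    }
    try:
        _advance(cfg, archive, state, int(round(extra_years)))
    except FloatingPointError as err:
        archive.failed = True
        archive.failure_info = str(err)
    return archive
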