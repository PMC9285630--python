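"""Post-processing: slope/extent diagnostics, edge trajectories, zonal
sediment budgets, station accretion rates and relative-displacement
vulnerability, all pure functions of a run archive.

Conventions: the mangrove *seaward edge* is the seaward-most cell with a
live tree, the *landward edge* the landward-most; edge displacement is
positive landward (retreat), negative seaward (expansion); zonal budget
rates are in cm of vertical change per m of cross-shore distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orchestrator import RunArchive

__all__ = [
    "ExtentRecord",
    "EdgeTrajectory",
    "BudgetReport",
    "vegetated_edges",
    "extents_and_slopes",
    "edge_movement",
    "sediment_budget_zones",
    "station_accretion_rates",
    "relative_displacement",
]


@dataclass(frozen=True)
class ExtentRecord:
    defined: bool
    unvegetated_slope: float = np.nan
    vegetated_slope: float = np.nan
    vertical_extent_unvegetated: float = np.nan  # m, MWL to seaward edge
    vertical_extent_vegetated: float = np.nan    # m, between the edges
    horizontal_extent_unvegetated: float = np.nan  # m, MWL crossing to edge
    horizontal_extent_vegetated: float = np.nan    # m, between the edges
    seaward_edge_x: float = np.nan
    landward_edge_x: float = np.nan


@dataclass
class EdgeTrajectory:
    time: np.ndarray
    seaward_edge_x: np.ndarray
    landward_edge_x: np.ndarray
    seaward_edge_elev: np.ndarray
    displacement: np.ndarray  # m, positive landward of the reference


@dataclass
class BudgetReport:
    zone1_rate: float              # cm/m
    zone2_rate: float | None       # cm/m; None when Zone 2 is degenerate
    zone1_cells: tuple[int, int]   # [start, stop) cell index range
    zone2_cells: tuple[int, int]
    zone1_length: float            # m
    zone2_length: float


def vegetated_edges(veg_count: np.ndarray, x: np.ndarray):
    """(seaward_x, landward_x, seaward_idx, landward_idx) of the live
    forest, or None when no cell is vegetated."""
    idx = np.flatnonzero(veg_count > 0)
    if idx.size == 0:
        return None
    return x[idx[0]], x[idx[-1]], int(idx[0]), int(idx[-1])


def _mwl_crossing_x(bed: np.ndarray, x: np.ndarray, level: float,
                    stop_idx: int) -> float:
    """Seaward-most cross-shore position where the profile reaches
    ``level``, searching seaward of cell ``stop_idx``; linear interp."""
    for i in range(stop_idx + 1):
        if bed[i] >= level:
            if i == 0:
                return x[0]
            frac = (level - bed[i - 1]) / (bed[i] - bed[i - 1])
            return x[i - 1] + frac * (x[i] - x[i - 1])
    return x[stop_idx]


def extents_and_slopes(archive: RunArchive, year: float) -> ExtentRecord:
    """Endpoint-based slopes and extents of the vegetated and seaward
    unvegetated profile sections at one snapshot.

    The unvegetated slope runs from the seaward boundary cell to the
    mangrove seaward edge; the vegetated slope between the two forest
    edges. Vertical/horizontal unvegetated extents are measured from the
    mean water level (crossing of the profile) to the seaward edge.
    """
    idx = archive.snapshot_at(year)
    bed = archive.bed[idx]
    counts = archive.veg_count[idx]
    x = archive.x
    edges = vegetated_edges(counts, x)
    if edges is None:
        return ExtentRecord(defined=False)
    xs, xl, i_s, i_l = edges
    mwl = archive.mean_offset[idx]
    z_s, z_l = bed[i_s], bed[i_l]
    unveg_slope = (z_s - bed[0]) / (xs - x[0]) if i_s > 0 else np.nan
    veg_slope = (z_l - z_s) / (xl - xs) if i_l > i_s else np.nan
    x_mwl = _mwl_crossing_x(bed, x, mwl, i_s)
    return ExtentRecord(
        defined=True,
        unvegetated_slope=unveg_slope,
        vegetated_slope=veg_slope,
        vertical_extent_unvegetated=z_s - mwl,
        vertical_extent_vegetated=z_l - z_s,
        horizontal_extent_unvegetated=xs - x_mwl,
        horizontal_extent_vegetated=xl - xs,
        seaward_edge_x=xs,
        landward_edge_x=xl,
    )


def edge_movement(archive: RunArchive, reference_year: float = None
                  ) -> EdgeTrajectory:
    """Seaward-edge trajectory with signed displacement from the
    reference snapshot (default: the SLR switch-on year). Positive
    displacement = landward retreat; negative = seaward expansion.
    Years without vegetation carry NaN edges."""
    if reference_year is None:
        reference_year = archive.config.years_spinup
    years = archive.years_array()
    x = archive.x
    n = len(years)
    xs = np.full(n, np.nan)
    xl = np.full(n, np.nan)
    zs = np.full(n, np.nan)
    for i in range(n):
        e = vegetated_edges(archive.veg_count[i], x)
        if e is not None:
            xs[i], xl[i] = e[0], e[1]
            zs[i] = archive.bed[i][e[2]]
    iref = archive.snapshot_at(reference_year)
    if np.isnan(xs[iref]):
        raise ValueError("no vegetation at the reference time")
    return EdgeTrajectory(
        time=years,
        seaward_edge_x=xs,
        landward_edge_x=xl,
        seaward_edge_elev=zs,
        displacement=xs - xs[iref],
    )


def sediment_budget_zones(archive: RunArchive, start_year: float = None,
                          end_year: float = None) -> BudgetReport:
    """Zonal bed-level budgets over the SLR window in cm/m.

    Zone 1 is the active profile from the seaward boundary up to the
    intersection of the pre-SLR profile with the high-water level before
    SLR; Zone 2 (new accommodation space) lies between the HWL-before
    and HWL-after intersections with the same pre-SLR profile. The rate
    in each zone is the spatial mean bed-level change in cm per meter of
    cross-shore distance (sign preserved, negative = net erosion).
    """
    cfg = archive.config
    if start_year is None:
        start_year = cfg.years_spinup
    if end_year is None:
        end_year = archive.years[-1]
    i0 = archive.snapshot_at(start_year)
    i1 = archive.snapshot_at(end_year)
    bed0 = archive.bed[i0]
    dz_cm = (archive.bed[i1] - bed0) * 100.0
    dx = cfg.cell_size
    amp = 0.5 * cfg.tidal_range
    hwl_before = archive.mean_offset[i0] + amp
    hwl_after = archive.mean_offset[i1] + amp

    below_before = np.flatnonzero(bed0 <= hwl_before)
    stop1 = int(below_before[-1]) + 1 if below_before.size else 0
    zone1 = (0, stop1)
    zone2_mask = (bed0 > hwl_before) & (bed0 <= hwl_after)
    z2_idx = np.flatnonzero(zone2_mask)
    if z2_idx.size == 0:
        zone2 = (stop1, stop1)
        zone2_rate = None
        zone2_len = 0.0
    else:
        zone2 = (int(z2_idx[0]), int(z2_idx[-1]) + 1)
        zone2_rate = float(np.mean(dz_cm[zone2[0]:zone2[1]]))
        zone2_len = (zone2[1] - zone2[0]) * dx
    zone1_rate = float(np.mean(dz_cm[:stop1])) if stop1 > 0 else 0.0
    return BudgetReport(
        zone1_rate=zone1_rate,
        zone2_rate=zone2_rate,
        zone1_cells=zone1,
        zone2_cells=zone2,
        zone1_length=stop1 * dx,
        zone2_length=zone2_len,
    )


def station_accretion_rates(archive: RunArchive, reference_year: float = None,
                            window: float = 10.0) -> pd.DataFrame:
    """Windowed accretion rate vs contemporaneous SLR rate at three fixed
    stations (seaward edge, center, landward edge of the pre-SLR
    forest), in mm/yr over centered windows of ``window`` morphological
    years. Rows where the station has lost its vegetation are flagged."""
    cfg = archive.config
    if reference_year is None:
        reference_year = cfg.years_spinup
    iref = archive.snapshot_at(reference_year)
    e = vegetated_edges(archive.veg_count[iref], archive.x)
    if e is None:
        raise ValueError("no vegetation at the reference time")
    _, _, i_s, i_l = e
    stations = {"seaward": i_s, "central": (i_s + i_l) // 2, "landward": i_l}
    years = archive.years_array()
    bed = archive.bed_array()
    offsets = np.asarray(archive.mean_offset, dtype=float)
    half = window / 2.0
    rows = []
    for year in years[years >= reference_year]:
        sel = (years >= year - half) & (years <= year + half)
        if np.sum(sel) < 2:
            continue
        t = years[sel]
        slr_rate = np.polyfit(t, offsets[sel], 1)[0] * 1000.0  # mm/yr
        iy = archive.snapshot_at(year)
        for name, cell in stations.items():
            acc = np.polyfit(t, bed[sel, cell], 1)[0] * 1000.0
            rows.append({
                "year": float(year),
                "station": name,
                "cell": cell,
                "accretion_rate_mm_yr": float(acc),
                "slr_rate_mm_yr": float(slr_rate),
                "vegetated": bool(archive.veg_count[iy][cell] > 0),
            })
    return pd.DataFrame(rows)


def relative_displacement(archive: RunArchive, mode: str = "dynamic",
                          start_year: float = None,
                          end_year: float = None) -> float:
    """Seaward-edge retreat after SLR relative to the pre-SLR horizontal
    vegetation extent; 0 = stable, -1 = the edge reached the old
    landward edge (full displacement). Seaward expansion counts as 0.

    "dynamic" reads the evolved edges from the archive; "static"
    freezes the pre-SLR profile and relocates the band to where the
    raised water levels reproduce its inundation geometry (the band's
    elevation window shifted up by the sea-level rise).
    """
    cfg = archive.config
    if start_year is None:
        start_year = cfg.years_spinup
    if end_year is None:
        end_year = archive.years[-1]
    i0 = archive.snapshot_at(start_year)
    i1 = archive.snapshot_at(end_year)
    e0 = vegetated_edges(archive.veg_count[i0], archive.x)
    if e0 is None:
        raise ValueError("no pre-SLR vegetation")
    xs0, xl0, i_s0, _ = e0
    extent0 = xl0 - xs0
    if extent0 <= 0:
        raise ValueError("pre-SLR vegetation extent must be positive")
    if mode == "dynamic":
        e1 = vegetated_edges(archive.veg_count[i1], archive.x)
        xs1 = e1[0] if e1 is not None else xl0  # forest gone: full retreat
    elif mode == "static":
        bed0 = archive.bed[i0]
        rise = archive.mean_offset[i1] - archive.mean_offset[i0]
        target = bed0[i_s0] + rise
        xs1 = xs0
        for i in range(i_s0, len(bed0)):
            if bed0[i] >= target:
                if i == i_s0:
                    xs1 = archive.x[i]
                else:
                    frac = (target - bed0[i - 1]) / (bed0[i] - bed0[i - 1])
                    xs1 = archive.x[i - 1] + frac * (archive.x[i] - archive.x[i - 1])
                break
        else:
            xs1 = archive.x[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    retreat = max(xs1 - xs0, 0.0)
    return -retreat / extent0
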