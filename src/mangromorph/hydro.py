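"""Depth-averaged 1D shallow-water solver for tidal flats.

A semi-implicit (theta-method) staggered-grid scheme with Chezy bed
friction, a quadratic vegetation momentum sink M = -(lambda/2)*u*|u|,
wetting/drying, an open (water-level) seaward boundary and a closed
landward wall. The flux-form continuity update conserves volume to
machine precision on closed domains; drying clips are returned for the
mass audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scenario import Grid1D, NumericsConfig

__all__ = [
    "HydroState",
    "RoughnessField",
    "step_hydro",
    "bed_shear_current",
    "relative_hydroperiod",
    "shear_percentile",
]

GRAVITY = 9.81


@dataclass
class RoughnessField:
    """Per-cell net Chezy roughness and vegetation resistance."""

    chezy: np.ndarray        # C_n [m^0.5/s]
    resistance: np.ndarray   # lambda [1/m]

    @classmethod
    def bare(cls, n_cells: int, chezy_bare: float = 65.0) -> "RoughnessField":
        return cls(chezy=np.full(n_cells, float(chezy_bare)),
                   resistance=np.zeros(n_cells))

    def validate(self) -> None:
        if np.any(self.chezy <= 0):
            raise ValueError("net Chezy coefficient must be positive")
        if np.any(self.resistance < 0):
            raise ValueError("vegetation resistance must be non-negative")


@dataclass
class HydroState:
    """Water level (cells), velocity (faces) and derived fields."""

    eta: np.ndarray           # (n,) water level [m]
    u: np.ndarray             # (n+1,) face velocity [m/s]
    bed: np.ndarray           # (n,) bed elevation [m] (shared with mud module)
    clipped_volume: float = 0.0

    @classmethod
    def at_rest(cls, grid: Grid1D, level: float = 0.0) -> "HydroState":
        bed = grid.bed_elevation.astype(float).copy()
        return cls(eta=np.maximum(bed, level), u=np.zeros(grid.n_cells + 1),
                   bed=bed)

    def depth(self) -> np.ndarray:
        return np.maximum(self.eta - self.bed, 0.0)

    def wet(self, drying_threshold: float = 0.05) -> np.ndarray:
        return self.depth() > drying_threshold

    def volume(self, dx: float) -> float:
        return float(np.sum(self.depth()) * dx)


def step_hydro(state: HydroState, roughness: RoughnessField,
               boundary_level: float, dt: float, dx: float,
               numerics: NumericsConfig | None = None,
               open_boundary: bool = True,
               wave_force: np.ndarray | None = None) -> HydroState:
    """Advance the state by one hydrodynamic step (in place; also returned).

    Momentum includes gravity, Chezy friction via the net Chezy C_n, the
    vegetation sink -(lambda/2)*u*|u|, optional upwind advection and an
    optional wave radiation force [N/m^2] per cell.
    """
    num = numerics or NumericsConfig()
    roughness.validate()
    if not np.all(np.isfinite(state.eta)) or not np.all(np.isfinite(state.u)):
        bad = int(np.argmax(~np.isfinite(state.eta)))
        raise FloatingPointError(f"non-finite hydro state at cell {bad}")
    fx = wave_force if wave_force is not None else np.zeros_like(state.eta)
    clipped = _kernels.hydro_step(
        state.eta, state.u, state.bed, dx, dt, num.theta,
        roughness.chezy, roughness.resistance, float(boundary_level),
        open_boundary, num.drying_threshold, num.rho_water,
        num.include_advection, fx,
    )
    state.clipped_volume += clipped
    if not np.all(np.isfinite(state.eta)):
        bad = int(np.argmax(~np.isfinite(state.eta)))
        raise FloatingPointError(f"non-finite water level at cell {bad}")
    return state


def bed_shear_current(state: HydroState, roughness: RoughnessField,
                      numerics: NumericsConfig | None = None,
                      chezy_bare: float = 65.0) -> np.ndarray:
    """Current-induced bed shear stress tau_c [N/m^2] per cell.

    partition "total": tau = rho*g*u|u|/C_n^2 (all drag, including
    vegetation form drag, felt at the bed); partition "bed": grain
    stress with the bare-bed Chezy, tau = rho*g*u|u|/C_b^2 (vegetation
    drag not transmitted to the bed). Dry cells return 0.
    """
    num = numerics or NumericsConfig()
    if np.any(roughness.chezy <= 0):
        raise ValueError("net Chezy coefficient must be positive")
    return _kernels.bed_shear_kernel(
        state.u, state.depth(), roughness.chezy, chezy_bare,
        num.rho_water, num.drying_threshold, num.shear_partition == "total",
    )


def relative_hydroperiod(depth_series: np.ndarray,
                         threshold: float = 0.05) -> np.ndarray:
    """Fraction of samples with depth above the inundation threshold.

    ``depth_series`` has time along axis 0; returns a scalar for a 1-D
    series, else the per-cell fraction.
    """
    d = np.asarray(depth_series, dtype=float)
    if d.shape[0] == 0:
        raise ValueError("empty depth series")
    p = np.mean(d > threshold, axis=0)
    return float(p) if np.ndim(p) == 0 else p


def shear_percentile(tau_series: np.ndarray, q: float = 90.0) -> np.ndarray:
    """Empirical q-th percentile of a bed-shear-stress series
    (linear-interpolation estimator, time along axis 0)."""
    t = np.asarray(tau_series, dtype=float)
    if t.shape[0] == 0:
        raise ValueError("empty shear series")
    if not 0.0 <= q <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    out = np.percentile(t, q, axis=0, method="linear")
    return float(out) if np.ndim(out) == 0 else out
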