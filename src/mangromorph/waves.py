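"""Cross-shore wave and roller energy balance.

A quasi-steady stand-in for a surf-zone roller model: small boundary
waves shoal over the profile conserving energy flux, break against a
bore-type depth limiter (Hs <= gamma*h), and feed a surface roller whose
dissipation lags the breaking point; the cross-shore radiation-stress
gradient forces the flow and the near-bed orbital motion adds a wave
bed shear stress. Wave damping by vegetation canopies is deliberately
not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .scenario import NumericsConfig

__all__ = ["WaveField", "solve_wave_field", "wave_bed_shear", "combine_shear"]

GRAVITY = 9.81

#: roughness length [m] for the wave friction factor (Swart-type);
#: mud beds are hydraulically smooth (Nikuradse ks ~ 0.5 mm, z0 = ks/30)
Z0_WAVE = 2e-5
FW_MAX = 0.3


@dataclass
class WaveField:
    energy: np.ndarray          # E [J/m^2]
    roller_energy: np.ndarray   # Er [J/m^2]
    hs: np.ndarray              # significant height [m]
    orbital_velocity: np.ndarray  # Uw [m/s]
    tau_w: np.ndarray           # wave bed shear stress [N/m^2]
    radiation_force: np.ndarray  # Fx [N/m^2]

    @classmethod
    def zero(cls, n_cells: int) -> "WaveField":
        z = lambda: np.zeros(n_cells)
        return cls(z(), z(), z(), z(), z(), z())


def solve_wave_field(depth: np.ndarray, dx: float, hs_boundary: float,
                     tp: float, numerics: NumericsConfig | None = None
                     ) -> WaveField:
    """Steady wave field over the current depth profile.

    Waves enter at the seaward boundary only; energy flux E*cg is
    conserved landward except for breaker dissipation, which transfers
    into the roller balance d(2*Er*c)/dx = D_br - D_r with
    D_r = 2*g*beta*Er/c. Dry cells terminate propagation.
    """
    if hs_boundary < 0:
        raise ValueError("boundary wave height must be non-negative")
    num = numerics or NumericsConfig()
    h = np.asarray(depth, dtype=float)
    E, Er, Hs, Uw, tau_w, Fx = _kernels.wave_march(
        h, dx, float(hs_boundary), float(tp), num.breaker_gamma,
        num.roller_beta, num.rho_water, num.drying_threshold, Z0_WAVE, FW_MAX,
    )
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("wave energy balance produced non-finite values")
    return WaveField(E, Er, Hs, Uw, tau_w, Fx)


def wave_bed_shear(hs: float, tp: float, h: float,
                   rho: float = 1000.0) -> float:
    """Wave-induced bed shear stress tau_w = 0.5*rho*fw*Uw^2 [N/m^2].

    Uw from linear theory, Uw = pi*Hs/(Tp*sinh(kh)); fw from the
    rough-bed Swart-type friction factor fw = 1.39*(A/z0)^-0.52 capped
    at 0.3, with orbital excursion A = Uw*Tp/(2*pi).
    """
    if hs <= 0 or h <= 0:
        return 0.0
    omega = 2.0 * np.pi / tp
    k = _kernels.dispersion_k(omega, h)
    sh = np.sinh(k * h)
    if sh < 1e-8:
        return 0.0
    uw = np.pi * hs / (tp * sh)
    if uw < 1e-9:
        return 0.0
    a_orb = uw * tp / (2.0 * np.pi)
    fw = min(1.39 * (a_orb / Z0_WAVE) ** (-0.52), FW_MAX)
    return 0.5 * rho * fw * uw * uw


def combine_shear(tau_c, tau_w, mode: str = "linear"):
    """Combined current+wave bed shear stress.

    "linear": simple addition tau_cw = tau_c + tau_w. "mean": Soulsby's
    nonlinear interaction — the mean stress tau_m = tau_c*(1 +
    1.2*(tau_w/(tau_c+tau_w))^3.2) plus the full wave stress, i.e. the
    maximum combined stress for co-linear waves and currents.
    """
    tau_c = np.asarray(tau_c, dtype=float)
    tau_w = np.asarray(tau_w, dtype=float)
    if np.any(tau_c < 0) or np.any(tau_w < 0):
        raise ValueError("shear stresses must be non-negative")
    if mode == "linear":
        out = tau_c + tau_w
    elif mode == "mean":
        tot = tau_c + tau_w
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(tot > 0, tau_w / np.where(tot > 0, tot, 1.0), 0.0)
        out = tau_c * (1.0 + 1.2 * frac**3.2) + tau_w
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return float(out) if np.ndim(out) == 0 else out
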