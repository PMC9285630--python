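"""Low-level time-stepping kernels.

Hot loops for the semi-implicit shallow-water step, the explicit mud
advection-diffusion step and the steady wave/roller energy march. They
are compiled with numba when available; the pure-Python definitions are
kept runnable so the package degrades gracefully without a JIT.

All kernels are free functions over plain float64 arrays so they stay
trivially jittable; state containers live one layer up in ``hydro``,
``mud`` and ``waves``.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

G = 9.81


@njit(cache=True)
def thomas_solve(a, b, c, d):
    """Tridiagonal solve (in-place on copies); a is sub-, c super-diagonal."""
    n = b.shape[0]
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@njit(cache=True)
def hydro_step(eta, u, z, dx, dt, theta, cn, lam, eta_b, open_boundary,
               h_dry, rho, include_adv, fx_wave):
    """One semi-implicit (theta) staggered-grid shallow-water step.

    eta: (n,) cell water levels, updated in place.
    u:   (n+1,) face velocities, updated in place; face 0 is the seaward
         boundary face, face n the closed landward wall.
    z:   (n,) cell bed elevations.
    cn, lam: (n,) net Chezy and vegetation resistance per cell.
    fx_wave: (n,) wave radiation force per unit area [N/m^2].
    Returns the volume clipped by the drying fix (m^3 per unit width).
    """
    n = eta.shape[0]
    Hf = np.zeros(n + 1)
    Fu = np.zeros(n + 1)
    Gu = np.zeros(n + 1)

    for j in range(n):  # face n stays closed (Hf=0)
        if j == 0:
            if not open_boundary:
                continue
            eta_l = eta_b
            eta_r = eta[0]
            z_f = z[0]
            cn_f = cn[0]
            lam_f = lam[0]
            fx_f = fx_wave[0]
        else:
            eta_l = eta[j - 1]
            eta_r = eta[j]
            z_f = max(z[j - 1], z[j])
            cn_f = 0.5 * (cn[j - 1] + cn[j])
            lam_f = 0.5 * (lam[j - 1] + lam[j])
            fx_f = 0.5 * (fx_wave[j - 1] + fx_wave[j])
        hf = max(eta_l, eta_r) - z_f
        if hf <= h_dry:
            u[j] = 0.0
            continue
        Hf[j] = hf
        adv = 0.0
        if include_adv:
            if u[j] > 0.0 and j >= 1:
                adv = -u[j] * (u[j] - u[j - 1]) / dx
            elif u[j] < 0.0 and j + 1 <= n:
                adv = -u[j] * (u[j + 1] - u[j]) / dx
        expl = u[j] + dt * (
            -G * (1.0 - theta) * (eta_r - eta_l) / dx
            + adv
            + fx_f / (rho * hf)
        )
        denom = 1.0 + dt * (G / (cn_f * cn_f * hf) + 0.5 * lam_f) * abs(u[j])
        Fu[j] = expl / denom
        Gu[j] = G * theta * dt / dx / denom

    # tridiagonal continuity system for eta^{n+1}
    r = dt / dx
    a = np.zeros(n)
    b = np.ones(n)
    c = np.zeros(n)
    d = np.empty(n)
    for i in range(n):
        gl = theta * r * Hf[i] * Gu[i]
        gr = theta * r * Hf[i + 1] * Gu[i + 1]
        b[i] = 1.0 + gl + gr
        if i > 0:
            a[i] = -gl
        if i < n - 1:
            c[i] = -gr
        d[i] = eta[i] - r * (
            theta * (Hf[i + 1] * Fu[i + 1] - Hf[i] * Fu[i])
            + (1.0 - theta) * (Hf[i + 1] * u[i + 1] - Hf[i] * u[i])
        )
    if open_boundary and Hf[0] > 0.0:
        d[0] += theta * r * Hf[0] * Gu[0] * eta_b

    eta_new = thomas_solve(a, b, c, d)

    clipped = 0.0
    for j in range(n + 1):
        if Hf[j] <= 0.0:
            u[j] = 0.0
        else:
            if j == 0:
                el = eta_b
            else:
                el = eta_new[j - 1]
            er = eta_new[j] if j < n else el
            if j == n:
                u[j] = 0.0
            else:
                u[j] = Fu[j] - Gu[j] * (er - el)
    for i in range(n):
        e = eta_new[i]
        if e < z[i]:  # drying fix; bookkeeping for mass audit
            clipped += (z[i] - e) * dx
            e = z[i]
        eta[i] = e
    return clipped


@njit(cache=True)
def bed_shear_kernel(u, h, cn, cb, rho, h_dry, partition_total):
    """Cell-centered current-induced bed shear stress [N/m^2]."""
    n = h.shape[0]
    tau = np.zeros(n)
    for i in range(n):
        if h[i] <= h_dry:
            continue
        uc = 0.5 * (u[i] + u[i + 1])
        cc = cn[i] if partition_total else cb
        tau[i] = rho * G * uc * abs(uc) / (cc * cc)
        if tau[i] < 0.0:
            tau[i] = -tau[i]
    return tau


@njit(cache=True)
def mud_step(hc, eta, u, z, tau, dx, dt, boundary_ssc, open_boundary,
             h_dry, tau_ce, tau_cd, m_eros, w_s, rho_dry, diffusivity,
             morfac):
    """Explicit upwind advection-diffusion + Partheniades-Krone exchange.

    hc: (n,) depth-integrated suspended mass [kg/m^2], updated in place.
    z:  (n,) bed elevation, updated in place (morfac-accelerated).
    Returns (bed_change_volume_per_width, boundary_import_mass,
             clipped_mass) for the mass ledger. Deposition is handled
    implicitly so settling cannot overdraw the suspended mass.
    """
    n = hc.shape[0]
    h = np.empty(n)
    for i in range(n):
        h[i] = max(eta[i] - z[i], 0.0)

    c = np.empty(n)
    for i in range(n):
        c[i] = hc[i] / h[i] if h[i] > h_dry else 0.0

    # face fluxes q [kg/m/s], positive landward
    q = np.zeros(n + 1)
    for j in range(n):
        if j == 0:
            if not open_boundary:
                continue
            hf = max(eta[0] - z[0], 0.0)
            if hf <= h_dry:
                continue
            cu = boundary_ssc if u[0] > 0.0 else c[0]
            q[0] = u[0] * hf * cu
        else:
            hf = max(eta[j - 1], eta[j]) - max(z[j - 1], z[j])
            if hf <= h_dry:
                continue
            cu = c[j - 1] if u[j] >= 0.0 else c[j]
            q[j] = u[j] * hf * cu - diffusivity * hf * (c[j] - c[j - 1]) / dx

    imported = dt * q[0]  # mass entering through the open boundary per width

    bed_vol = 0.0
    clipped = 0.0
    for i in range(n):
        hc_i = hc[i] + dt * (q[i] - q[i + 1]) / dx
        ero = 0.0
        dep = 0.0
        if h[i] > h_dry:
            if tau[i] > tau_ce:
                ero = m_eros * (tau[i] / tau_ce - 1.0)
            hc_i += dt * ero
            red = 1.0 - tau[i] / tau_cd
            if red < 0.0:
                red = 0.0
            if red > 0.0 and hc_i > 0.0:
                fac = 1.0 + dt * w_s * red / h[i]
                hc_new = hc_i / fac
                dep = (hc_i - hc_new) / dt
                hc_i = hc_new
        if hc_i < 0.0:
            clipped += -hc_i
            hc_i = 0.0
        hc[i] = hc_i
        dz = morfac * (dep - ero) * dt / rho_dry
        z[i] += dz
        bed_vol += dz * dx
    return bed_vol, imported, clipped


@njit(cache=True)
def dispersion_k(omega, h):
    """Wavenumber from the linear dispersion relation (Newton iteration)."""
    k = omega * omega / G  # deep-water seed
    if h <= 0.0:
        return 0.0
    # shallow-water seed when kh small
    ksh = omega / math.sqrt(G * h)
    if ksh * h < 1.0:
        k = ksh
    for _ in range(30):
        t = math.tanh(k * h)
        f = G * k * t - omega * omega
        df = G * t + G * k * h * (1.0 - t * t)
        dk = f / df
        k -= dk
        if abs(dk) < 1e-12 * k:
            break
    return k


@njit(cache=True)
def wave_march(h, dx, hs0, tp, gamma, beta, rho, h_dry, z0, fw_max):
    """Steady cross-shore wave + roller energy balance (landward march).

    Returns (E, Er, Hs, Uw, tau_w, Fx). Breaking is a bore-type limiter
    Hs <= gamma*h; the excess energy flux feeds the roller, which decays
    with dissipation D_r = 2*g*beta*Er/c. The radiation force Fx is the
    negative cross-shore gradient of Sxx = (2cg/c - 1/2)E + 2Er.
    """
    n = h.shape[0]
    E = np.zeros(n)
    Er = np.zeros(n)
    Hs = np.zeros(n)
    Uw = np.zeros(n)
    tau_w = np.zeros(n)
    Fx = np.zeros(n)
    Sxx = np.zeros(n)
    if hs0 <= 0.0:
        return E, Er, Hs, Uw, tau_w, Fx
    omega = 2.0 * math.pi / tp
    flux = -1.0  # wave energy flux E*cg, set at first wet cell
    rflux = 0.0  # roller flux 2*Er*c
    blocked = False
    for i in range(n):
        if blocked or h[i] <= h_dry:
            blocked = True
            flux = 0.0
            rflux = 0.0
            continue
        k = dispersion_k(omega, h[i])
        kh = k * h[i]
        cph = omega / k
        nfac = 0.5 * (1.0 + 2.0 * kh / math.sinh(2.0 * kh))
        cg = nfac * cph
        if flux < 0.0:
            hs_in = min(hs0, gamma * h[i])
            E[i] = rho * G * hs_in * hs_in / 8.0
            flux = E[i] * cg
            d_br = 0.0
        else:
            E[i] = flux / cg
            hs_i = math.sqrt(8.0 * E[i] / (rho * G))
            hmax = gamma * h[i]
            d_br = 0.0
            if hs_i > hmax:
                e_lim = rho * G * hmax * hmax / 8.0
                d_br = (E[i] - e_lim) * cg / dx
                E[i] = e_lim
            flux = E[i] * cg
        # roller balance, explicit march
        d_r = 2.0 * G * beta * Er[i - 1] / cph if i > 0 else 0.0
        rflux = max(rflux + dx * (d_br - d_r), 0.0)
        Er[i] = rflux / (2.0 * cph)
        Hs[i] = math.sqrt(8.0 * E[i] / (rho * G))
        sh = math.sinh(kh)
        if sh > 1e-8:
            Uw[i] = math.pi * Hs[i] / (tp * sh)
        if Uw[i] > 1e-9:
            a_orb = Uw[i] * tp / (2.0 * math.pi)
            fw = 1.39 * (a_orb / z0) ** (-0.52)
            if fw > fw_max:
                fw = fw_max
            tau_w[i] = 0.5 * rho * fw * Uw[i] * Uw[i]
        Sxx[i] = (2.0 * nfac - 0.5) * E[i] + 2.0 * Er[i]
    for i in range(n):
        if i == 0:
            Fx[i] = -(Sxx[1] - Sxx[0]) / dx
        elif i == n - 1:
            Fx[i] = -(Sxx[i] - Sxx[i - 1]) / dx
        else:
            Fx[i] = -(Sxx[i + 1] - Sxx[i - 1]) / (2.0 * dx)
    return E, Er, Hs, Uw, tau_w, Fx
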