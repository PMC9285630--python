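"""Dynamic mangrove population model.

Implements the cohort-based vegetation dynamics of an *Avicennia marina*
forest on a muddy intertidal profile: seedling colonization inside
hydrodynamic "windows of opportunity", diameter growth limited by an
inundation fitness and a biomass-based competition stress, delayed
mortality after sustained poor growth, a root-number allometry for
pneumatophores, and the mapping from cohorts to hydraulic roughness
(Baptist formulation with separate stem and root fractions).

All tree state is kept per *cohort*: trees recruited into one cell in one
year share diameter, height and stress history, so a cell carries a short
list of cohorts instead of thousands of individuals.

Units follow mangrove forestry convention: stem diameter D in cm, tree
height H in cm, biomass in kg, cell areas in m^2; hydraulics are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VegConstants",
    "Cohort",
    "CohortCell",
    "fitness",
    "biomass_single",
    "influence_radius",
    "critical_biomass",
    "competition",
    "grow_cohort",
    "root_count",
    "colonize",
    "evaluate_mortality",
    "stagnation_flag",
    "roughness_from_vegetation",
]

GRAVITY = 9.81
VON_KARMAN = 0.41


@dataclass(frozen=True)
class VegConstants:
    """Vegetation model constants (defaults are the *Avicennia marina*
    parameterization used throughout).

    Growth: ``G`` [cm/month], ``b2`` [-], ``b3`` [1/cm] set the
    diameter-increment curve so the maximum increase is ~1 cm/yr;
    ``d_max``/``h_max`` cap diameter [cm] and height [cm].

    Fitness/competition: quadratic fitness coefficients ``a, b, c`` over
    relative hydroperiod; sigmoid slope ``d`` [1/kg] against the critical
    biomass W_0.5 derived from the zone-of-influence packing argument.
    """

    G: float = 12.68          # cm/month
    b2: float = 43.0
    b3: float = 0.536         # 1/cm
    d_max: float = 40.0       # cm
    h_max: float = 1000.0     # cm
    a: float = -8.0
    b: float = 4.0
    c: float = 0.5
    d: float = -0.0003        # 1/kg
    cell_area: float = 2500.0  # m^2, resource area of one grid cell
    seedling_density_cap: float = 30.0  # trees per 100 m^2 (also initial density)
    d_seedling: float = 1.37  # cm
    k_root: float = 0.3       # 1/cm
    n_root_max: float = 1000.0
    root_height: float = 0.15   # m (pneumatophore height)
    root_diameter: float = 0.01  # m
    cd_stem: float = 1.5
    cd_root: float = 1.0
    chezy_bare: float = 65.0  # m^0.5/s
    p_window: tuple[float, float] = (0.0, 0.5)  # open interval for colonization
    tau_colonize: float = 0.2  # N/m^2, 90th-percentile threshold
    stress_years_to_death: int = 5
    quality_threshold: float = 0.5  # f*C below this counts as a stress year


@dataclass
class Cohort:
    """One recruitment class: all trees that settled in a cell in the same
    year.  Height is always slaved to diameter through the allometric
    height-diameter relation."""

    diameter: float            # cm
    count: float               # trees in the cell
    stress_years: int = 0

    @property
    def height(self) -> float:
        """Tree height [cm] from the parabolic height-diameter allometry."""
        return tree_height(self.diameter)


@dataclass
class CohortCell:
    """Vegetation state of one grid cell."""

    cohorts: list[Cohort] = field(default_factory=list)
    stagnant: bool = False

    def total_count(self) -> float:
        return sum(c.count for c in self.cohorts)

    def biomass(self, k: VegConstants | None = None) -> float:
        """Total above+belowground biomass [kg] in the cell."""
        return sum(c.count * biomass_single(c.diameter)[2] for c in self.cohorts)

    def copy(self) -> "CohortCell":
        return CohortCell(
            cohorts=[replace(c) for c in self.cohorts], stagnant=self.stagnant
        )


def tree_height(D: float, k: VegConstants = VegConstants()) -> float:
    """Height H [cm] = 137 + b2*D - b3*D^2."""
    return 137.0 + k.b2 * D - k.b3 * D * D


def fitness(P, k: VegConstants = VegConstants()):
    """Inundation fitness f = a*P^2 + b*P + c.

    Peaks at f = 1 for the optimal relative hydroperiod P = 0.25 and
    falls to 0.5 at the window edges P = 0 and P = 0.5; strongly negative
    for permanently submerged cells (P = 1), which drives mortality.
    """
    P = np.asarray(P, dtype=float)
    f = k.a * P**2 + k.b * P + k.c
    return float(f) if f.ndim == 0 else f


def biomass_single(D: float) -> tuple[float, float, float]:
    """Above- and belowground biomass [kg] of a single tree of diameter D [cm].

    Allometric relations Wa = 0.308 D^2.11 and Wb = 1.28 D^1.17.
    Returns (Wa, Wb, Wa + Wb).
    """
    if D <= 0:
        raise ValueError(f"diameter must be positive, got {D}")
    wa = 0.308 * D**2.11
    wb = 1.28 * D**1.17
    return wa, wb, wa + wb


def influence_radius(D: float) -> float:
    """Zone-of-influence radius R [m] = 10*sqrt(stem radius in m).

    The stem radius D/2 is converted from cm to m before the square root.
    """
    r_stem_m = (D / 2.0) / 100.0
    return 10.0 * math.sqrt(max(r_stem_m, 0.0))


def critical_biomass(k: VegConstants = VegConstants()) -> float:
    """Critical competition biomass W_0.5 [kg] per cell.

    The cell is imagined packed with mature trees (D = d_max) whose
    zones of influence tile the cell without overlap: the number of trees
    is A_cell/(2R)^2, each contributing the mature-tree biomass.
    """
    w_mature = biomass_single(k.d_max)[2]
    two_r = 2.0 * influence_radius(k.d_max)
    return k.cell_area / two_r**2 * w_mature


def competition(W: float, k: VegConstants = VegConstants()) -> float:
    """Competition stress C = 1/(1 + exp(d*(W_0.5 - W))), in (0, 1).

    C = 0.5 at W = W_0.5; decreases with biomass (d < 0).
    """
    if W < 0:
        raise ValueError("biomass must be non-negative")
    w_half = critical_biomass(k)
    return 1.0 / (1.0 + math.exp(k.d * (w_half - W)))


def diameter_increment(D: float, k: VegConstants = VegConstants()) -> float:
    """Optimal-conditions monthly diameter increment dD/dt [cm/month].

    dD/dt = G*D*(1 - D*H/(d_max*h_max)) / (274 + 3*b2*D - 4*b3*D^2),
    to be multiplied by the growth quality f*C.
    """
    H = tree_height(D, k)
    denom = 274.0 + 3.0 * k.b2 * D - 4.0 * k.b3 * D * D
    return k.G * D * (1.0 - D * H / (k.d_max * k.h_max)) / denom


def grow_cohort(cohort: Cohort, f: float, C: float,
                k: VegConstants = VegConstants()) -> Cohort:
    """Advance a cohort by one ecological month (explicit Euler).

    Growth quality f*C scales the optimal increment; negative quality
    (e.g. permanently submerged, f < 0) does not shrink the tree — the
    increment is floored at zero; diameter is capped at d_max.
    """
    quality = max(f * C, 0.0)
    dD = diameter_increment(cohort.diameter, k) * quality
    new_d = min(cohort.diameter + max(dD, 0.0), k.d_max)
    return replace(cohort, diameter=new_d)


def root_count(D: float, k: VegConstants = VegConstants()) -> float:
    """Number of pneumatophore root elements per tree,
    N = n_root_max / (1 + exp(k_root*(d_max/2 - D))).  Always < n_root_max."""
    return k.n_root_max / (1.0 + math.exp(k.k_root * (k.d_max / 2.0 - D)))


def colonize(cell: CohortCell, P_first_step: float, tau90_prev_year: float,
             k: VegConstants = VegConstants()) -> CohortCell:
    """Annual seedling establishment (first ecological step of the year).

    Seedlings settle only inside the window of opportunity: relative
    hydroperiod strictly inside (0, 0.5) and previous-year 90th-percentile
    bed shear stress below the uprooting threshold.  Settlement tops the
    cell up to the density cap (seedling_density_cap per 100 m^2).
    """
    lo, hi = k.p_window
    if not (lo < P_first_step < hi):
        return cell
    if not (tau90_prev_year < k.tau_colonize):
        return cell
    cap = k.seedling_density_cap * k.cell_area / 100.0
    room = cap - cell.total_count()
    if room <= 0:
        return cell
    out = cell.copy()
    out.cohorts.append(Cohort(diameter=k.d_seedling, count=room))
    return out


def evaluate_mortality(cell: CohortCell, f: float, C: float,
                       k: VegConstants = VegConstants()) -> CohortCell:
    """Annual growth-quality evaluation (12th ecological step).

    Each cohort with f*C < 0.5 accrues one stress year (otherwise the
    counter resets); cohorts reaching 5 consecutive stress years die.
    Dead cohorts are removed smallest-diameter-first, one at a time,
    recomputing biomass and competition after each removal, stopping as
    soon as the relieved growth quality f*C reaches 0.5 again (surviving
    marked cohorts then have their counter reset — the consecutive chain
    is broken by the relief) or the cell is empty.
    """
    if cell.stagnant or not cell.cohorts:
        return cell
    out = cell.copy()
    quality = f * C
    for c in out.cohorts:
        if quality < k.quality_threshold:
            c.stress_years += 1
        else:
            c.stress_years = 0
    doomed = sorted(
        (c for c in out.cohorts if c.stress_years >= k.stress_years_to_death),
        key=lambda c: c.diameter,
    )
    for victim in doomed:
        q = f * competition(out.biomass(k), k)
        if q >= k.quality_threshold:
            break
        out.cohorts.remove(victim)
    if out.cohorts and f * competition(out.biomass(k), k) >= k.quality_threshold:
        for c in out.cohorts:
            if c.stress_years >= k.stress_years_to_death:
                c.stress_years = 0
    return out


def stagnation_flag(depth_series, bed_elev: float, low_water: float,
                    wet_threshold: float = 0.05) -> bool:
    """Detect ponded (stagnant) water on the upper flat.

    True iff the cell stayed wet through the whole month *and* its bed
    lies above the seaward low-water level — i.e. the water cannot be
    tidal submergence but a trapped layer with no lateral drainage.
    Stagnant cells neither grow nor accrue mortality stress.
    """
    depth_series = np.asarray(depth_series, dtype=float)
    if depth_series.size == 0:
        raise ValueError("empty depth series")
    always_wet = bool(np.all(depth_series > wet_threshold))
    return always_wet and bed_elev > low_water


# ---------------------------------------------------------------------------
# Baptist / trachytope roughness


def _baptist_class(n: float, hv: float, cd: float, h: float,
                   cb: float) -> tuple[float, float]:
    """(C_n, lambda) for one vegetation object class.

    Emergent (h < hv): the canopy occupies the whole column — bed Chezy
    unchanged, resistance lambda = CD*n.  Submerged: Baptist net Chezy
    (bed term reduced by canopy drag, log overflow term above the canopy)
    and lambda = CD*n*(hv/h)*(Cb/Cn)^2.
    """
    if hv <= 0:
        raise ValueError("vegetation object height must be positive")
    if n <= 0:
        return cb, 0.0
    if h < hv:
        return cb, cd * n
    cn = 1.0 / math.sqrt(1.0 / cb**2 + cd * n * hv / (2.0 * GRAVITY))
    if h > hv:
        cn += math.sqrt(GRAVITY) / VON_KARMAN * math.log(h / hv)
    lam = cd * n * (hv / h) * (cb / cn) ** 2
    return cn, lam


def roughness_from_vegetation(cell: CohortCell, h: float,
                              k: VegConstants = VegConstants()
                              ) -> tuple[float, float]:
    """Net Chezy C_n [m^0.5/s] and resistance lambda [1/m] for one cell.

    Every cohort contributes two object classes — stems (height H,
    diameter D) and pneumatophore roots (fixed geometry, count from the
    root-number sigmoid).  Each class has density n = m*D_obj with m
    objects per m^2 and D_obj the object diameter in m.  Per-class
    (C_n, lambda) values are combined by fraction-coverage averaging
    (equal weights across the classes present).  A bare cell returns
    (chezy_bare, 0).
    """
    if h < 0:
        raise ValueError("depth must be non-negative")
    classes: list[tuple[float, float]] = []
    for c in cell.cohorts:
        if c.count <= 0:
            continue
        m_stem = c.count / k.cell_area
        n_stem = m_stem * (c.diameter / 100.0)
        hv_stem = c.height / 100.0
        classes.append(_baptist_class(n_stem, hv_stem, k.cd_stem, h, k.chezy_bare))
        m_root = c.count * root_count(c.diameter, k) / k.cell_area
        n_root = m_root * k.root_diameter
        classes.append(_baptist_class(n_root, k.root_height, k.cd_root, h, k.chezy_bare))
    if not classes:
        return k.chezy_bare, 0.0
    cn = sum(c for c, _ in classes) / len(classes)
    lam = sum(l for _, l in classes) / len(classes)
    return cn, lam
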