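"""Closed-form vegetation model: allometry, fitness, competition,
growth, colonization, mortality and the Baptist roughness mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mangromorph.vegetation import (
    Cohort, CohortCell, VegConstants, biomass_single, colonize, competition,
    critical_biomass, diameter_increment, evaluate_mortality, fitness,
    grow_cohort, influence_radius, root_count, roughness_from_vegetation,
    stagnation_flag, tree_height,
)

K = VegConstants()


class TestFitness:
    @pytest.mark.parametrize("P, expected", [
        (0.25, 1.0),       # optimum
        (0.0, 0.5),        # intercept
        (0.5, 0.5),        # window edge
        (1.0, -3.5),       # permanently submerged
    ])
    def test_values(self, P, expected):
        assert fitness(P) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_bounded_above_by_optimum(self, P):
        assert fitness(P) <= 1.0 + 1e-12

    def test_at_least_half_inside_window(self):
        P = np.linspace(0.0, 0.5, 201)
        assert np.all(fitness(P) >= 0.5 - 1e-12)


class TestAllometry:
    def test_mature_biomass(self):
        wa, wb, _ = biomass_single(40.0)
        assert wa == pytest.approx(0.308 * 40**2.11, rel=1e-12)
        assert wa == pytest.approx(740.4, rel=2e-3)
        assert wb == pytest.approx(95.9, rel=2e-3)

    def test_unit_diameter(self):
        wa, wb, tot = biomass_single(1.0)
        assert (wa, wb) == (0.308, 1.28)
        assert tot == pytest.approx(1.588)

    @given(st.floats(0.1, 39.0))
    @settings(deadline=None)
    def test_monotone_in_diameter(self, D):
        assert biomass_single(D + 1.0)[2] > biomass_single(D)[2]

    def test_height_at_caps(self):
        assert tree_height(40.0) == pytest.approx(999.4)
        # rounds to the 1000 cm maximum height
        assert round(tree_height(40.0) / 100) * 100 == 1000

    def test_influence_radius(self):
        assert influence_radius(40.0) == pytest.approx(10 * math.sqrt(0.2))
        assert influence_radius(1e-9) == pytest.approx(0.0, abs=1e-3)
        D = np.linspace(0.5, 40, 50)
        R = [influence_radius(d) for d in D]
        assert np.all(np.diff(R) > 0)


class TestCompetition:
    def test_critical_biomass_value(self):
        # packing a 2500 m^2 cell with mature trees
        assert critical_biomass() == pytest.approx(2.61e4, rel=5e-3)

    def test_critical_biomass_scales_with_area(self):
        k2 = VegConstants(cell_area=5000.0)
        assert critical_biomass(k2) == pytest.approx(2 * critical_biomass())

    def test_midpoint_and_empty(self):
        w_half = critical_biomass()
        assert competition(w_half) == pytest.approx(0.5)
        assert competition(0.0) == pytest.approx(
            1 / (1 + math.exp(-0.0003 * w_half)), rel=1e-9)
        assert competition(0.0) > 0.999

    @given(st.floats(0.0, 1e5))
    @settings(deadline=None)
    def test_strictly_decreasing(self, W):
        c1, c2 = competition(W), competition(W + 10.0)
        assert 0.0 < c2 < c1 < 1.0


class TestGrowth:
    def test_no_growth_without_quality(self):
        c = Cohort(diameter=5.0, count=10)
        assert grow_cohort(c, 0.0, 1.0).diameter == 5.0

    def test_single_month_increment(self):
        c = grow_cohort(Cohort(diameter=12.0, count=1), 1.0, 1.0)
        assert c.diameter - 12.0 == pytest.approx(0.083, abs=2e-3)

    def test_max_annual_increment_about_one_cm(self):
        D = np.linspace(0.05, 40.0, 8000)
        inc = np.array([diameter_increment(d) for d in D]) * 12
        assert inc.max() == pytest.approx(1.0, rel=0.05)

    def test_capped_at_dmax(self):
        c = Cohort(diameter=39.999, count=1)
        for _ in range(240):
            c = grow_cohort(c, 1.0, 1.0)
        assert c.diameter <= K.d_max

    def test_monthly_euler_matches_daily_oracle(self):
        """Monthly explicit Euler vs a ~daily fine-step integration of the
        same growth ODE stays within 1% over 20 years at f = C = 1."""
        c = Cohort(diameter=K.d_seedling, count=1)
        for _ in range(240):
            c = grow_cohort(c, 1.0, 1.0)
        d_fine = K.d_seedling
        sub = 30  # substeps per month
        for _ in range(240 * sub):
            d_fine = min(d_fine + diameter_increment(d_fine) / sub, K.d_max)
        assert c.diameter == pytest.approx(d_fine, rel=0.01)

    def test_height_slaved_to_diameter(self):
        c = Cohort(diameter=17.3, count=4)
        assert c.height == pytest.approx(137 + 43 * 17.3 - 0.536 * 17.3**2)


class TestRoots:
    def test_sigmoid_points(self):
        assert root_count(20.0) == pytest.approx(500.0)
        assert root_count(40.0) == pytest.approx(1000 / (1 + math.exp(-6)), rel=1e-9)

    def test_bounded_by_maximum(self):
        D = np.linspace(0.0, 40.0, 4001)
        n = np.array([root_count(d) for d in D])
        assert np.all(n < 1000.0)
        assert np.all(np.diff(n) > 0)


class TestColonization:
    def test_fills_empty_cell_to_cap(self):
        cell = colonize(CohortCell(), 0.3, 0.1)
        assert cell.total_count() == pytest.approx(750)  # 30/100 m^2 * 2500 m^2
        assert cell.cohorts[0].diameter == 1.37

    def test_tops_up_partially_filled_cell(self):
        cell = CohortCell(cohorts=[Cohort(diameter=10.0, count=500)])
        cell = colonize(cell, 0.3, 0.1)
        assert cell.total_count() == pytest.approx(750)
        assert len(cell.cohorts) == 2

    @pytest.mark.parametrize("P, tau", [
        (0.6, 0.1),    # inundated too long
        (0.0, 0.1),    # never inundated
        (0.5, 0.1),    # window is open: P = 0.5 excluded
        (0.3, 0.25),   # bed shear above the uprooting threshold
        (0.3, 0.2),    # threshold itself does not qualify
    ])
    def test_window_of_opportunity_respected(self, P, tau):
        cell = colonize(CohortCell(), P, tau)
        assert cell.total_count() == 0

    def test_full_cell_unchanged(self):
        cell = CohortCell(cohorts=[Cohort(diameter=5.0, count=750)])
        out = colonize(cell, 0.3, 0.1)
        assert out.total_count() == 750
        assert len(out.cohorts) == 1


class TestMortality:
    def test_stress_counter_exact_semantics(self):
        """A cohort held at f*C = 0.49 dies in year 5, not year 4 or 6."""
        cell = CohortCell(cohorts=[Cohort(diameter=2.0, count=10)])
        for year in range(1, 7):
            if not cell.cohorts:
                died_in = year - 1
                break
            cell = evaluate_mortality(cell, 0.49, 1.0)
        else:
            died_in = None
        assert died_in == 5

    def test_good_year_resets_counter(self):
        cell = CohortCell(cohorts=[Cohort(diameter=2.0, count=10, stress_years=4)])
        cell = evaluate_mortality(cell, 0.9, 0.9)
        assert cell.cohorts[0].stress_years == 0

    def test_stepwise_removal_smallest_first(self):
        """Removing the small cohort relieves competition so the large one
        survives the purge."""
        k = K
        big = Cohort(diameter=30.0, count=51, stress_years=4)
        small = Cohort(diameter=2.0, count=200, stress_years=4)
        cell = CohortCell(cohorts=[small, big])
        f = 0.8
        C = competition(cell.biomass(k), k)
        assert f * C < 0.5  # both accrue their 5th stress year
        out = evaluate_mortality(cell, f, C, k)
        diameters = [c.diameter for c in out.cohorts]
        assert diameters == [30.0]
        assert out.cohorts[0].stress_years == 0  # relief broke the chain

    def test_stagnant_cell_skipped(self):
        cell = CohortCell(cohorts=[Cohort(diameter=2.0, count=10, stress_years=4)],
                          stagnant=True)
        out = evaluate_mortality(cell, 0.1, 0.5)
        assert out.cohorts[0].stress_years == 4


class TestStagnation:
    def test_dry_cell_not_stagnant(self):
        assert not stagnation_flag(np.zeros(100), bed_elev=1.0, low_water=-0.5)

    def test_subtidal_cell_not_stagnant(self):
        assert not stagnation_flag(np.full(100, 2.0), bed_elev=-2.0, low_water=-0.5)

    def test_perched_ponded_cell_stagnant(self):
        assert stagnation_flag(np.full(100, 0.2), bed_elev=0.3, low_water=-0.5)

    def test_intermittently_dry_not_stagnant(self):
        series = np.full(100, 0.2)
        series[40] = 0.0
        assert not stagnation_flag(series, bed_elev=0.3, low_water=-0.5)


class TestBaptistRoughness:
    def test_bare_cell(self):
        assert roughness_from_vegetation(CohortCell(), 1.0) == (65.0, 0.0)

    def test_emergent_stem_resistance(self):
        """With an emergent canopy and negligible roots, lambda for the stem
        class equals CD*n exactly and the Chezy stays at the bare value."""
        k = VegConstants(root_diameter=0.0)  # suppress the root class
        cell = CohortCell(cohorts=[Cohort(diameter=10.0, count=100)])
        h = 0.5  # well below the ~5.7 m tree height
        cn, lam = roughness_from_vegetation(cell, h, k)
        n_stem = 100 / k.cell_area * 0.10
        # classes are (stems, roots); roots have n = 0 -> (Cb, 0)
        assert lam == pytest.approx(0.5 * (k.cd_stem * n_stem + 0.0))
        assert cn == pytest.approx(65.0)

    def test_submerged_matches_independent_oracle(self):
        """Submerged-class values agree with an independently coded Baptist
        formula (bed term damped by canopy drag + log overflow term)."""
        cb, cd, n, hv, h = 65.0, 1.0, 0.011, 0.15, 1.0
        cn_oracle = (1.0 / math.sqrt(cb**-2 + cd * n * hv / (2 * 9.81))
                     + math.sqrt(9.81) / 0.41 * math.log(h / hv))
        lam_oracle = cd * n * (hv / h) * (cb / cn_oracle) ** 2
        from mangromorph.vegetation import _baptist_class
        cn, lam = _baptist_class(n, hv, cd, h, cb)
        assert cn == pytest.approx(cn_oracle, rel=1e-12)
        assert lam == pytest.approx(lam_oracle, rel=1e-12)

    def test_resistance_monotone_in_density(self):
        from mangromorph.vegetation import _baptist_class
        lams = [_baptist_class(n, 0.15, 1.0, 1.0, 65.0)[1]
                for n in np.linspace(1e-4, 0.5, 40)]
        assert np.all(np.diff(lams) > 0)
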