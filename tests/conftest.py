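"""Shared fixtures: reduced-scale coupled runs reused by the trend and
property tests (session-scoped — each scenario is simulated once)."""

import numpy as np
import pytest

import mangromorph as mm


@pytest.fixture(scope="session")
def equilibrium_runs_by_tide():
    """20-yr scaled runs at 30 mg/L without waves for the three tidal
    systems (Figure-4-style slope comparison)."""
    out = {}
    for system in ("micro", "meso", "macro"):
        cfg = mm.scaled_scenario(system, years_spinup=20)
        out[system] = mm.run_scenario(cfg, years=20)
    return out


@pytest.fixture(scope="session")
def equilibrium_runs_by_ssc(equilibrium_runs_by_tide):
    """20-yr scaled meso runs across the boundary-SSC levels."""
    out = {30.0: equilibrium_runs_by_tide["meso"]}
    for ssc in (10.0, 50.0):
        cfg = mm.scaled_scenario("meso", ssc_mg_l=ssc, years_spinup=20)
        out[ssc] = mm.run_scenario(cfg, years=20)
    return out


@pytest.fixture(scope="session")
def retreat_runs():
    """Fast-rate (11 mm/yr) linear ramps after spin-up, micro vs macro."""
    out = {}
    for system in ("micro", "macro"):
        cfg = mm.scaled_scenario(system, years_spinup=20, years_slr=20,
                                 slr_total_rise=0.22, slr_name="fast")
        out[system] = mm.run_scenario(cfg)
    return out


@pytest.fixture(scope="session")
def slow_ramp_wave_runs():
    """Slow-rate (2.9 mm/yr) ramps with and without waves, meso system,
    spun up to morphological equilibrium before the ramp."""
    out = {}
    for waves in (False, True):
        cfg = mm.scaled_scenario("meso", waves_on=waves, years_spinup=250,
                                 years_slr=20, slr_total_rise=0.058,
                                 slr_name="slow")
        out[waves] = mm.run_scenario(cfg)
    return out
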