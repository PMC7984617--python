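"""Shared fixtures: a session-wide cache of model simulations.

Long integrations dominate the suite's runtime, and several tests interrogate
the same operating points, so simulated traces are memoized per
(densities, duration, settings) key.
"""

from __future__ import annotations

import pytest

from biopacer import ModelParameters, SimulationConfig, integrate

_CACHE: dict = {}


@pytest.fixture(scope="session")
def sim():
    """Memoized simulation factory keyed on operating point and settings."""

    def _sim(ik1_density: float, if_density: float, duration: float,
             dt: float = 0.02, icat: bool = False,
             concentrations: bool = False, currents: bool = False):
        key = (ik1_density, if_density, duration, dt, icat,
               concentrations, currents)
        if key not in _CACHE:
            params = ModelParameters.from_densities(
                ik1_density, if_density, include_I_CaT=icat)
            cfg = SimulationConfig(duration=duration, dt=dt,
                                   record_concentrations=concentrations,
                                   record_currents=currents)
            _CACHE[key] = integrate(params, cfg, raise_on_failure=False)
        return _CACHE[key]

    return _sim
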