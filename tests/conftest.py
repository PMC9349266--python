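"""Shared fixtures: desk-scale transport runs reused across the suite.

The desk scenario (100 x 200 cells at 25 μm, see ``captrans.scenarios``) is
expensive enough that each release simulation is run once per session and
shared between the ordering and end-to-end tests.
"""

from __future__ import annotations

import pytest

from captrans.model_config import TransportParams
from captrans.porous_flow import solve_flow
from captrans.scenarios import desk_geometry, desk_release


@pytest.fixture(scope="session")
def desk_passive():
    """Passive release curves at the three studied capsule thicknesses (200 s)."""
    return {th: desk_release(th, n_cycles=0) for th in (50, 100, 200)}


@pytest.fixture(scope="session")
def desk_rr():
    """Rapid-release curves keyed by (fc_thickness_um, n_cycles) over 200 s."""
    return {
        (th, n): desk_release(th, n_cycles=n)
        for th in (100, 200)
        for n in (1, 5)
    }


@pytest.fixture(scope="session")
def desk_peak_flow():
    """Desk geometry and Brinkman field at the 2 psi actuation peak."""
    params = TransportParams()
    geometry = desk_geometry(100)
    return geometry, params, solve_flow(geometry, params, params.p_inlet_pa)
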