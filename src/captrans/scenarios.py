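"""Reference scenarios shared by the analysis drivers and the test suite.

The production geometry is the full 5 × 20 mm outer domain.  The desk-scale
scenario shrinks the outer domain to 2.5 × 5 mm at 25 μm spacing (a 100 × 200
cell grid, reservoir 0.5 × 2 mm) so that a 200 s transport simulation with
the finest studied capsule (50 μm, two cells across) runs in seconds while
preserving the layered reservoir/capsule/outer structure and all qualitative
orderings.  The capsule remains by far the dominant transport resistance, so
peri-membrane quantities are insensitive to the truncated outer extent.
"""

from __future__ import annotations

from .drug_transport import ReleaseCurve, simulate_release
from .model_config import ActuationPulse, DomainGeometry, TransportParams, build_geometry
from .porous_flow import FlowField, solve_flow

__all__ = [
    "desk_geometry",
    "desk_flow",
    "desk_release",
    "DESK_OUTER_MM",
    "DESK_RESERVOIR_MM",
    "DESK_SPACING_UM",
]

DESK_OUTER_MM = (2.5, 5.0)
DESK_RESERVOIR_MM = (0.5, 2.0)
DESK_SPACING_UM = 25.0


def desk_geometry(fc_thickness_um: float = 100.0) -> DomainGeometry:
    """Desk-scale three-domain geometry (100 × 200 cells at 25 μm)."""
    return build_geometry(
        fc_thickness_um,
        DESK_SPACING_UM,
        reservoir_extent=DESK_RESERVOIR_MM,
        outer_extent=DESK_OUTER_MM,
    )


def desk_flow(
    fc_thickness_um: float = 100.0, params: TransportParams | None = None
) -> tuple[DomainGeometry, FlowField]:
    """Brinkman field of the desk scenario at peak actuation pressure."""
    params = params or TransportParams()
    geometry = desk_geometry(fc_thickness_um)
    return geometry, solve_flow(geometry, params, params.p_inlet_pa)


def desk_release(
    fc_thickness_um: float = 100.0,
    n_cycles: int = 0,
    t_end: float = 200.0,
    params: TransportParams | None = None,
) -> ReleaseCurve:
    """Release curve of the desk scenario (``n_cycles=0``: passive diffusion)."""
    params = params or TransportParams()
    geometry = desk_geometry(fc_thickness_um)
    pulse = ActuationPulse(n_cycles=n_cycles) if n_cycles > 0 else None
    _, curve = simulate_release(geometry, params, pulse, t_end)
    return curve
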