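"""Physical parameters and discretized geometry of the capsule transport model.

The model describes an implanted drug reservoir separated from the surrounding
tissue fluid by a fibrous capsule (FC) — the dense collagenous layer the
foreign body response deposits around an implant.  The 2D computational domain
has three regions: the drug reservoir, the FC (a thin porous layer wrapped
around the reservoir), and the outer fluid representing the body.

All configuration accepts the mixed units the problem is usually stated in
(diffusivities in μm²/s, pressures in psi, concentrations in mol/mm³);
everything downstream of the constructors runs in SI (m, s, Pa, mol/m³).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_cdt

__all__ = [
    "PSI_TO_PA",
    "Region",
    "TransportParams",
    "ActuationPulse",
    "DomainGeometry",
    "GeometryResolutionError",
    "build_geometry",
    "pressure_in_pascal",
    "pressure_in_psi",
]

#: Fixed conversion constant, 1 psi in pascal.
PSI_TO_PA = 6894.757

_UM = 1e-6
_MM = 1e-3


class Region(enum.IntEnum):
    """Cell labels of the three-domain geometry."""

    RESERVOIR = 0
    CAPSULE = 1
    OUTER = 2


class GeometryResolutionError(ValueError):
    """Capsule layer cannot be resolved on the requested grid."""


def pressure_in_pascal(p_psi: float) -> float:
    """Convert a gauge pressure from psi to Pa (1 psi = 6894.757 Pa)."""
    if not np.isfinite(p_psi):
        raise ValueError("pressure must be finite")
    return float(p_psi) * PSI_TO_PA


def pressure_in_psi(p_pa: float) -> float:
    """Inverse of :func:`pressure_in_pascal`."""
    if not np.isfinite(p_pa):
        raise ValueError("pressure must be finite")
    return float(p_pa) / PSI_TO_PA


@dataclass(frozen=True)
class TransportParams:
    """Physical constants of the three-domain transport model.

    Defaults are the model constants of the reference scenario: insulin-scale
    diffusivity of 855 μm²/s in free fluid and 50 μm²/s inside the capsule,
    capsule permeability 8.9e-16 m² with porosity 0.8, water-like fluid
    (997 kg/m³, 8.9e-4 Pa·s), 2 psi actuation pressure, and unit initial
    reservoir concentration.

    Parameters are stored in the units they are conventionally quoted in;
    the ``*_si`` properties expose SI values for the solvers.
    """

    d_free: float = 855.0   # μm²/s, reservoir and outer fluid
    d_fc: float = 50.0      # μm²/s, fibrous capsule
    k_perm: float = 8.9e-16  # m², capsule permeability
    porosity: float = 0.8   # dimensionless
    rho: float = 997.0      # kg/m³
    mu_visc: float = 8.9e-4  # Pa·s
    p_inlet: float = 2.0    # psi, actuation amplitude
    c0: float = 1.0         # mol/mm³, initial reservoir concentration

    def __post_init__(self) -> None:
        for name in ("d_free", "d_fc", "k_perm", "rho", "mu_visc", "c0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.p_inlet < 0:
            raise ValueError("p_inlet must be >= 0")
        if not 0 < self.porosity <= 1:
            raise ValueError("porosity must lie in (0, 1]")

    @property
    def d_free_si(self) -> float:
        """Free-fluid diffusivity in m²/s."""
        return self.d_free * 1e-12

    @property
    def d_fc_si(self) -> float:
        """Capsule diffusivity in m²/s."""
        return self.d_fc * 1e-12

    @property
    def p_inlet_pa(self) -> float:
        """Actuation pressure amplitude in Pa."""
        return pressure_in_pascal(self.p_inlet)

    @property
    def c0_si(self) -> float:
        """Initial reservoir concentration in mol/m³."""
        return self.c0 * 1e9


@dataclass(frozen=True)
class ActuationPulse:
    """Triangular pressure pulse train applied at the reservoir inlet.

    Each cycle ramps linearly 0 → ``amplitude`` → 0 over ``ramp_duration``
    seconds; ``n_cycles`` cycles repeat at ``cycle_frequency``.  The default
    (2 psi over 1 s) is the rapid-release actuation pulse; in-vivo rapid
    release used 5 such cycles at 1 Hz.
    """

    amplitude: float = 2.0      # psi
    ramp_duration: float = 1.0  # s, total up + down time
    n_cycles: int = 1
    cycle_frequency: float = 1.0  # Hz

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")
        if self.cycle_frequency <= 0:
            raise ValueError("cycle_frequency must be > 0")

    @property
    def amplitude_pa(self) -> float:
        return pressure_in_pascal(self.amplitude)

    @property
    def duration(self) -> float:
        """Time at which the last cycle's ramp has finished (s)."""
        if self.n_cycles == 0:
            return 0.0
        return (self.n_cycles - 1) / self.cycle_frequency + self.ramp_duration


@dataclass(frozen=True)
class DomainGeometry:
    """Cell-centred 2D grid with per-cell region labels.

    The origin sits at the lower-left corner of the outer rectangle; row index
    ``j`` increases with y (away from the device), column index ``i`` with x.
    The reservoir abuts the bottom boundary (where the pressure inlet acts)
    and the capsule is a uniform-thickness shell over the reservoir's exposed
    faces.
    """

    fc_thickness: float          # μm
    grid_spacing: float          # μm
    outer_extent: tuple[float, float]      # (height, width) mm
    reservoir_extent: tuple[float, float]  # (height, width) mm
    region_labels: np.ndarray = field(repr=False)
    degenerate: bool = False
    flagged_thickness: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_labels.shape

    @property
    def h(self) -> float:
        """Grid spacing in metres."""
        return self.grid_spacing * _UM

    @property
    def cell_area(self) -> float:
        """Cell area in m² (unit depth)."""
        return self.h * self.h

    def mask(self, region: Region) -> np.ndarray:
        return self.region_labels == int(region)

    @property
    def reservoir_mask(self) -> np.ndarray:
        return self.mask(Region.RESERVOIR)

    @property
    def capsule_mask(self) -> np.ndarray:
        return self.mask(Region.CAPSULE)

    @property
    def outer_mask(self) -> np.ndarray:
        return self.mask(Region.OUTER)

    @property
    def inlet_columns(self) -> np.ndarray:
        """Column indices of the bottom-boundary inlet (reservoir footprint)."""
        return np.flatnonzero(self.reservoir_mask[0])

    def region_area(self, region: Region) -> float:
        """Region area in m²."""
        return float(self.mask(region).sum()) * self.cell_area


def _cells(extent_mm: float, spacing_um: float) -> int:
    n = int(round(extent_mm * _MM / (spacing_um * _UM)))
    if n < 1:
        raise ValueError(f"extent {extent_mm} mm unresolvable at {spacing_um} μm")
    return n


def build_geometry(
    fc_thickness: float,
    grid_spacing: float,
    reservoir_extent: tuple[float, float] = (1.0, 6.0),
    outer_extent: tuple[float, float] = (5.0, 20.0),
) -> DomainGeometry:
    """Build the labelled three-domain grid.

    Parameters
    ----------
    fc_thickness : float
        Capsule layer thickness in μm.  Values outside the studied 50–200 μm
        range are allowed but flagged; 0 yields a degenerate two-domain
        geometry with a warning.
    grid_spacing : float
        Cell size in μm; the capsule must span at least two cells.
    reservoir_extent, outer_extent : (height, width) in mm
        Reservoir rectangle (bottom-centred) and total domain rectangle.

    The capsule shell is drawn at uniform chessboard (L∞) distance from the
    reservoir so its cell thickness is the same on the top face, side faces
    and corners.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    if fc_thickness < 0:
        raise ValueError("fc_thickness must be >= 0")
    ny, nx = (_cells(outer_extent[0], grid_spacing), _cells(outer_extent[1], grid_spacing))
    nry, nrx = (_cells(reservoir_extent[0], grid_spacing), _cells(reservoir_extent[1], grid_spacing))
    if nrx > nx or nry >= ny:
        raise ValueError("reservoir does not fit inside the outer domain")

    degenerate = fc_thickness == 0
    n_fc = int(round(fc_thickness / grid_spacing))
    if not degenerate and fc_thickness < 2 * grid_spacing:
        raise GeometryResolutionError(
            f"capsule of {fc_thickness} μm needs grid_spacing <= {fc_thickness / 2} μm "
            f"(two cells across the layer); got {grid_spacing} μm"
        )
    flagged = not degenerate and not (50.0 <= fc_thickness <= 200.0)
    if flagged:
        warnings.warn(
            f"fc_thickness {fc_thickness} μm lies outside the studied 50-200 μm range",
            stacklevel=2,
        )
    if degenerate:
        warnings.warn("fc_thickness 0: degenerate two-domain geometry", stacklevel=2)

    labels = np.full((ny, nx), int(Region.OUTER), dtype=np.int8)
    i0 = (nx - nrx) // 2
    reservoir = np.zeros((ny, nx), dtype=bool)
    reservoir[:nry, i0:i0 + nrx] = True
    labels[reservoir] = int(Region.RESERVOIR)

    if n_fc > 0:
        side_margin_ok = (i0 == 0 or i0 - n_fc >= 0) and (
            i0 + nrx == nx or i0 + nrx + n_fc <= nx
        )  # full-width reservoirs (1D columns) need no side shell
        if nry + n_fc >= ny or not side_margin_ok:
            raise ValueError("capsule shell does not fit inside the outer domain")
        dist = distance_transform_cdt(~reservoir, metric="chessboard")
        labels[(dist > 0) & (dist <= n_fc)] = int(Region.CAPSULE)

    return DomainGeometry(
        fc_thickness=float(fc_thickness),
        grid_spacing=float(grid_spacing),
        outer_extent=(float(outer_extent[0]), float(outer_extent[1])),
        reservoir_extent=(float(reservoir_extent[0]), float(reservoir_extent[1])),
        region_labels=labels,
        degenerate=degenerate,
        flagged_thickness=flagged,
    )
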