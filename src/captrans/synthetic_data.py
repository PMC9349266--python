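"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage gets an input generator that emulates the statistical
structure of the corresponding experimental data — blood-glucose responses
with capsule-dependent attenuation and lag, fibre-texture images with
controllable orientation concentration, band masks with programmed thickness,
and blob masks with a programmed positive fraction — so parameter-recovery
tests need no external data.  All generators are deterministic given their
seed and record (seed, parameters) in the returned metadata.

The glucose generator uses an explicit pharmacodynamic coupling: the
glucose-lowering effect is proportional to the cumulative drug amount that
has crossed the capsule (from a transport :class:`ReleaseCurve` or a
parametric lag/attenuation pair).  This coupling is a modelling choice of
this package, made to exercise the ITT metric pipeline with the qualitative
response shapes seen in vivo (rapid drop then recovery for responsive
devices, blunted delayed drop for encapsulated ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.draw import line_aa

from .drug_transport import ReleaseCurve
from .itt_analysis import ITT_SAMPLE_TIMES, BGSeries

__all__ = [
    "BGGeneratorParams",
    "FiberFieldParams",
    "BGCohort",
    "FiberImage",
    "CapsuleMaskResult",
    "PointMaskResult",
    "parametric_effect",
    "effect_from_release",
    "k_insulin_for_drop",
    "gen_bg_curves",
    "gen_fiber_image",
    "gen_capsule_mask",
    "gen_point_mask",
    "gen_thickness_efficacy_pairs",
]


def parametric_effect(
    attenuation: float, lag_min: float, tau_min: float = 15.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Saturating insulin-effect input with onset lag.

    ``E(t) = attenuation * (1 - exp(-(t - lag)/tau))`` for ``t > lag``, else
    0.  ``attenuation`` in [0, 1] encodes how much the capsule blunts the
    effect; ``lag_min`` the transport delay across it.
    """

    def effect(t_min):
        t = np.asarray(t_min, dtype=float)
        return attenuation * np.clip(1.0 - np.exp(-(t - lag_min) / tau_min), 0.0, None)

    return effect


def effect_from_release(
    curve: ReleaseCurve,
    scale: float = 1.0,
    reference_amount: float | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Effect input proportional to the cumulative drug past the capsule.

    The outside-capsule amount is normalized by ``reference_amount`` (its own
    final value when omitted) and scaled by ``scale``, clipped to [0, 1].
    Passing a common reference for several curves preserves their relative
    amplitudes — e.g. a thick-capsule curve yields a proportionally weaker
    effect than a thin-capsule one.
    """
    ref = reference_amount if reference_amount is not None else curve.outside_fc_amount[-1]
    if ref <= 0:
        return lambda t_min: np.zeros_like(np.asarray(t_min, dtype=float))

    def effect(t_min):
        t_s = np.asarray(t_min, dtype=float) * 60.0
        raw = np.interp(t_s, curve.times, curve.outside_fc_amount) / ref
        return np.clip(scale * raw, 0.0, 1.0)

    return effect


def k_insulin_for_drop(
    target_drop: float, effect_level: float = 1.0, k_recovery: float = 0.015
) -> float:
    """Insulin rate constant giving a programmed steady-state BG drop.

    At constant effect E the glucose ODE settles at a fractional drop
    ``k_i E / (k_i E + k_r)``; inverting gives the ``k_insulin`` needed for
    ``target_drop`` (fraction in (0, 1))."""
    if not 0 < target_drop < 1:
        raise ValueError("target_drop must lie in (0, 1)")
    if effect_level <= 0:
        raise ValueError("effect_level must be > 0")
    return k_recovery * target_drop / ((1.0 - target_drop) * effect_level)


@dataclass(frozen=True)
class BGGeneratorParams:
    """Conditions of the synthetic insulin-tolerance test.

    Defaults reflect the in-vivo study conditions: cohorts of 5 animals,
    fasted murine baseline glucose ~150 mg/dL, glucometer-scale measurement
    noise of 5 mg/dL, and rate constants giving a ~70% steady drop with an
    onset time constant of ~20 min for an unencapsulated device.
    """

    baseline_mgdl: float = 150.0
    k_insulin: float = 0.035     # 1/min per unit effect
    k_recovery: float = 0.015    # 1/min
    effect: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: parametric_effect(1.0, 0.0)
    )
    noise_sd: float = 5.0        # mg/dL
    n_animals: int = 5
    seed: int = 0
    animal_sigma: float = 0.15   # lognormal sd of per-animal k_insulin
    group: str = "synthetic"
    timepoint_week: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mgdl <= 0:
            raise ValueError("baseline must be positive")
        for name in ("k_insulin", "k_recovery", "noise_sd", "animal_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass(frozen=True)
class FiberFieldParams:
    """Synthetic fibre-texture image conditions (polarised-light stand-in)."""

    n_fibers: int = 200
    kappa: float = 10.0        # von Mises orientation concentration
    fiber_width: int = 3       # px
    image_size: int = 256      # px
    fiber_length: float = 0.5  # fraction of image size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_fibers < 1 or self.image_size < 16:
            raise ValueError("degenerate fibre field")


@dataclass(frozen=True)
class BGCohort:
    series: list[BGSeries]
    meta: dict


@dataclass(frozen=True)
class FiberImage:
    image: np.ndarray
    true_kappa: float
    meta: dict


@dataclass(frozen=True)
class CapsuleMaskResult:
    mask: np.ndarray
    truth_um: np.ndarray  # programmed thickness per column
    meta: dict


@dataclass(frozen=True)
class PointMaskResult:
    mask: np.ndarray
    true_fraction_actual: float
    meta: dict


def gen_bg_curves(params: BGGeneratorParams) -> BGCohort:
    """Simulate a cohort of ITT blood-glucose series.

    Per animal, glucose follows ``dG/dt = -k_i E(t) G + k_r (G_b - G)`` with
    a lognormal random effect on ``k_i`` and additive Gaussian measurement
    noise at the standard ITT sampling times; fine-step Euler integration
    (dt = 0.05 min) keeps the ODE solution accurate to well below the noise
    scale.
    """
    rng = np.random.default_rng(params.seed)
    dt = 0.05
    t_grid = np.arange(0.0, ITT_SAMPLE_TIMES[-1] + dt / 2, dt)
    e_grid = np.asarray(params.effect(t_grid), dtype=float)
    series = []
    for a in range(params.n_animals):
        k_i = params.k_insulin * rng.lognormal(0.0, params.animal_sigma) \
            if params.animal_sigma > 0 else params.k_insulin
        g = np.empty_like(t_grid)
        g[0] = params.baseline_mgdl
        for n in range(1, t_grid.size):
            dgdt = (-k_i * e_grid[n - 1] * g[n - 1]
                    + params.k_recovery * (params.baseline_mgdl - g[n - 1]))
            g[n] = g[n - 1] + dt * dgdt
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite glucose trajectory")
        sampled = np.interp(ITT_SAMPLE_TIMES, t_grid, g)
        noise = rng.normal(0.0, params.noise_sd, size=sampled.size) \
            if params.noise_sd > 0 else 0.0
        glucose = np.maximum(sampled + noise, 1.0)
        series.append(
            BGSeries(
                animal_id=f"{params.group}-{a:02d}",
                group=params.group,
                timepoint_week=params.timepoint_week,
                times=ITT_SAMPLE_TIMES.copy(),
                glucose=glucose,
            )
        )
    meta = {
        "seed": params.seed,
        "n_animals": params.n_animals,
        "baseline_mgdl": params.baseline_mgdl,
        "k_insulin": params.k_insulin,
        "k_recovery": params.k_recovery,
        "noise_sd": params.noise_sd,
        "animal_sigma": params.animal_sigma,
    }
    return BGCohort(series=series, meta=meta)


def gen_fiber_image(params: FiberFieldParams) -> FiberImage:
    """Render an anti-aliased fibre field with von Mises orientations.

    Fibre axes are drawn from a von Mises distribution on the doubled angle
    (axial statistics, π-periodic); ``kappa = 0`` gives an isotropic field,
    large kappa near-parallel fibres.
    """
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    img = np.zeros((n, n), dtype=float)
    half_len = 0.5 * params.fiber_length * n
    for _ in range(params.n_fibers):
        theta = 0.5 * rng.vonmises(0.0, params.kappa) if params.kappa > 0 \
            else rng.uniform(-np.pi / 2, np.pi / 2)
        cy, cx = rng.uniform(0, n, size=2)
        dy, dx = np.sin(theta) * half_len, np.cos(theta) * half_len
        # perpendicular offsets build up the fibre width
        py, px = -np.cos(theta), np.sin(theta)
        for w in range(params.fiber_width):
            off = w - (params.fiber_width - 1) / 2.0
            r0 = int(round(cy - dy + off * py))
            c0 = int(round(cx - dx + off * px))
            r1 = int(round(cy + dy + off * py))
            c1 = int(round(cx + dx + off * px))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            img[rr[keep], cc[keep]] += val[keep]
    img = np.clip(img, 0.0, 1.0)
    meta = {"seed": params.seed, "kappa": params.kappa, "n_fibers": params.n_fibers,
            "fiber_width": params.fiber_width, "image_size": params.image_size}
    return FiberImage(image=img, true_kappa=params.kappa, meta=meta)


def gen_capsule_mask(
    thickness_profile: float | np.ndarray,
    pixel_size: float,
    waviness: float = 0.0,
    image_size: tuple[int, int] = (256, 512),
    seed: int = 0,
) -> CapsuleMaskResult:
    """Horizontal band mask with programmed (possibly varying) thickness.

    ``thickness_profile`` is μm, scalar or per-column; ``waviness`` is the
    midline sine amplitude in px (random phase from ``seed``).  The band is
    clipped against the image, so profiles must fit inside ``image_size``.
    """
    H, W = image_size
    profile = np.broadcast_to(np.asarray(thickness_profile, dtype=float), (W,)).copy()
    if np.any(profile <= 0):
        raise ValueError("thickness must be positive")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(W)
    mid = H / 2.0 + waviness * np.sin(2 * np.pi * x / (W / 2.0) + phase)
    # widen the vertical cross-section so thickness along the local band
    # normal equals the programmed profile regardless of midline slope
    slope = np.gradient(mid)
    half_px = profile / pixel_size / 2.0 * np.sqrt(1.0 + slope**2)
    rows = np.arange(H)[:, None]
    mask = np.abs(rows - mid[None, :]) < half_px[None, :]
    if mask.all(axis=0).any():
        raise ValueError("band does not fit inside the image")
    meta = {"seed": seed, "pixel_size": pixel_size, "waviness": waviness,
            "image_size": image_size}
    return CapsuleMaskResult(mask=mask, truth_um=profile, meta=meta)


def gen_point_mask(
    true_fraction: float,
    image_size: int = 256,
    blob_scale: float = 8.0,
    seed: int = 0,
) -> PointMaskResult:
    """Blob field thresholded to a programmed positive-pixel fraction.

    Smooth Gaussian-filtered noise is thresholded at the matching quantile,
    so the realized fraction is within rounding of the target; the realized
    value is returned as ground truth.
    """
    if not 0 <= true_fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    meta = {"seed": seed, "blob_scale": blob_scale, "image_size": image_size,
            "target_fraction": true_fraction}
    if true_fraction == 0.0:
        return PointMaskResult(np.zeros((image_size, image_size), bool), 0.0, meta)
    if true_fraction == 1.0:
        return PointMaskResult(np.ones((image_size, image_size), bool), 1.0, meta)
    from scipy.ndimage import gaussian_filter

    fieldv = gaussian_filter(rng.normal(size=(image_size, image_size)), blob_scale)
    thr = np.quantile(fieldv, 1.0 - true_fraction)
    mask = fieldv > thr
    return PointMaskResult(mask, float(mask.mean()), meta)


def gen_thickness_efficacy_pairs(
    r: float = -0.9,
    n: int = 200,
    seed: int = 0,
    thickness_mean_mm: float = 0.4,
    thickness_sd_mm: float = 0.15,
    drop_mean_pct: float = 45.0,
    drop_sd_pct: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired (capsule thickness, max BG drop) samples with programmed Pearson r."""
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    thickness = thickness_mean_mm + thickness_sd_mm * z1
    drops = drop_mean_pct + drop_sd_pct * z2
    meta = {"seed": seed, "r": r, "n": n}
    return thickness, drops, meta
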