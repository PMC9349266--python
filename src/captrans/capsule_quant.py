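"""Quantification estimators for ex-vivo capsule images and masks.

Implements the 2D measurement contracts of the histology / µCT analysis:
stereological point counting (area fraction from a random-offset square
grid), unbiased counting-frame vessel density with the forbidden-line rule,
relative marker volume, structure-tensor orientation coherency of collagen
fibres, wall thickness of a segmented capsule band, and background-subtracted
radiodensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.feature import structure_tensor

__all__ = [
    "GridCountResult",
    "CoherencyResult",
    "ThicknessResult",
    "point_grid_fraction",
    "relative_volume",
    "vessel_density",
    "coherency",
    "capsule_thickness",
    "radiodensity",
]


@dataclass(frozen=True)
class GridCountResult:
    """Stereological point-count outcome."""

    n_positive_hits: int
    n_total_points: int
    grid_spacing: float  # μm
    offset_seed: int

    @property
    def fraction(self) -> float:
        return self.n_positive_hits / self.n_total_points


@dataclass(frozen=True)
class CoherencyResult:
    """Structure-tensor coherency per ROI (1 = aligned, 0 = isotropic)."""

    coherency: float
    roi_box: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    tensor_sigma: float


@dataclass(frozen=True)
class ThicknessResult:
    """Wall thickness of a band-like mask, measured along its midline."""

    mean_um: float
    per_location_um: np.ndarray          # μm, one value per midline pixel
    midline: np.ndarray                  # (n, 2) row/col coordinates
    pixel_size: float


def point_grid_fraction(
    mask: np.ndarray,
    grid_spacing: float,
    pixel_size: float,
    seed: int,
) -> GridCountResult:
    """Area fraction of a binary mask by random-offset square-grid counting.

    A square point grid of pitch ``grid_spacing`` (μm; 100 μm pitch gives the
    classic 10,000 μm² grid cell) is overlaid with a uniform random offset in
    ``[0, spacing)²`` drawn from ``seed``; points landing on positive pixels
    (pixel-membership rule, boundary pixels count as hits) are counted.  The
    grid wraps toroidally so the point count is offset-independent, which
    makes the estimator exactly unbiased for the pixel area fraction under
    the random offset.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    if grid_spacing < pixel_size:
        raise ValueError("grid_spacing must be >= pixel_size")
    rng = np.random.default_rng(seed)
    pitch = grid_spacing / pixel_size  # px
    n_rows = int(mask.shape[0] / pitch)
    n_cols = int(mask.shape[1] / pitch)
    if n_rows == 0 or n_cols == 0:
        raise ValueError("grid places no points inside the image")
    # offset uniform over the full extent with toroidal wrap: every pixel is
    # sampled with identical probability n_points/extent
    oy = rng.uniform(0.0, mask.shape[0])
    ox = rng.uniform(0.0, mask.shape[1])
    rows = np.mod(oy + np.arange(n_rows) * pitch, mask.shape[0])
    cols = np.mod(ox + np.arange(n_cols) * pitch, mask.shape[1])
    rr, cc = np.meshgrid(rows.astype(int), cols.astype(int), indexing="ij")
    hits = int(mask[rr, cc].sum())
    return GridCountResult(
        n_positive_hits=hits,
        n_total_points=rr.size,
        grid_spacing=float(grid_spacing),
        offset_seed=int(seed),
    )


def relative_volume(
    volume_fraction: float, fc_thickness_mm: float, mode: str = "verbatim"
) -> float:
    """Relative marker volume (mm³) per unit 1 mm × 1 mm capsule area.

    ``mode="verbatim"`` evaluates the published formula
    ``fraction / thickness × 1 mm²``; ``mode="prose"`` evaluates the
    alternative reading ``fraction × thickness × 1 mm²`` (fraction of the
    volume defined by thickness times unit area).  The two disagree
    dimensionally; both are exposed, neither is silently corrected.
    """
    if not 0 <= volume_fraction <= 1:
        raise ValueError("volume_fraction must lie in [0, 1]")
    if fc_thickness_mm <= 0:
        raise ValueError("fc_thickness must be > 0")
    if mode == "verbatim":
        return volume_fraction / fc_thickness_mm * 1.0 * 1.0
    if mode == "prose":
        return volume_fraction * fc_thickness_mm * 1.0 * 1.0
    raise ValueError("mode must be 'verbatim' or 'prose'")


def vessel_density(
    vessel_marks: np.ndarray,
    frames: np.ndarray,
    mode: str = "default",
    grid_points_per_frame: int | None = None,
) -> float:
    """Vessel numerical density from unbiased counting frames.

    ``vessel_marks`` is an (n, 2) array of (x, y) positions; ``frames`` an
    (m, 4) array of (x0, y0, x1, y1) rectangles of equal area.  Following the
    forbidden-line rule (Gundersen convention, forbidden lines on the left
    and bottom edges), a vessel inside a frame is counted unless it touches
    the left or bottom edge; the top and right acceptance edges count.

    ``mode="default"`` returns the unbiased density
    ``sum(counts) / (n_frames × frame_area)`` in vessels per μm² (frame
    coordinates in μm).  ``mode="verbatim"`` evaluates the published product
    ``CN × Cpts × A`` for traceability only — it is not a density
    (``grid_points_per_frame`` supplies Cpts per frame).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] == 0:
        raise ValueError("at least one counting frame required")
    areas = (frames[:, 2] - frames[:, 0]) * (frames[:, 3] - frames[:, 1])
    if np.any(areas <= 0):
        raise ValueError("degenerate counting frame")
    if not np.allclose(areas, areas[0]):
        raise ValueError("frames must have equal area")
    marks = np.asarray(vessel_marks, dtype=float).reshape(-1, 2)

    total = 0
    for x0, y0, x1, y1 in frames:
        if marks.size:
            inside = (
                (marks[:, 0] >= x0) & (marks[:, 0] <= x1)
                & (marks[:, 1] >= y0) & (marks[:, 1] <= y1)
            )
            forbidden = (marks[:, 0] == x0) | (marks[:, 1] == y0)
            total += int((inside & ~forbidden).sum())
    if mode == "default":
        return total / (frames.shape[0] * float(areas[0]))
    if mode == "verbatim":
        if grid_points_per_frame is None:
            raise ValueError("verbatim mode needs grid_points_per_frame")
        cpts = grid_points_per_frame * frames.shape[0]
        return float(total * cpts * areas[0])
    raise ValueError("mode must be 'default' or 'verbatim'")


def coherency(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    tensor_sigma: float = 2.0,
) -> CoherencyResult:
    """Orientation coherency of an ROI from the averaged structure tensor.

    The gradient structure tensor is smoothed with a Gaussian of width
    ``tensor_sigma`` pixels and averaged over the ROI; coherency is the
    eigenvalue contrast (λ1 − λ2)/(λ1 + λ2) with λ1 ≥ λ2 ≥ 0 (0 by
    convention for a flat image).
    """
    image = np.asarray(image, dtype=float)
    if roi is None:
        roi = (0, 0, image.shape[0], image.shape[1])
    r0, c0, r1, c1 = roi
    if r1 - r0 < 8 or c1 - c0 < 8:
        raise ValueError("ROI must be at least 8x8 px")
    # reflective padding: zero-padding would fabricate border gradients
    Arr, Arc, Acc = structure_tensor(image, sigma=tensor_sigma, order="rc", mode="reflect")
    jrr = Arr[r0:r1, c0:c1].mean()
    jrc = Arc[r0:r1, c0:c1].mean()
    jcc = Acc[r0:r1, c0:c1].mean()
    trace = jrr + jcc
    # flat-image convention: gradient energy at roundoff scale counts as zero
    flat_tol = 1e-14 * max(1.0, float(np.ptp(image)) ** 2)
    if trace <= flat_tol:
        coh = 0.0
    else:
        coh = float(np.sqrt((jrr - jcc) ** 2 + 4.0 * jrc**2) / trace)
    return CoherencyResult(coherency=coh, roi_box=tuple(roi), tensor_sigma=tensor_sigma)


def capsule_thickness(capsule_mask: np.ndarray, pixel_size: float) -> ThicknessResult:
    """Wall thickness of a band-like binary mask.

    The 2D analogue of a µCT wall-thickness analysis on a segmented capsule:
    the midline is the ridge of the Euclidean distance transform (per
    position along the band's principal axis, the mask pixel farthest from
    background), and local thickness is the mask chord through each midline
    point along the local midline normal.  Positions within one maximal
    inscribed radius of the band ends are discarded to avoid end effects;
    ``pixel_size`` (μm/px) converts to μm.
    """
    mask = np.asarray(capsule_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty capsule mask")
    edt = distance_transform_edt(mask)
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    centred = pts - pts.mean(axis=0)
    # principal (long) axis of the band
    _, vecs = np.linalg.eigh(centred.T @ centred)
    axis = vecs[:, -1]
    s = centred @ axis
    bins = np.round(s).astype(int)
    d = edt[ys, xs]
    order = np.lexsort((-d, bins))
    b_sorted = bins[order]
    first = np.ones(b_sorted.size, dtype=bool)
    first[1:] = b_sorted[1:] != b_sorted[:-1]
    ridge = order[first]  # max-EDT pixel per bin, sorted along the axis
    rmax = d.max()
    keep = (s[ridge] >= s.min() + rmax) & (s[ridge] <= s.max() - rmax)
    ridge = ridge[keep]
    if ridge.size == 0:
        raise ValueError("mask is not band-like (no midline after end trimming)")

    mid = pts[ridge]
    # local tangent from neighbouring ridge points, normal perpendicular
    k = min(5, max(1, mid.shape[0] - 1))
    lo = np.maximum(np.arange(mid.shape[0]) - k, 0)
    hi = np.minimum(np.arange(mid.shape[0]) + k, mid.shape[0] - 1)
    tang = mid[hi] - mid[lo]
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    norm /= np.maximum(np.linalg.norm(norm, axis=1, keepdims=True), 1e-12)

    step = 0.25
    max_steps = int(np.ceil((2 * rmax + 4) / step))
    ny, nx = mask.shape
    per_loc = np.empty(mid.shape[0])
    for m in range(mid.shape[0]):
        chord = 0.0
        for sign in (1.0, -1.0):
            for q in range(1, max_steps + 1):
                r = mid[m, 0] + sign * norm[m, 0] * q * step
                c = mid[m, 1] + sign * norm[m, 1] * q * step
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < ny and 0 <= ci < nx) or not mask[ri, ci]:
                    chord += (q - 0.5) * step
                    break
            else:
                chord += max_steps * step
        per_loc[m] = chord * pixel_size
    return ThicknessResult(
        mean_um=float(per_loc.mean()),
        per_location_um=per_loc,
        midline=mid.astype(int),
        pixel_size=float(pixel_size),
    )


def radiodensity(
    image: np.ndarray,
    sample_rects: np.ndarray,
    background_rects: np.ndarray,
) -> float:
    """Background-subtracted mean intensity over sample rectangles.

    Rectangles are (r0, c0, r1, c1), half-open, and must lie inside the
    image; overlapping sample/background rectangles are flagged with a
    warning.  Returns mean(sample) − mean(background).
    """
    image = np.asarray(image, dtype=float)

    def _means(rects):
        rects = np.atleast_2d(np.asarray(rects, dtype=int))
        if rects.shape[0] == 0:
            raise ValueError("at least one rectangle of each kind required")
        vals = []
        for r0, c0, r1, c1 in rects:
            if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
                raise ValueError("rectangle outside image")
            vals.append(image[r0:r1, c0:c1].mean())
        return rects, float(np.mean(vals))

    srects, smean = _means(sample_rects)
    brects, bmean = _means(background_rects)
    for r0, c0, r1, c1 in srects:
        for q0, d0, q1, d1 in brects:
            if r0 < q1 and q0 < r1 and c0 < d1 and d0 < c1:
                warnings.warn("sample and background rectangles overlap", stacklevel=2)
    return smean - bmean
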