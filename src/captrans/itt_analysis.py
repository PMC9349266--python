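"""Pharmacodynamic metrics from insulin-tolerance-test blood-glucose series.

The insulin transport test (ITT) injects a fixed insulin dose into the
implanted reservoir and follows blood glucose (BG) over 120 min (samples at
0, 15, 30, 45, 60, 75, 90, 120 min).  As the fibrous capsule thickens, less
insulin crosses into circulation, so the BG drop is blunted and delayed.
The metrics quantify this: maximum % drop below baseline (effect size), time
to a 30% drop (speed of effect, censored at 120 min for non-responders), and
the area under the %-of-baseline curve (AUC, lower = stronger overall
effect).  Group comparisons use pooled two-sample t-tests (one-tailed for BG
metrics), with Levene's test for equality of variances and a Bonferroni
threshold alpha/m for m comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ITT_SAMPLE_TIMES",
    "BGSeries",
    "ITTMetrics",
    "StepFunction",
    "ComparisonResult",
    "GroupComparisonReport",
    "normalize_bg",
    "max_drop",
    "time_to_drop",
    "auc_bg",
    "compute_metrics",
    "cumulative_incidence",
    "compare_groups",
    "thickness_efficacy_correlation",
]

#: Standard ITT sampling schedule (min).
ITT_SAMPLE_TIMES = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0])

#: Observation window (min); non-responders are censored here.
ITT_WINDOW = 120.0


@dataclass(frozen=True)
class BGSeries:
    """One animal's blood-glucose time course during an ITT."""

    animal_id: str
    group: str
    timepoint_week: float
    times: np.ndarray    # min, strictly increasing from 0
    glucose: np.ndarray  # mg/dL

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        if t.size != g.size or t.size < 2:
            raise ValueError("times and glucose must be equal-length (n >= 2)")
        if t[0] != 0:
            raise ValueError("series must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("glucose values must be positive")

    @property
    def baseline(self) -> float:
        return float(self.glucose[0])


@dataclass(frozen=True)
class ITTMetrics:
    """Derived effect metrics for one series."""

    animal_id: str
    group: str
    timepoint_week: float
    max_drop_pct: float
    time_to_drop: float   # min (censoring time when censored)
    censored: bool
    auc: float            # %·min


def normalize_bg(series: BGSeries) -> np.ndarray:
    """Percent-of-baseline BG values (100 at time 0)."""
    if series.baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * series.glucose / series.baseline


def max_drop(series: BGSeries) -> float:
    """Maximum % drop below baseline over the observation window."""
    return float(100.0 - normalize_bg(series).min())


def time_to_drop(series: BGSeries, drop_pct: float = 30.0) -> tuple[float, bool]:
    """First time (min) BG falls to ``100 - drop_pct`` percent of baseline.

    Linearly interpolated between adjacent samples; exact sample times are
    returned when the level is hit at a sample.  Returns
    ``(ITT_WINDOW, True)`` when the drop is never achieved (censored).
    """
    if not 0 < drop_pct < 100:
        raise ValueError("drop_pct must lie in (0, 100)")
    pct = normalize_bg(series)
    level = 100.0 - drop_pct
    below = np.flatnonzero(pct <= level)
    if below.size == 0:
        return ITT_WINDOW, True
    k = below[0]
    if pct[k] == level or k == 0:
        return float(series.times[k]), False
    t0, t1 = series.times[k - 1], series.times[k]
    p0, p1 = pct[k - 1], pct[k]
    return float(t0 + (level - p0) / (p1 - p0) * (t1 - t0)), False


def auc_bg(series: BGSeries) -> float:
    """Trapezoidal area under the %-of-baseline curve over 0–120 min (%·min).

    A series that stops short of 120 min is integrated over its available
    span with a warning.
    """
    pct = normalize_bg(series)
    if series.times[-1] < ITT_WINDOW:
        warnings.warn(
            f"series {series.animal_id} ends at {series.times[-1]} min; "
            f"AUC computed over the available span",
            stacklevel=2,
        )
    return float(np.trapezoid(pct, series.times))


def compute_metrics(series: BGSeries, drop_pct: float = 30.0) -> ITTMetrics:
    """All ITT metrics for one series."""
    ttd, censored = time_to_drop(series, drop_pct)
    return ITTMetrics(
        animal_id=series.animal_id,
        group=series.group,
        timepoint_week=series.timepoint_week,
        max_drop_pct=max_drop(series),
        time_to_drop=ttd,
        censored=censored,
        auc=auc_bg(series),
    )


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-decreasing step function on [0, window]."""

    event_times: np.ndarray
    values: np.ndarray
    window: float = ITT_WINDOW

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[0.0], self.values])
        return vals[idx]


def cumulative_incidence(
    results: list[tuple[float, bool]], window: float = ITT_WINDOW
) -> StepFunction:
    """Empirical cumulative incidence of achieving the BG drop.

    ``results`` are ``(time, censored)`` pairs per animal; the curve steps by
    1/n at each event time and censored animals never contribute an event.
    """
    if len(results) == 0:
        raise ValueError("at least one animal required")
    n = len(results)
    events = np.sort([t for t, cens in results if not cens])
    frac = np.arange(1, events.size + 1) / n
    # collapse ties to the last (highest) step at each distinct time
    keep = np.append(np.diff(events) > 0, True) if events.size else np.array([], bool)
    return StepFunction(events[keep], frac[keep], window)


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    t_stat: float
    p_value: float
    levene_stat: float
    levene_p: float
    significant: bool
    skipped: bool = False
    note: str = ""


@dataclass(frozen=True)
class GroupComparisonReport:
    alpha: float
    m_comparisons: int
    threshold: float     # Bonferroni-corrected alpha/m
    tails: str
    direction: str
    comparisons: list[ComparisonResult] = field(default_factory=list)


def compare_groups(
    groups: dict[str, np.ndarray],
    tails: str = "one",
    direction: str = "greater",
    alpha: float = 0.05,
    m_comparisons: int | None = None,
) -> GroupComparisonReport:
    """Pairwise pooled t-tests between groups with Bonferroni correction.

    ``direction`` applies to one-tailed tests and states the alternative for
    the first-named group of each pair (``"greater"``: its mean is
    hypothesized larger).  Variance equality is reported via Levene's test.
    Groups with zero variance and very small n are flagged and skipped.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = m_comparisons if m_comparisons is not None else len(pairs)
    threshold = alpha / m
    alternative = "two-sided" if tails == "two" else direction

    out = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if (np.var(xa) == 0 or np.var(xb) == 0) and min(xa.size, xb.size) < 8:
            out.append(
                ComparisonResult(a, b, np.nan, np.nan, np.nan, np.nan,
                                 significant=False, skipped=True,
                                 note="zero within-group variance at small n")
            )
            continue
        lev = stats.levene(xa, xb)
        tt = stats.ttest_ind(xa, xb, equal_var=True, alternative=alternative)
        out.append(
            ComparisonResult(a, b, float(tt.statistic), float(tt.pvalue),
                             float(lev.statistic), float(lev.pvalue),
                             significant=bool(tt.pvalue < threshold))
        )
    return GroupComparisonReport(
        alpha=alpha, m_comparisons=m, threshold=threshold, tails=tails,
        direction=alternative, comparisons=out,
    )


def thickness_efficacy_correlation(
    thickness_mm: np.ndarray, max_drop_pct: np.ndarray
) -> float:
    """Pearson correlation between capsule thickness and insulin efficacy.

    A strongly negative r reproduces the inverse relationship between capsule
    thickness and the maximum BG drop.
    """
    x = np.asarray(thickness_mm, dtype=float)
    y = np.asarray(max_drop_pct, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in thickness or efficacy")
    return float(stats.pearsonr(x, y).statistic)
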