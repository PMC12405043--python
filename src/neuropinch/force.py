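"""Force steadiness metrics for trapezoidal isometric contractions.

A trapezoidal pinch trial ramps to a submaximal target (a fraction of the
participant's maximal voluntary contraction, MVC), holds it isometrically,
and ramps back down.  Steadiness is quantified as the coefficient of
variation (COV) of force *relative to the target force* — not the trial
mean — so a participant who holds a steady but offset force is still
rewarded for steadiness, and the measure is comparable across targets.

Two COV variants are used downstream:

* the hold-phase COV over the 6 s centred on the midpoint of the hold,
  used for group comparisons of steadiness;
* the steadiest 4 s window found by an exhaustive sliding search (50 ms
  steps), which anchors the motor-unit firing and coherence analyses to
  the portion of the trial least contaminated by force corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "ForceTrace",
    "SteadyWindow",
    "RegressionResult",
    "compute_mvc",
    "steadiness_cov",
    "find_steadiest_window",
    "normalize_capacity",
    "regress_peak_vs_cov",
]


def _round_half_away(x: float) -> int:
    # deterministic sample conversion across sampling rates
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ForceTrace:
    """A sampled force trace with its protocol timing.

    Parameters
    ----------
    samples : array of force values in newtons.
    fs : sampling rate, Hz.
    target : the scalar target force (N) for the hold phase; must be > 0
        for submaximal trials (COV is referenced to it).
    level : target as a fraction of MVC (bookkeeping only).
    hold_start, hold_end : hold-phase boundaries in seconds, taken from the
        protocol timestamps rather than detected from the force signal.
    """

    samples: np.ndarray
    fs: float
    target: float = 0.0
    level: float = 0.0
    hold_start: float = 0.0
    hold_end: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.hold_end > self.duration + 1.0 / self.fs:
            raise ValueError("hold window extends past the trace")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def value_at(self, t: float) -> float:
        """Force at time ``t`` by linear interpolation between samples."""
        return float(np.interp(t, self.times, self.samples))


@dataclass(frozen=True)
class SteadyWindow:
    """An analysis window located by the steadiest-window search."""

    start: float
    width: float
    cov: float

    @property
    def end(self) -> float:
        return self.start + self.width


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of steadiness against peak force."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    adj_r2: float
    n: int


def compute_mvc(traces: Sequence[ForceTrace]) -> float:
    """Maximal voluntary contraction: the global maximum force sample
    across all maximal-effort traces."""
    if len(traces) == 0:
        raise ValueError("at least one trace required")
    return float(max(t.samples.max() for t in traces))


def steadiness_cov(trace: ForceTrace) -> float:
    """Hold-phase force steadiness, % of target.

    100 x SD(force over the 6 s centred on the hold midpoint) / target.
    Requires a hold of at least 6 s and a positive target.
    """
    hold = trace.hold_end - trace.hold_start
    if hold < 6.0:
        raise ValueError("hold phase shorter than 6 s")
    if trace.target <= 0:
        raise ValueError("target force must be positive")
    mid = 0.5 * (trace.hold_start + trace.hold_end)
    i0 = _round_half_away((mid - 3.0) * trace.fs)
    i1 = i0 + _round_half_away(6.0 * trace.fs)
    seg = trace.samples[i0:i1]
    return float(100.0 * seg.std(ddof=0) / trace.target)


def _window_covs(samples: np.ndarray, target: float, fs: float,
                 width: float, step: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Target-referenced COV of every candidate window (vectorised).

    Returns (start indices, COV per window in %, window length in samples).
    """
    w = _round_half_away(width * fs)
    s = max(1, _round_half_away(step * fs))
    n = samples.size
    if w > n:
        raise ValueError("trace shorter than the window")
    starts = np.arange(0, n - w + 1, s)
    # cumulative sums give O(1) mean/variance per window
    c1 = np.concatenate(([0.0], np.cumsum(samples)))
    c2 = np.concatenate(([0.0], np.cumsum(samples ** 2)))
    sm_ = c1[starts + w] - c1[starts]
    sq = c2[starts + w] - c2[starts]
    var = np.maximum(sq / w - (sm_ / w) ** 2, 0.0)
    cov = 100.0 * np.sqrt(var) / target
    return starts, cov, w


def find_steadiest_window(trace: ForceTrace, width: float = 4.0,
                          step: float = 0.05) -> SteadyWindow:
    """Locate the window of ``width`` s with the smallest target-referenced
    COV, sliding in ``step`` s increments over the full trial.

    The search is exhaustive over all candidate starts; ties break to the
    earliest start.  Ramp phases need no explicit exclusion: their SD about
    the target is huge, so they never win.
    """
    if trace.target <= 0:
        raise ValueError("target force must be positive")
    starts, covs, _ = _window_covs(trace.samples, trace.target, trace.fs,
                                   width, step)
    best = int(np.argmin(covs))  # argmin returns the first minimum: tie-break
    return SteadyWindow(start=float(starts[best] / trace.fs), width=width,
                        cov=float(covs[best]))


def normalize_capacity(peak: float, size: float) -> float:
    """Peak force normalised to a structural size measure (e.g. forearm
    circumference or muscle thickness, mm) -> N/mm."""
    if size <= 0:
        raise ValueError("size must be positive")
    return peak / size


def regress_peak_vs_cov(pairs: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS regression of force COV (%) on peak force (N).

    Returns the intercept, slope with its 95% CI, and adjusted R².  Used to
    ask how much of between-participant steadiness is explained by raw
    force capacity.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (peak, cov) pairs")
    peak = np.array([p for p, _ in pairs], dtype=float)
    cov = np.array([c for _, c in pairs], dtype=float)
    if np.ptp(peak) == 0:
        raise ValueError("zero variance in peak force")
    X = sm.add_constant(peak)
    fit = sm.OLS(cov, X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return RegressionResult(intercept=float(fit.params[0]),
                            slope=float(fit.params[1]),
                            slope_ci=(float(lo), float(hi)),
                            adj_r2=float(fit.rsquared_adj),
                            n=len(pairs))
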