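"""Bootstrap group statistics and effect sizes.

Inference follows the estimation-statistics style used for small-cohort
neuromuscular comparisons: percentile bootstrap confidence intervals for
group mean differences and for Cohen's d, with effect magnitudes mapped
onto the conventional trivial/small/moderate/large taxonomy.  No p-values
are produced; a difference is read as significant when its 95% CI excludes
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BootResult",
    "EffectSize",
    "boot_mean_diff",
    "boot_cohens_d",
    "classify_d",
    "cohens_d",
    "ci_excludes_zero",
]

#: Effect-size class boundaries applied to |d|; each interval is half-open
#: [lo, hi) so boundary values land in the upper class.
D_THRESHOLDS = ((0.2, "trivial"), (0.5, "small"), (0.8, "moderate"))


@dataclass(frozen=True)
class BootResult:
    """Point estimate with a percentile bootstrap 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero (no overlap with the null)."""
        return ci_excludes_zero(self.ci_low, self.ci_high)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with bootstrap CI and magnitude label."""

    d: float
    ci_low: float
    ci_high: float
    label: str
    n_resamples: int
    seed: int


def classify_d(d: float) -> str:
    """Map an effect size onto {trivial, small, moderate, large} by |d|.

    Boundaries are half-open: |d| in [0, 0.2) is trivial, [0.2, 0.5) small,
    [0.5, 0.8) moderate and [0.8, inf) large, so e.g. d = 0.5 is moderate.
    """
    mag = abs(float(d))
    for upper, label in D_THRESHOLDS:
        if mag < upper:
            return label
    return "large"


def cohens_d(a, b) -> float:
    """Cohen's d of two samples using the pooled (n-1) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def _resamples(x, n, rng):
    """(n, |x|) matrix of with-replacement resamples."""
    return x[rng.integers(0, x.size, (n, x.size))]


def boot_mean_diff(a, b, n: int = 10_000, seed: int = 0) -> BootResult:
    """Percentile bootstrap CI for mean(a) - mean(b).

    Each group is resampled with replacement independently ``n`` times
    (default 10,000); the CI is the 2.5/97.5 percentile of the resampled
    mean differences.  Deterministic for a fixed ``seed``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    rng = np.random.default_rng(seed)
    boots = (_resamples(a, n, rng).mean(axis=1)
             - _resamples(b, n, rng).mean(axis=1))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return BootResult(float(a.mean() - b.mean()), float(lo), float(hi), n, seed)


def boot_cohens_d(a, b, n: int = 10_000, seed: int = 0) -> EffectSize:
    """Cohen's d with a percentile bootstrap 95% CI and magnitude label.

    Degenerate resamples with zero pooled SD are dropped from the CI
    (they can occur with tiny groups of repeated values).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    point = cohens_d(a, b)  # validates sizes / pooled SD
    rng = np.random.default_rng(seed)
    ra, rb = _resamples(a, n, rng), _resamples(b, n, rng)
    na, nb = a.size, b.size
    va, vb = ra.var(axis=1, ddof=1), rb.var(axis=1, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (ra.mean(axis=1) - rb.mean(axis=1)) / pooled
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectSize(point, float(lo), float(hi), classify_d(point), n, seed)


def ci_excludes_zero(lo: float, hi: float) -> bool:
    """Significance-by-CI rule: True when [lo, hi] does not contain 0."""
    return lo > 0 or hi < 0
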