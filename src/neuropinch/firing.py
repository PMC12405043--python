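"""Motor-unit spike-train statistics and the firing-rate mixed model.

Spike trains come from EMG decomposition, each with a decomposition
accuracy score (%).  Before any rate statistic, trains are gated on three
rules inside the analysis window: accuracy >= 90%, at least 7 interpulse
intervals (IPIs), and IPI coefficient of variation (COV_IPIs) <= 30%
(irregular trains are discarded, COV exactly 30% is kept since the removal
rule is "> 30%").

Average firing rate is the mean of reciprocal IPIs, x̄(1/IPIs) — note this
is NOT n/(total time): IPIs {0.1 s, 0.2 s} give mean(10, 5) = 7.5 Hz.

The firing threshold of a unit is the force (as % of MVC, linearly
interpolated) at the onset of *regular* firing: the first IPI whose
following 750 ms of IPIs (at least two of them) has COV_IPIs < 30%.

Group differences in firing rate are modelled with a linear mixed model,
rate ~ group * level * muscle, with crossed random intercepts for
participant (electrode placement, tissue) and for firing threshold
(Henneman's size principle: low-threshold units fire faster).  The
threshold intercept is formed over 1%-MVC bins.  Group contrasts are
reported as estimated-marginal-mean (EMM) differences with 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .force import ForceTrace, SteadyWindow

__all__ = [
    "SpikeTrain",
    "FiringStats",
    "EmmContrast",
    "LmmResult",
    "NO_REGULAR_ONSET",
    "filter_trains",
    "mean_firing_rate",
    "cov_ipis",
    "firing_threshold",
    "firing_stats",
    "fit_firing_lmm",
    "simulate_firing_records",
]

#: Sentinel returned by firing_threshold when no IPI starts regular firing.
NO_REGULAR_ONSET = float("nan")

ACCURACY_GATE = 90.0       # % decomposition accuracy required
MIN_IPIS = 7               # trains with fewer IPIs in-window are removed
MAX_COV_IPIS = 30.0        # % ; strictly greater is removed
ONSET_WINDOW_S = 0.75      # regular-firing onset look-ahead


@dataclass
class SpikeTrain:
    """Sorted spike times of one motor unit with its accuracy score."""

    unit_id: str
    muscle: str
    spike_times: np.ndarray
    accuracy: float

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"spike times of {self.unit_id} not strictly increasing")
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must be in [0, 100]")

    def in_window(self, window: SteadyWindow) -> np.ndarray:
        t = self.spike_times
        return t[(t >= window.start) & (t <= window.end)]


@dataclass(frozen=True)
class FiringStats:
    unit_id: str
    muscle: str
    mean_rate: float
    n_ipis: int
    cov_ipi: float
    firing_threshold: float  # % MVC, NaN when no regular onset


def _ipis(times: np.ndarray) -> np.ndarray:
    return np.diff(times)


def cov_ipis(times: np.ndarray) -> float:
    """Coefficient of variation of interpulse intervals, %."""
    ipi = _ipis(np.asarray(times, dtype=float))
    if ipi.size < 2:
        return float("nan")
    return float(100.0 * ipi.std(ddof=0) / ipi.mean())


def filter_trains(trains: Sequence[SpikeTrain],
                  window: SteadyWindow,
                  accuracy_gate: float = ACCURACY_GATE,
                  min_ipis: int = MIN_IPIS,
                  max_cov: float = MAX_COV_IPIS) -> list[SpikeTrain]:
    """Apply the three quality rules inside the analysis window.

    Keeps a train when accuracy >= 90%, its in-window spikes give at least
    7 IPIs, and COV_IPIs <= 30%.  Idempotent; may return an empty list.
    """
    kept = []
    for tr in trains:
        if tr.accuracy < accuracy_gate:
            continue
        t = tr.in_window(window)
        if t.size - 1 < min_ipis:
            continue
        # strict "> 30%" removal; tiny relative slack so a COV sitting
        # exactly on the boundary is kept regardless of rounding
        if cov_ipis(t) > max_cov * (1 + 1e-12):
            continue
        kept.append(tr)
    return kept


def mean_firing_rate(train: SpikeTrain, window: SteadyWindow) -> float:
    """Average firing rate as the mean of reciprocal in-window IPIs, Hz."""
    ipi = _ipis(train.in_window(window))
    if ipi.size < 1:
        raise ValueError("no interpulse interval inside the window")
    return float(np.mean(1.0 / ipi))


def firing_threshold(train: SpikeTrain, force: ForceTrace, mvc: float) -> float:
    """Force at the onset of regular firing, % of MVC.

    IPIs are scanned in order.  For a candidate IPI beginning at spike time
    t0, the IPIs whose onsets fall in [t0, t0 + 750 ms] are collected; if at
    least two exist and their COV_IPIs < 30%, regular firing starts at t0
    and the threshold is 100 x force(t0)/mvc, with force linearly
    interpolated.  Returns NaN (sentinel) when no IPI qualifies.
    """
    t = train.spike_times
    if t.size < 2:
        return NO_REGULAR_ONSET
    onsets = t[:-1]           # IPI i spans [t[i], t[i+1]]
    ipi = _ipis(t)
    for i, t0 in enumerate(onsets):
        sel = (onsets >= t0) & (onsets <= t0 + ONSET_WINDOW_S)
        vals = ipi[sel]
        if vals.size >= 2:
            cv = 100.0 * vals.std(ddof=0) / vals.mean()
            if cv < MAX_COV_IPIS:
                return 100.0 * force.value_at(float(t0)) / mvc
    return NO_REGULAR_ONSET


def firing_stats(train: SpikeTrain, window: SteadyWindow,
                 force: ForceTrace | None = None,
                 mvc: float | None = None) -> FiringStats:
    """Bundle the per-unit statistics for one filtered train."""
    t = train.in_window(window)
    thr = NO_REGULAR_ONSET
    if force is not None and mvc:
        thr = firing_threshold(train, force, mvc)
    return FiringStats(unit_id=train.unit_id, muscle=train.muscle,
                       mean_rate=mean_firing_rate(train, window),
                       n_ipis=int(t.size - 1), cov_ipi=cov_ipis(t),
                       firing_threshold=thr)


# ---------------------------------------------------------------------------
# linear mixed model of firing rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmmContrast:
    """EMM group difference (group_a − group_b) within one (level, muscle)
    cell, with its 95% CI and a small-cell caution flag."""

    level: float
    muscle: str
    estimate: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    caution: bool  # fewer than 3 units in either group's cell


@dataclass
class LmmResult:
    fixed_effects: pd.Series
    vc_participant: float
    vc_threshold: float
    resid_var: float
    marginal_r2: float
    conditional_r2: float
    contrasts: list[EmmContrast]
    converged: bool
    singular: bool


_FORMULA = "rate ~ C(group) * C(level) * C(muscle)"


def fit_firing_lmm(records: pd.DataFrame,
                   threshold_bin_pct: float = 1.0) -> LmmResult:
    """REML fit of rate ~ group * level * muscle with crossed random
    intercepts for participant and firing-threshold bin.

    ``records`` needs columns rate, group, level, muscle, participant,
    threshold (% MVC; NaN thresholds fall into their own bin).  Threshold
    bins are ``threshold_bin_pct`` wide.  Marginal R² is the fixed-effect
    share of variance, conditional R² adds the variance components
    (Nakagawa's formulation); conditional >= marginal by construction.
    Group EMM contrasts are returned per (level, muscle) cell; cells with
    fewer than 3 units in either group are flagged for caution.
    """
    df = records.copy()
    need = {"rate", "group", "level", "muscle", "participant", "threshold"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for g in groups:
        if df.loc[df.group == g, "participant"].nunique() < 2:
            raise ValueError("need >= 2 participants per group")
    if df["level"].nunique() < 2:
        raise ValueError("need >= 2 force levels")

    thr = df["threshold"].to_numpy(dtype=float)
    bins = np.where(np.isfinite(thr),
                    np.floor(thr / threshold_bin_pct), -1).astype(int)
    df["thr_bin"] = bins
    df["all"] = 1

    vc = {"participant": "0 + C(participant)", "thr_bin": "0 + C(thr_bin)"}
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(_FORMULA, df, groups="all", vc_formula=vc,
                            re_formula="0")
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True)
    vcs = fit.vcomp
    vc_p = float(max(vcs[list(model.exog_vc.names).index("participant")], 0.0))
    vc_t = float(max(vcs[list(model.exog_vc.names).index("thr_bin")], 0.0))
    if vc_p == 0.0 or vc_t == 0.0:
        singular = True
        warnings.warn("singular fit: a variance component pinned at 0")

    fixed = fit.fe_params
    resid = float(fit.scale)
    # Nakagawa R²: fixed-effect predictions vs total variance
    exog = model.exog
    var_fixed = float(np.var(exog @ fixed.to_numpy()))
    total = var_fixed + vc_p + vc_t + resid
    marg = var_fixed / total
    cond = (var_fixed + vc_p + vc_t) / total

    contrasts = _emm_contrasts(df, model, fit, groups)
    return LmmResult(fixed_effects=fixed, vc_participant=vc_p,
                     vc_threshold=vc_t, resid_var=resid,
                     marginal_r2=marg, conditional_r2=cond,
                     contrasts=contrasts,
                     converged=bool(getattr(fit, "converged", True)),
                     singular=singular)


def _emm_contrasts(df, model, fit, groups) -> list[EmmContrast]:
    """EMM differences (first group − second) per (level, muscle) cell.

    With a fully factorial fixed structure the EMM of a cell is the fixed
    design row evaluated at that cell (random intercepts average to zero),
    so the contrast is L·β with variance L·Cov(β)·Lᵀ.  The CI uses a t
    critical value on between-participant degrees of freedom
    (participants − groups), the dominant level of replication for a
    group contrast; a normal quantile would undercover on small cohorts.
    """
    import patsy
    from scipy.stats import t as t_dist

    design_info = model.data.design_info
    cov = np.asarray(fit.cov_params())[: len(fit.fe_params), : len(fit.fe_params)]
    beta = fit.fe_params.to_numpy()
    ddf = df["participant"].nunique() - len(groups)
    crit = float(t_dist.ppf(0.975, ddf)) if ddf > 0 else 1.96
    out = []
    ga, gb = groups
    for level in sorted(df["level"].unique()):
        for muscle in sorted(df["muscle"].unique()):
            cell = {"level": level, "muscle": muscle}
            Xa = patsy.build_design_matrices(
                [design_info], {"group": [ga], **{k: [v] for k, v in cell.items()}})[0]
            Xb = patsy.build_design_matrices(
                [design_info], {"group": [gb], **{k: [v] for k, v in cell.items()}})[0]
            L = np.asarray(Xa)[0] - np.asarray(Xb)[0]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            n_a = int(((df.group == ga) & (df.level == level)
                       & (df.muscle == muscle)).sum())
            n_b = int(((df.group == gb) & (df.level == level)
                       & (df.muscle == muscle)).sum())
            out.append(EmmContrast(level=float(level), muscle=str(muscle),
                                   estimate=est,
                                   ci_low=est - crit * se,
                                   ci_high=est + crit * se,
                                   n_a=n_a, n_b=n_b,
                                   caution=min(n_a, n_b) < 3))
    return out


def simulate_firing_records(n_per_group: int = 5,
                            levels: Sequence[float] = (0.35, 0.55),
                            muscles: Sequence[str] = ("APB", "FDS"),
                            units_per_cell: int = 5,
                            group_effect_hz: float = 0.0,
                            effect_cell: tuple[float, str] = (0.35, "APB"),
                            participant_sd: float = 1.0,
                            threshold_slope: float = -8.0,
                            resid_sd: float = 1.5,
                            seed: int = 0) -> pd.DataFrame:
    """Generate per-unit firing-rate records with known structure.

    Rates rise with force level, fall with recruitment threshold (size
    principle, ``threshold_slope`` Hz per unit-fraction of MVC), carry a
    participant random intercept, and optionally a group effect of
    ``group_effect_hz`` added for group "a" in ``effect_cell`` only.
    Used for mixed-model parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("a", "b"):
        for p in range(n_per_group):
            pid = f"{group}{p}"
            p_int = rng.normal(0.0, participant_sd)
            for level in levels:
                for muscle in muscles:
                    base = 8.0 + 12.0 * level + (1.0 if muscle == "APB" else 0.0)
                    for u in range(units_per_cell):
                        thr = rng.uniform(0.0, level)
                        rate = (base + p_int + threshold_slope * thr
                                + rng.normal(0.0, resid_sd))
                        if group == "a" and (level, muscle) == effect_cell:
                            rate += group_effect_hz
                        rows.append(dict(rate=rate, group=group, level=level,
                                         muscle=muscle, participant=pid,
                                         threshold=100.0 * thr))
    return pd.DataFrame(rows)
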