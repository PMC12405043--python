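"""EMG-activity envelopes and k-shape clustering of participants.

The ramp phase of a submaximal contraction reveals different muscle-use
strategies: some participants' EMG activity follows the force trace, in
others it is inversely related.  To group participants by the *shape* of
their activity pattern, the first 15 s of each trial's channel-1 EMG is
z-normalised, full-wave rectified and smoothed with a sliding 500 ms RMS
window; the three repeats at a force level are averaged per participant,
and the participant-average envelopes are clustered with k-shape.

k-shape uses the shape-based distance (SBD): one minus the maximum of the
coefficient-normalised cross-correlation over all shifts of the
z-normalised series (0 for identical shapes up to shift/scale, 2 for
perfectly anti-correlated ones).  Centroids are computed by shape
extraction — the leading right singular vector of the shift-aligned,
column-centred member matrix — which maximises the summed squared
cross-correlation to the members.

Cluster-count selection follows a two-step recipe: a within-cluster
sum-of-squares (WCSS) elbow plot for visual inspection of whether
clustering is appropriate at all, then silhouette scores for k = 2..5 with
the largest taken as the optimal k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from sklearn.metrics import silhouette_score

__all__ = [
    "ActivityEnvelope",
    "ClusterModel",
    "ClusterDiagnostics",
    "smoothed_power",
    "participant_average",
    "sbd_distance",
    "sbd_matrix",
    "kshape",
    "choose_k",
]

RMS_WINDOW_S = 0.5
ANALYSIS_S = 15.0


@dataclass
class ActivityEnvelope:
    """Smoothed RMS of unit-variance rectified EMG over the first 15 s."""

    samples: np.ndarray
    fs: float
    participant: str = ""
    muscle: str = ""
    level: float = 0.0


def smoothed_power(emg: np.ndarray, fs: float,
                   rms_window_s: float = RMS_WINDOW_S,
                   analysis_s: float = ANALYSIS_S, **meta) -> ActivityEnvelope:
    """z-normalise -> rectify -> sliding 500 ms RMS -> first 15 s.

    The RMS window slides one sample at a time; at the record edges the
    window shrinks to the available samples (no padding), so the envelope
    has the same length as its input before clipping.
    """
    emg = np.asarray(emg, dtype=float)
    n_needed = int(round(analysis_s * fs))
    if emg.size < n_needed:
        raise ValueError(f"trial shorter than {analysis_s} s")
    sd = emg.std()
    if sd == 0:
        raise ValueError("zero-variance EMG")
    z = (emg - emg.mean()) / sd
    sq = z ** 2  # |z|² — rectification then squaring inside the RMS
    w = int(round(rms_window_s * fs))
    half_lo = w // 2
    half_hi = w - half_lo  # window [i - half_lo, i + half_hi)
    c = np.concatenate(([0.0], np.cumsum(sq)))
    n = sq.size
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi, 0, n)
    rms = np.sqrt((c[hi] - c[lo]) / (hi - lo))
    return ActivityEnvelope(samples=rms[:n_needed], fs=fs, **meta)


def participant_average(envelopes: Sequence[ActivityEnvelope]) -> ActivityEnvelope:
    """Pointwise mean of a participant's repeat envelopes."""
    if len(envelopes) == 0:
        raise ValueError("no envelopes to average")
    n = envelopes[0].samples.size
    if any(e.samples.size != n for e in envelopes):
        raise ValueError("envelope length mismatch")
    mean = np.mean([e.samples for e in envelopes], axis=0)
    first = envelopes[0]
    return ActivityEnvelope(samples=mean, fs=first.fs,
                            participant=first.participant,
                            muscle=first.muscle, level=first.level)


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance series")
    return (x - x.mean()) / sd


def _ncc_max(a: np.ndarray, b: np.ndarray,
             max_shift: int | None = None) -> tuple[float, int]:
    """Max coefficient-normalised cross-correlation of z-normalised series
    and the shift achieving it (positive shift delays b).  ``max_shift``
    restricts the search to lags within +/- that many samples."""
    za, zb = _znorm(a), _znorm(b)
    cc = _signal.correlate(za, zb, mode="full", method="auto")
    cc = cc / (np.linalg.norm(za) * np.linalg.norm(zb))
    centre = len(b) - 1
    if max_shift is not None:
        lo = max(0, centre - max_shift)
        hi = min(cc.size, centre + max_shift + 1)
        i = lo + int(np.argmax(cc[lo:hi]))
    else:
        i = int(np.argmax(cc))
    return float(cc[i]), i - centre


def sbd_distance(a: np.ndarray, b: np.ndarray,
                 max_shift: int | None = None) -> float:
    """Shape-based distance in [0, 2]: 1 − the shift-maximised NCC of the
    z-normalised series.

    0 means identical shapes (up to scale, offset and an allowed shift);
    2 is perfect anticorrelation.  With unrestricted shifts a series and
    its negation are rarely exactly 2 apart — some lag usually correlates
    positively — so ``max_shift`` can restrict the alignment search
    (``max_shift=0`` disables alignment altogether).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    ncc, _ = _ncc_max(a, b, max_shift)
    return float(max(0.0, 1.0 - ncc))


def sbd_matrix(series: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise SBDs."""
    n = len(series)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sbd_distance(series[i], series[j])
    return d


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    centroids: list[np.ndarray]
    inertia: float  # sum of squared SBD to own centroid (WCSS)
    n_iter: int
    seed: int


def _align_to(ref: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Shift x (zero-padded) to its best cross-correlation lag with ref."""
    _, shift = _ncc_max(ref, x)
    out = np.zeros_like(x)
    if shift >= 0:
        out[shift:] = x[: x.size - shift]
    else:
        out[:shift] = x[-shift:]
    return out


def _shape_extract(members: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Centroid of a cluster: leading right singular vector of the
    shift-aligned, column-centred member matrix, z-normalised and
    sign-fixed to correlate positively with the member mean."""
    aligned = np.array([_align_to(ref, _znorm(m)) for m in members])
    centred = aligned - aligned.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    c = vt[0]
    if np.dot(c, aligned.mean(axis=0)) < 0:
        c = -c
    return _znorm(c)


def kshape(envelopes: Sequence[np.ndarray | ActivityEnvelope], k: int,
           seed: int = 0, max_iter: int = 100, n_init: int = 3) -> ClusterModel:
    """k-shape clustering: alternate minimum-SBD assignment and shape
    extraction until assignments stabilise (or ``max_iter``).

    Initialisation is a seeded random partition, restarted ``n_init``
    times with the lowest-inertia model kept (the objective has local
    optima).  Deterministic for a fixed seed.
    """
    best = None
    for restart in range(n_init):
        model = _kshape_once(envelopes, k, seed + 7919 * restart, max_iter)
        if best is None or model.inertia < best.inertia:
            best = model
    return best


def _kshape_once(envelopes, k, seed, max_iter) -> ClusterModel:
    X = [np.asarray(getattr(e, "samples", e), dtype=float) for e in envelopes]
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= number of series")
    rng = np.random.default_rng(seed)
    # random init guaranteeing every cluster non-empty
    labels = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
    rng.shuffle(labels)
    centroids: list[np.ndarray] = [np.zeros(X[0].size)] * k
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for c in range(k):
            members = [X[i] for i in np.flatnonzero(labels == c)]
            if not members:
                # re-seed an empty cluster with the worst-fitting series
                worst = int(np.argmax([sbd_distance(x, centroids[labels[i]])
                                       for i, x in enumerate(X)]))
                labels[worst] = c
                members = [X[worst]]
            ref = centroids[c] if centroids[c].any() else _znorm(members[0])
            centroids[c] = _shape_extract(np.array(members), ref)
        d = np.array([[sbd_distance(x, c) for c in centroids] for x in X])
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
    inertia = float(sum(d[i, labels[i]] ** 2 for i in range(n)))
    return ClusterModel(k=k, assignments=labels.copy(), centroids=centroids,
                        inertia=inertia, n_iter=n_iter, seed=seed)


@dataclass
class ClusterDiagnostics:
    wcss: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int
    supported: bool  # False when even the best silhouette is weak


def choose_k(envelopes: Sequence[np.ndarray | ActivityEnvelope], seed: int = 0,
             k_max: int = 5, support_threshold: float = 0.25) -> ClusterDiagnostics:
    """Two-step cluster-count selection.

    WCSS is computed for k = 1..k_max to draw an elbow plot (inspected
    visually, not auto-detected); silhouette scores on the precomputed SBD
    matrix are computed for k = 2..k_max and the argmax is chosen_k.  When
    the best silhouette falls below ``support_threshold`` the data are
    flagged as not supporting clustering.
    """
    X = [np.asarray(getattr(e, "samples", e), dtype=float) for e in envelopes]
    n = len(X)
    if n < 6:
        raise ValueError("need at least 6 series to select k")
    dmat = sbd_matrix(X)
    wcss, sil = {}, {}
    for k in range(1, min(k_max, n - 1) + 1):
        model = kshape(X, k, seed=seed)
        wcss[k] = model.inertia
        if k >= 2 and len(set(model.assignments)) >= 2:
            sil[k] = float(silhouette_score(dmat, model.assignments,
                                            metric="precomputed"))
    chosen = max(sil, key=sil.get)
    return ClusterDiagnostics(wcss=wcss, silhouette=sil, chosen_k=chosen,
                              supported=sil[chosen] >= support_threshold)
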