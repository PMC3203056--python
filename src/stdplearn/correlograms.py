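"""Input spike-train cross-correlograms and spike-count variability.

The repeating pattern leaves its signature in the time-averaged
cross-covariance between afferents: a pattern pair (i, j) with latencies
``lam_i^m`` and ``lam_j^n`` produces Gaussian bumps

    C_ij(u) = nu * p^2 * sum_{m,n} a_i^m a_j^n g_st(u - (lam_j^n - lam_i^m)),

where ``st = sqrt(sigma_i^2 + sigma_j^2)`` combines the two afferents'
temporal widths (jitter for spike patterns, rate-peak width for
rate-modulated ones) and ``g_st`` is the unit-area Gaussian.  Reliable
spike patterns are the delta limit ``st -> 0``.  This module provides the
closed-form prediction, the empirical estimator, and the spike-count Fano
factors of the deletion model.

Units: lags in ms; covariance density in Hz per ms of lag, i.e. integrating
a correlogram peak over lag (ms) gives its mass in Hz (a pattern peak has
mass ``nu * p^2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import PatternSpec, PresentationSchedule, SpikeTrainSet  # noqa: F401 (re-exported types)

__all__ = [
    "Correlogram",
    "gaussian_kernel",
    "empirical_correlogram",
    "group_correlogram",
    "predicted_correlogram",
    "predicted_group_correlogram",
    "fano_sd",
    "fano_empirical",
    "presentation_counts",
    "write_correlogram",
]


@dataclass
class Correlogram:
    """Covariance density on a uniform lag grid.

    ``lags`` are bin centers (ms); ``values`` in Hz/ms.  The empirical
    estimator satisfies C_ij(u) = C_ji(-u) on the same data.
    """

    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    pair: tuple[int, int] | tuple[str, str] | None = None

    def mass(self, lo: float, hi: float) -> float:
        """Integrated covariance (Hz) over the lag interval [lo, hi]."""
        sel = (self.lags >= lo) & (self.lags <= hi)
        return float(np.sum(self.values[sel]) * self.bin_width)


def gaussian_kernel(lag, width: float):
    """Unit-area Gaussian density g_sigma(u) = exp(-u^2/2 sigma^2)/(sigma sqrt(2 pi)).

    ``width`` must be positive; the width-zero delta limit is handled
    symbolically by the callers that need it.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0:
        raise ValueError("width 0 is a delta; callers must special-case it")
    u = np.asarray(lag, dtype=float)
    return np.exp(-0.5 * (u / width) ** 2) / (width * np.sqrt(2.0 * np.pi))


def _lag_grid(max_lag: float, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(max_lag / bin_width))
    edges = (np.arange(-n, n + 2) - 0.5) * bin_width  # symmetric about 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def empirical_correlogram(
    train_i: np.ndarray,
    train_j: np.ndarray,
    max_lag: float = 60.0,
    bin_width: float = 1.0,
    duration: float | None = None,
    pair: tuple | None = None,
) -> Correlogram:
    """Estimate the cross-covariance density between two spike trains.

    Histograms the pairwise lags ``t_j - t_i`` per unit time and bin, then
    subtracts the rate-product baseline estimated on the same realization so
    that independent trains are centered on zero in expectation.
    """
    ti = np.asarray(train_i, dtype=float)
    tj = np.asarray(train_j, dtype=float)
    if duration is None:
        duration = float(max(ti.max(initial=0.0), tj.max(initial=0.0)))
    edges, centers = _lag_grid(max_lag, bin_width)
    if ti.size == 0 or tj.size == 0 or duration <= 0:
        warnings.warn("empty spike train: returning all-zero correlogram")
        return Correlogram(centers, np.zeros_like(centers), bin_width, pair)
    counts = np.zeros(centers.size)
    lo = np.searchsorted(tj, ti - max_lag - bin_width)
    hi = np.searchsorted(tj, ti + max_lag + bin_width)
    for k in range(ti.size):
        if hi[k] > lo[k]:
            counts += np.histogram(tj[lo[k]:hi[k]] - ti[k], bins=edges)[0]
    r_i = ti.size / duration  # per ms
    r_j = tj.size / duration
    dens = counts / (duration * bin_width) - r_i * r_j
    return Correlogram(centers, dens * 1000.0, bin_width, pair)


def group_correlogram(
    train_set: SpikeTrainSet,
    group_a: Sequence[int],
    group_b: Sequence[int],
    max_lag: float = 60.0,
    bin_width: float = 1.0,
) -> Correlogram:
    """Pair-averaged cross-covariance between two groups of afferents.

    Pools all (a, b) pairs by merging each group's trains, so the result is
    the mean single-pair correlogram (the pooled histogram divided by the
    number of pairs).
    """
    ta = np.sort(np.concatenate([train_set.trains[i] for i in group_a]))
    tb = np.sort(np.concatenate([train_set.trains[j] for j in group_b]))
    T = train_set.total_duration
    edges, centers = _lag_grid(max_lag, bin_width)
    if ta.size == 0 or tb.size == 0:
        warnings.warn("empty group: returning all-zero correlogram")
        return Correlogram(centers, np.zeros_like(centers), bin_width, ("A", "B"))
    counts = np.zeros(centers.size)
    lo = np.searchsorted(tb, ta - max_lag - bin_width)
    hi = np.searchsorted(tb, ta + max_lag + bin_width)
    for k in range(ta.size):
        if hi[k] > lo[k]:
            counts += np.histogram(tb[lo[k]:hi[k]] - ta[k], bins=edges)[0]
    n_pairs = len(group_a) * len(group_b)
    base = sum(train_set.trains[i].size for i in group_a) / T \
        * sum(train_set.trains[j].size for j in group_b) / T / n_pairs
    dens = counts / (T * bin_width * n_pairs) - base
    return Correlogram(centers, dens * 1000.0, bin_width, ("A", "B"))


def predicted_correlogram(
    spec: PatternSpec,
    pair: tuple[int, int],
    max_lag: float = 60.0,
    bin_width: float = 1.0,
) -> Correlogram:
    """Closed-form cross-covariance for a pattern pair.

    Sum of Gaussian kernels of width ``sqrt(sigma_i^2 + sigma_j^2)`` centered
    on the latency differences, each carrying mass ``nu * p^2 * a_i * a_j``
    (delta mass placed in the containing bin when the width vanishes).
    Non-pattern pairs predict identically zero.
    """
    i, j = pair
    edges, centers = _lag_grid(max_lag, bin_width)
    values = np.zeros_like(centers)
    if i >= spec.n_pattern or j >= spec.n_pattern:
        return Correlogram(centers, values, bin_width, pair)
    if spec.latencies is None:
        raise ValueError("spec.latencies required for a prediction")
    nu_ms = spec.presentation_rate / 1000.0
    p2 = spec.occurrence_prob**2
    sig = np.hypot(spec.sigma_of(i), spec.sigma_of(j))
    if sig > 0 and bin_width > sig / 2.0:
        raise ValueError("lag grid coarser than sigma_tilde/2; refine bin_width")
    a_i, a_j = spec.amp_of(i), spec.amp_of(j)
    same = i == j
    for m, lam_i in enumerate(spec.latencies[i]):
        for n, lam_j in enumerate(spec.latencies[j]):
            if same and m == n and spec.model_kind != "R":
                continue  # a spike cannot pair with itself
            d = lam_j - lam_i
            mass = nu_ms * p2 * a_i * a_j
            if sig == 0:
                k = np.searchsorted(edges, d, side="right") - 1
                if 0 <= k < values.size:
                    values[k] += mass / bin_width
            else:
                values += mass * gaussian_kernel(centers - d, sig)
    return Correlogram(centers, values * 1000.0, bin_width, pair)


def predicted_group_correlogram(
    spec: PatternSpec,
    groups: tuple[int, int] = (0, 1),
    max_lag: float = 60.0,
    bin_width: float = 1.0,
) -> Correlogram:
    """Population-averaged prediction between the two groups of SB/RB.

    One Gaussian of mass ``nu`` centered at the group-mean latency difference
    with width ``sqrt(w_k^2 + w_l^2)``: the across-afferent latency scatter of
    SB plays the same role as the shared rate-peak width of RB, so both
    models share this expression.
    """
    if spec.group_spec is None:
        raise ValueError("group_spec required")
    k, l = groups
    gk, gl = spec.group_spec[k], spec.group_spec[l]
    edges, centers = _lag_grid(max_lag, bin_width)
    nu_ms = spec.presentation_rate / 1000.0
    sig = float(np.hypot(gk.width, gl.width))
    d = gl.mean_latency - gk.mean_latency
    if sig == 0:
        values = np.zeros_like(centers)
        idx = np.searchsorted(edges, d, side="right") - 1
        if 0 <= idx < values.size:
            values[idx] = nu_ms / bin_width
    else:
        values = nu_ms * gaussian_kernel(centers - d, sig)
    return Correlogram(centers, values * 1000.0, bin_width, ("g%d" % k, "g%d" % l))


def fano_sd(occurrence_prob: float) -> float:
    """Presentation-window spike-count Fano factor of the deletion model.

    At the mean latency count ``n = r0 * Delta`` the binomial pattern count
    plus the independent Poisson compensation give F = 1 - p^2: 0 for fully
    reliable trains (p = 1), 1 in the Poisson limit (p = 0).
    """
    p = float(occurrence_prob)
    if not (0.0 <= p <= 1.0):
        raise ValueError("occurrence probability must lie in [0, 1]")
    return 1.0 - p * p


def presentation_counts(
    train: np.ndarray, schedule: PresentationSchedule
) -> np.ndarray:
    """Spike count of one train inside each presentation window."""
    t = np.asarray(train, dtype=float)
    lo = np.searchsorted(t, schedule.onsets)
    hi = np.searchsorted(t, schedule.onsets + schedule.pattern_duration)
    return hi - lo


def fano_empirical(
    train_set: SpikeTrainSet | np.ndarray,
    schedule: PresentationSchedule,
    afferent: int = 0,
) -> float:
    """Variance/mean of per-presentation spike counts for one afferent."""
    train = train_set.trains[afferent] if isinstance(train_set, SpikeTrainSet) else train_set
    if len(schedule) < 2:
        raise ValueError("need at least two presentations")
    counts = presentation_counts(train, schedule)
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean presentation count: Fano factor undefined")
    return float(counts.var(ddof=1) / mean)


def write_correlogram(corr: Correlogram, path) -> None:
    """Delimited text export: ``lag_ms<TAB>cov_hz``."""
    with open(path, "w") as fh:
        fh.write("lag_ms\tcov_hz\n")
        for u, v in zip(corr.lags, corr.values):
            fh.write(f"{u:.6f}\t{v:.8f}\n")
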