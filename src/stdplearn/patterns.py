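"""Generators for afferent spike-train ensembles carrying a repeating pattern.

A single hidden pattern is presented repeatedly (at random, non-overlapping
times) to ``n_pattern`` of ``n_total`` afferents; all remaining activity is
statistically matched background firing at the common rate ``r0``.  Six
pattern models are supported:

``S``
    reliable spike pattern: each latency fires at every presentation,
``SD``
    spike pattern with deletion: each latency fires with probability ``p``,
    and a rate-preserving homogeneous Poisson compensation train of rate
    ``(1 - p) * r0`` is added inside the presentation window,
``SJ``
    jittered spike pattern: spike times are drawn around each latency with a
    Gaussian jitter of width ``sigma`` (only with ``p = 1``),
``R``
    rate-modulated pattern: each latency is the center of a Gaussian rate
    peak of width ``sigma`` and area ``a``; spikes are drawn from the summed
    intensity by inhomogeneous Poisson sampling,
``SB`` / ``RB``
    bimodal variants of S and R where pattern afferents split into an early
    and a late group with Gaussian-distributed (SB) or shared (RB) latencies,
``R_envelope``
    model R whose intensities (pattern and non-pattern alike) are multiplied
    by a shared global envelope that repeats identically inside every
    presentation.

All times are milliseconds, all rates Hz.  Every generator is driven by a
``numpy.random.Generator`` seeded explicitly, and identical seeds give
identical spike sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PatternSpec",
    "GroupSpec",
    "EnvelopeSpec",
    "PresentationSchedule",
    "SpikeTrainSet",
    "RateFunctionSet",
    "make_schedule",
    "make_latencies",
    "draw_uniform_latencies",
    "resolve_bimodal",
    "gen_spike_pattern",
    "gen_rate_pattern",
    "gen_bimodal_pattern",
    "gen_envelope_pattern",
    "generate",
    "write_spikes",
    "read_spikes",
    "write_schedule",
    "read_schedule",
]

SPIKE_MODELS = ("S", "SD", "SJ")
RATE_MODELS = ("R",)
BIMODAL_MODELS = ("SB", "RB")
ALL_MODELS = SPIKE_MODELS + RATE_MODELS + BIMODAL_MODELS + ("R_envelope",)


@dataclass(frozen=True)
class GroupSpec:
    """One latency group of a bimodal pattern.

    ``size`` afferents share a mean latency ``mean_latency`` (ms) with
    temporal spread ``width`` (ms): individually drawn latencies for SB,
    a shared Gaussian rate peak for RB.
    """

    size: int
    mean_latency: float
    width: float


@dataclass(frozen=True)
class EnvelopeSpec:
    """Global rate envelope: Gaussian peaks of width ``peak_width`` (ms)
    whose centers form a homogeneous Poisson process at ``center_rate`` (Hz).
    The envelope is normalized to unit mean so the long-run rate stays r0."""

    peak_width: float = 20.0
    center_rate: float = 20.0


@dataclass
class PatternSpec:
    """Full parameterization of one repeating pattern.

    Parameters
    ----------
    model_kind:
        One of ``S, SD, SJ, SB, R, RB, R_envelope``.
    n_total, n_pattern:
        Number of afferents N and of pattern afferents M (first ``n_pattern``
        indices are the pattern afferents).
    pattern_duration:
        Pattern duration Delta in ms.
    presentation_rate:
        Presentation frequency nu in Hz; the low-frequency regime
        ``nu * Delta < 1`` is required.
    background_rate:
        Common background firing rate r0 in Hz.
    latencies:
        Per-pattern-afferent arrays of latencies in [0, Delta); possibly
        empty for some afferents.
    occurrence_prob:
        Probability p that a latency fires at a presentation (S/SD).
    jitter_width:
        Gaussian jitter width sigma in ms (SJ), or rate-peak width (R);
        scalar or per-afferent array.
    amplitude:
        Area a of each Gaussian rate peak (model R); scalar or per-afferent.
    group_spec:
        Two :class:`GroupSpec` for SB/RB.
    envelope_spec:
        :class:`EnvelopeSpec` for ``R_envelope``.
    """

    model_kind: str
    n_total: int
    n_pattern: int
    pattern_duration: float
    presentation_rate: float
    background_rate: float
    latencies: list[np.ndarray] | None = None
    occurrence_prob: float = 1.0
    jitter_width: float | np.ndarray = 0.0
    amplitude: float | np.ndarray = 1.0
    group_spec: tuple[GroupSpec, GroupSpec] | None = None
    envelope_spec: EnvelopeSpec | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ALL_MODELS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not (0 < self.n_pattern <= self.n_total):
            raise ValueError("need 0 < n_pattern <= n_total")
        if not (0.0 <= self.occurrence_prob <= 1.0):
            raise ValueError("occurrence_prob must lie in [0, 1]")
        if np.any(np.asarray(self.jitter_width) < 0):
            raise ValueError("jitter widths must be >= 0")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitudes must be >= 0")
        nu_delta = self.presentation_rate * self.pattern_duration / 1000.0
        if nu_delta >= 1.0:
            raise ValueError(
                f"presentation_rate * pattern_duration = {nu_delta:.3f} >= 1; "
                "presentations must occupy a minority of time"
            )
        if self.latencies is not None:
            if len(self.latencies) != self.n_pattern:
                raise ValueError("one latency array per pattern afferent required")
            self.latencies = [np.asarray(l, dtype=float) for l in self.latencies]
            for lat in self.latencies:
                if lat.size and (lat.min() < 0 or lat.max() >= self.pattern_duration):
                    raise ValueError("latencies must lie in [0, pattern_duration)")
        if self.model_kind in BIMODAL_MODELS:
            if self.group_spec is None:
                raise ValueError(f"model {self.model_kind} requires group_spec")
            g1, g2 = self.group_spec
            if g1.size + g2.size > self.n_pattern:
                raise ValueError("group sizes must not exceed n_pattern")
        if self.model_kind == "SJ" and self.occurrence_prob < 1.0:
            raise ValueError("jittered spike patterns (SJ) require occurrence_prob = 1")

    # -- convenience -------------------------------------------------------
    def sigma_of(self, afferent: int) -> float:
        """Temporal width (jitter or rate-peak width) of one pattern afferent."""
        sig = np.asarray(self.jitter_width, dtype=float)
        return float(sig if sig.ndim == 0 else sig[afferent])

    def amp_of(self, afferent: int) -> float:
        amp = np.asarray(self.amplitude, dtype=float)
        return float(amp if amp.ndim == 0 else amp[afferent])

    def with_random_latencies(self, seed: int) -> "PatternSpec":
        """Return a copy whose latencies are fresh homogeneous-Poisson draws."""
        rng = np.random.default_rng(seed)
        lats = [
            make_latencies(self.pattern_duration, self.background_rate, rng=rng)
            for _ in range(self.n_pattern)
        ]
        return replace(self, latencies=lats)


@dataclass
class PresentationSchedule:
    """Sorted presentation onsets (ms) over [0, total_duration]."""

    onsets: np.ndarray
    total_duration: float
    pattern_duration: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size:
            if np.any(np.diff(self.onsets) < self.pattern_duration):
                raise ValueError("presentations overlap")
            if self.onsets[0] < 0 or self.onsets[-1] > self.total_duration - self.pattern_duration:
                raise ValueError("onsets out of range")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Onsets falling in [t0, t1)."""
        i0, i1 = np.searchsorted(self.onsets, [t0, t1])
        return self.onsets[i0:i1]


@dataclass
class SpikeTrainSet:
    """Per-afferent sorted spike times (ms) over [0, total_duration]."""

    trains: list[np.ndarray]
    total_duration: float
    pattern_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pattern_mask = np.asarray(self.pattern_mask, dtype=bool)

    @property
    def n_afferents(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def rates(self) -> np.ndarray:
        """Empirical mean rate per afferent, Hz."""
        return self.counts() / (self.total_duration / 1000.0)

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (times, afferent_ids), time-sorted (stable)."""
        times = np.concatenate(self.trains) if self.trains else np.empty(0)
        ids = np.repeat(np.arange(len(self.trains)), self.counts())
        order = np.argsort(times, kind="stable")
        return times[order], ids[order]


@dataclass
class RateFunctionSet:
    """Lazy per-afferent intensity functions (sum of Gaussian rate peaks).

    Stores, per afferent, the peak centers (ms), widths (ms) and areas; the
    instantaneous rate is materialized on demand with :meth:`sample`.  An
    optional shared multiplicative envelope applies to all afferents.
    """

    centers: list[np.ndarray]
    widths: list[np.ndarray]
    areas: list[np.ndarray]
    total_duration: float
    grid_step: float = 0.1
    envelope: "Envelope | None" = None

    def intensity(self, afferent: int, t: np.ndarray) -> np.ndarray:
        """Instantaneous rate (Hz) of one afferent at times ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        c, w, a = self.centers[afferent], self.widths[afferent], self.areas[afferent]
        lam = np.zeros_like(t)
        if c.size:
            order = np.argsort(c)
            c, w, a = c[order], w[order], a[order]
            wmax = float(w.max(initial=0.0)) or 1e-9
            lo = np.searchsorted(c, t - 6.0 * wmax)
            hi = np.searchsorted(c, t + 6.0 * wmax)
            for k, tk in enumerate(t):
                sl = slice(lo[k], hi[k])
                if hi[k] > lo[k]:
                    z = (tk - c[sl]) / w[sl]
                    lam[k] = np.sum(a[sl] * np.exp(-0.5 * z * z) / (w[sl] * np.sqrt(2 * np.pi)))
        lam *= 1000.0  # per-ms density of unit-area peaks -> Hz
        if self.envelope is not None:
            lam = np.maximum(lam * self.envelope(t), 0.0)
        return lam

    def sample(self, afferent: int, t0: float = 0.0, t1: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Intensity on a uniform grid over [t0, t1]; returns (grid_ms, rate_hz)."""
        t1 = self.total_duration if t1 is None else t1
        grid = np.arange(t0, t1 + 0.5 * self.grid_step, self.grid_step)
        return grid, self.intensity(afferent, grid)


@dataclass
class Envelope:
    """Shared global rate envelope, unit mean, evaluated from its peak centers."""

    centers: np.ndarray
    width: float
    center_rate_ms: float  # peaks per ms; the normalization constant

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        c = np.sort(self.centers)
        lo = np.searchsorted(c, t - 6.0 * self.width)
        hi = np.searchsorted(c, t + 6.0 * self.width)
        norm = self.width * np.sqrt(2 * np.pi)
        for k, tk in enumerate(t):
            if hi[k] > lo[k]:
                z = (tk - c[lo[k]:hi[k]]) / self.width
                out[k] = np.sum(np.exp(-0.5 * z * z)) / norm
        return out / self.center_rate_ms


# ---------------------------------------------------------------------------
# schedules and latencies
# ---------------------------------------------------------------------------

def make_schedule(
    total_duration: float,
    presentation_rate: float,
    pattern_duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PresentationSchedule:
    """Random non-overlapping presentation onsets with mean rate ``presentation_rate``.

    Candidate onsets are a homogeneous Poisson process at the dead-time
    compensated rate ``nu / (1 - nu * Delta)``; candidates closer than
    ``Delta`` to the previously accepted onset are dropped, so the delivered
    onset process has mean rate ``nu`` and no two presentations overlap.
    """
    nu_ms = presentation_rate / 1000.0
    nu_delta = nu_ms * pattern_duration
    if nu_delta >= 1.0:
        raise ValueError("presentation_rate * pattern_duration must be < 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    horizon = total_duration - pattern_duration
    if horizon <= 0:
        return PresentationSchedule(np.empty(0), total_duration, pattern_duration)
    lam = nu_ms / (1.0 - nu_delta)
    n_cand = rng.poisson(lam * horizon)
    cand = np.sort(rng.random(n_cand) * horizon)
    onsets = []
    last = -np.inf
    for t in cand:
        if t - last >= pattern_duration:
            onsets.append(t)
            last = t
    return PresentationSchedule(np.array(onsets), total_duration, pattern_duration)


def make_latencies(
    pattern_duration: float,
    background_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One realization of a homogeneous Poisson process on [0, Delta).

    The number of latencies is Poisson(r0 * Delta) — possibly zero — and each
    latency is uniform on [0, Delta).
    """
    if pattern_duration < 0 or background_rate < 0:
        raise ValueError("pattern_duration and background_rate must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = rng.poisson(background_rate / 1000.0 * pattern_duration)
    return np.sort(rng.random(n) * pattern_duration)


def draw_uniform_latencies(spec: PatternSpec, seed: int) -> PatternSpec:
    """Alias for :meth:`PatternSpec.with_random_latencies` (uniform latencies)."""
    return spec.with_random_latencies(seed)


def resolve_bimodal(spec: PatternSpec, seed: int) -> PatternSpec:
    """Materialize an SB/RB spec into a concrete S/R spec with explicit latencies.

    SB: each group-k afferent receives a single latency drawn from
    N(mean_latency_k, width_k^2), clipped into [0, Delta); spikes are reliable
    (p = 1) and unjittered.  RB: every group-k afferent carries the same
    Gaussian rate peak centered on mean_latency_k with width width_k and unit
    amplitude.  Pattern afferents beyond the two groups receive no latencies.
    """
    if spec.model_kind not in BIMODAL_MODELS:
        raise ValueError("resolve_bimodal expects an SB or RB spec")
    rng = np.random.default_rng(seed)
    g1, g2 = spec.group_spec
    lats: list[np.ndarray] = []
    widths = np.zeros(spec.n_pattern)
    hi = spec.pattern_duration * (1.0 - 1e-9)
    for g, lo_idx in ((g1, 0), (g2, g1.size)):
        for _ in range(g.size):
            if spec.model_kind == "SB":
                lam = np.clip(rng.normal(g.mean_latency, g.width), 0.0, hi)
                lats.append(np.array([lam]))
            else:
                lats.append(np.array([g.mean_latency]))
        widths[lo_idx:lo_idx + g.size] = 0.0 if spec.model_kind == "SB" else g.width
    for _ in range(spec.n_pattern - g1.size - g2.size):
        lats.append(np.empty(0))
    kind = "S" if spec.model_kind == "SB" else "R"
    return replace(
        spec,
        model_kind=kind,
        latencies=lats,
        occurrence_prob=1.0,
        jitter_width=widths if kind == "R" else 0.0,
        amplitude=1.0,
        group_spec=spec.group_spec,
    )


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _gaps(window: tuple[float, float], onsets: np.ndarray, delta: float) -> np.ndarray:
    """Sub-intervals of [t0, t1) not covered by any presentation window."""
    t0, t1 = window
    # consider presentations possibly intersecting the window
    lo = np.searchsorted(onsets, t0 - delta)
    hi = np.searchsorted(onsets, t1)
    segs = []
    cur = t0
    for o in onsets[lo:hi]:
        a, b = max(o, t0), min(o + delta, t1)
        if b > a:
            if a > cur:
                segs.append((cur, a))
            cur = max(cur, b)
    if cur < t1:
        segs.append((cur, t1))
    return np.array(segs).reshape(-1, 2)


def _poisson_on_gaps(
    rng: np.random.Generator, rate_ms: float, gaps: np.ndarray, n_chan: int
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson events on a union of intervals for ``n_chan`` channels.

    Returns flat (times, channel) arrays, unsorted.
    """
    if gaps.size == 0 or rate_ms <= 0 or n_chan == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    lens = gaps[:, 1] - gaps[:, 0]
    total = float(lens.sum())
    counts = rng.poisson(rate_ms * total, size=n_chan)
    n = int(counts.sum())
    u = rng.random(n) * total
    edges = np.concatenate(([0.0], np.cumsum(lens)))
    seg = np.searchsorted(edges, u, side="right") - 1
    times = gaps[seg, 0] + (u - edges[seg])
    chan = np.repeat(np.arange(n_chan, dtype=np.int64), counts)
    return times, chan


def _flat_latencies(spec: PatternSpec) -> tuple[np.ndarray, np.ndarray]:
    lat = np.concatenate(spec.latencies) if spec.latencies else np.empty(0)
    owner = np.repeat(
        np.arange(spec.n_pattern, dtype=np.int64),
        [l.size for l in spec.latencies],
    )
    return lat, owner


def _sample_window(
    spec: PatternSpec,
    schedule: PresentationSchedule,
    rng: np.random.Generator,
    t0: float,
    t1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """All spikes with 'cause' inside [t0, t1): presentations with onset in the
    window plus background on the window's complement of presentation time.

    Spike times may spill slightly outside the window (jitter, rate-peak
    tails); the caller decides whether to clip or carry them over.
    Returns flat unsorted (times, afferent_id).
    """
    delta = spec.pattern_duration
    r_ms = spec.background_rate / 1000.0
    p = spec.occurrence_prob
    onsets = schedule.window(t0, t1)
    out_t: list[np.ndarray] = []
    out_i: list[np.ndarray] = []

    sig = np.asarray(spec.jitter_width, dtype=float)
    amp = np.asarray(spec.amplitude, dtype=float)
    lat, owner = _flat_latencies(spec)
    sig_o = sig[owner] if sig.ndim else np.full(owner.size, float(sig))
    amp_o = amp[owner] if amp.ndim else np.full(owner.size, float(amp))

    if spec.model_kind in SPIKE_MODELS:
        if onsets.size and lat.size:
            centers = onsets[:, None] + lat[None, :]  # (K, L)
            keep = rng.random(centers.shape) < p if p < 1.0 else np.ones(centers.shape, bool)
            times = centers[keep]
            owners = np.broadcast_to(owner, centers.shape)[keep]
            if spec.model_kind == "SJ":
                s = np.broadcast_to(sig_o, centers.shape)[keep]
                times = times + rng.normal(size=times.size) * s
            out_t.append(times)
            out_i.append(owners)
        if onsets.size and p < 1.0:
            # rate-preserving compensation inside the presentation window
            comp_rate = (1.0 - p) * r_ms
            counts = rng.poisson(comp_rate * delta, size=(onsets.size, spec.n_pattern))
            n = int(counts.sum())
            times = np.repeat(onsets, counts.sum(axis=1)) + rng.random(n) * delta
            pres_chan = np.broadcast_to(np.arange(spec.n_pattern), counts.shape)
            out_t.append(times)
            out_i.append(np.repeat(pres_chan.ravel(), counts.ravel()))
        # background: pattern afferents outside presentations ...
        gaps = _gaps((t0, t1), schedule.onsets, delta)
        bt, bi = _poisson_on_gaps(rng, r_ms, gaps, spec.n_pattern)
        out_t.append(bt)
        out_i.append(bi)
        # ... non-pattern afferents everywhere (fresh latencies fired with
        # probability p plus (1-p)-rate compensation collapse to a
        # homogeneous Poisson process at r0)
        nt, ni = _poisson_on_gaps(
            rng, r_ms, np.array([[t0, t1]]), spec.n_total - spec.n_pattern
        )
        out_t.append(nt)
        out_i.append(ni + spec.n_pattern)
    elif spec.model_kind == "R":
        # collect rate-peak centers, then sample K~Poisson(area) spikes per
        # peak at N(center, sigma^2): exactly the inhomogeneous Poisson
        # process whose intensity is the sum of the Gaussian peaks.
        cen_t: list[np.ndarray] = []
        cen_i: list[np.ndarray] = []
        cen_s: list[np.ndarray] = []
        cen_a: list[np.ndarray] = []
        if onsets.size and lat.size:
            centers = (onsets[:, None] + lat[None, :]).ravel()
            cen_t.append(centers)
            cen_i.append(np.tile(owner, onsets.size))
            cen_s.append(np.tile(sig_o, onsets.size))
            cen_a.append(np.tile(amp_o, onsets.size))
        gaps = _gaps((t0, t1), schedule.onsets, delta)
        bt, bi = _poisson_on_gaps(rng, r_ms, gaps, spec.n_pattern)
        cen_t.append(bt)
        cen_i.append(bi)
        cen_s.append(sig[bi] if sig.ndim else np.full(bi.size, float(sig)))
        cen_a.append(amp[bi] if amp.ndim else np.full(bi.size, float(amp)))
        nt, ni = _poisson_on_gaps(
            rng, r_ms, np.array([[t0, t1]]), spec.n_total - spec.n_pattern
        )
        ni = ni + spec.n_pattern
        cen_t.append(nt)
        cen_i.append(ni)
        cen_s.append(np.full(ni.size, float(np.mean(sig))))
        cen_a.append(np.full(ni.size, float(np.mean(amp))))
        c = np.concatenate(cen_t)
        ci = np.concatenate(cen_i)
        cs = np.concatenate(cen_s)
        ca = np.concatenate(cen_a)
        k = rng.poisson(ca)
        times = np.repeat(c, k) + rng.normal(size=int(k.sum())) * np.repeat(cs, k)
        out_t.append(times)
        out_i.append(np.repeat(ci, k))
        return np.concatenate(out_t), np.concatenate(out_i)
    else:  # pragma: no cover - resolved upstream
        raise ValueError(f"cannot sample model {spec.model_kind} directly")
    return np.concatenate(out_t), np.concatenate(out_i)


def _flat_to_set(
    times: np.ndarray, ids: np.ndarray, spec: PatternSpec, total_duration: float
) -> SpikeTrainSet:
    keep = (times >= 0.0) & (times < total_duration)
    times, ids = times[keep], ids[keep]
    order = np.lexsort((times, ids))
    times, ids = times[order], ids[order]
    counts = np.bincount(ids, minlength=spec.n_total)
    trains = np.split(times, np.cumsum(counts)[:-1])
    mask = np.zeros(spec.n_total, dtype=bool)
    mask[: spec.n_pattern] = True
    return SpikeTrainSet([np.ascontiguousarray(t) for t in trains], total_duration, mask)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _require_latencies(spec: PatternSpec) -> None:
    if spec.latencies is None:
        raise ValueError(
            "spec.latencies must be populated (use with_random_latencies)"
        )


def gen_spike_pattern(
    spec: PatternSpec, schedule: PresentationSchedule, seed: int
) -> SpikeTrainSet:
    """Spike-pattern ensemble for models S, SD and SJ."""
    if spec.model_kind not in SPIKE_MODELS:
        raise ValueError("gen_spike_pattern handles models S, SD, SJ")
    _require_latencies(spec)
    rng = np.random.default_rng(seed)
    t, i = _sample_window(spec, schedule, rng, 0.0, schedule.total_duration)
    return _flat_to_set(t, i, spec, schedule.total_duration)


def gen_rate_pattern(
    spec: PatternSpec, schedule: PresentationSchedule, seed: int
) -> tuple[SpikeTrainSet, RateFunctionSet]:
    """Rate-modulated ensemble (model R) plus its intensity functions."""
    if spec.model_kind != "R":
        raise ValueError("gen_rate_pattern handles model R")
    _require_latencies(spec)
    rng = np.random.default_rng(seed)
    t, i = _sample_window(spec, schedule, rng, 0.0, schedule.total_duration)
    ts = _flat_to_set(t, i, spec, schedule.total_duration)
    rates = _rate_functions(spec, schedule, seed)
    return ts, rates


def _rate_functions(
    spec: PatternSpec, schedule: PresentationSchedule, seed: int
) -> RateFunctionSet:
    """Rebuild the peak centers of the model-R intensity, deterministically.

    Uses an independent RNG stream from the same seed, replaying the
    background-center draws of :func:`gen_rate_pattern` so that the returned
    intensities are the ones the spikes were sampled from.
    """
    rng = np.random.default_rng(seed)
    delta = spec.pattern_duration
    r_ms = spec.background_rate / 1000.0
    sig = np.asarray(spec.jitter_width, dtype=float)
    amp = np.asarray(spec.amplitude, dtype=float)
    lat, owner = _flat_latencies(spec)
    onsets = schedule.onsets
    centers = [[] for _ in range(spec.n_total)]
    if onsets.size and lat.size:
        allc = (onsets[:, None] + lat[None, :]).ravel()
        alli = np.tile(owner, onsets.size)
        for i in range(spec.n_pattern):
            centers[i].append(allc[alli == i])
    gaps = _gaps((0.0, schedule.total_duration), onsets, delta)
    bt, bi = _poisson_on_gaps(rng, r_ms, gaps, spec.n_pattern)
    for i in range(spec.n_pattern):
        centers[i].append(bt[bi == i])
    nt, ni = _poisson_on_gaps(
        rng, r_ms, np.array([[0.0, schedule.total_duration]]),
        spec.n_total - spec.n_pattern,
    )
    for i in range(spec.n_total - spec.n_pattern):
        centers[spec.n_pattern + i].append(nt[ni == i])
    cen = [np.sort(np.concatenate(c)) if c else np.empty(0) for c in centers]

    def _per(i: int, arr: np.ndarray) -> float:
        if arr.ndim == 0:
            return float(arr)
        return float(arr[i]) if i < spec.n_pattern else float(np.mean(arr))

    widths = [np.full(c.size, _per(i, sig)) for i, c in enumerate(cen)]
    areas = [np.full(c.size, _per(i, amp)) for i, c in enumerate(cen)]
    return RateFunctionSet(cen, widths, areas, schedule.total_duration)


def gen_bimodal_pattern(
    spec: PatternSpec, schedule: PresentationSchedule, seed: int
) -> SpikeTrainSet:
    """Bimodal pattern (SB or RB): resolve group structure, then delegate."""
    if spec.model_kind not in BIMODAL_MODELS:
        raise ValueError("gen_bimodal_pattern handles models SB and RB")
    concrete = resolve_bimodal(spec, seed)
    if concrete.model_kind == "S":
        return gen_spike_pattern(concrete, schedule, seed + 1)
    return gen_rate_pattern(concrete, schedule, seed + 1)[0]


def gen_envelope_pattern(
    spec: PatternSpec, schedule: PresentationSchedule, seed: int
) -> tuple[SpikeTrainSet, RateFunctionSet]:
    """Model R under a shared global rate envelope.

    The envelope is a unit-mean sum of Gaussian peaks whose centers follow a
    homogeneous Poisson process; outside presentations it is drawn freshly,
    while one fixed within-pattern envelope segment repeats identically at
    every presentation.  Spikes are drawn by thinning model-R candidates
    against a numerical upper bound of the envelope.
    """
    if spec.model_kind != "R_envelope":
        raise ValueError("gen_envelope_pattern handles model R_envelope")
    _require_latencies(spec)
    env_spec = spec.envelope_spec or EnvelopeSpec()
    rng = np.random.default_rng(seed)
    delta = spec.pattern_duration
    T = schedule.total_duration
    rate_ms = env_spec.center_rate / 1000.0
    w = env_spec.peak_width
    # within-pattern envelope segment, re-used at every presentation
    n_in = rng.poisson(rate_ms * (delta + 8 * w))
    seg = rng.random(n_in) * (delta + 8 * w) - 4 * w
    gaps = _gaps((0.0, T), schedule.onsets, delta)
    bg_t, _ = _poisson_on_gaps(rng, rate_ms, gaps, 1)
    env_centers = np.concatenate(
        [bg_t] + [o + seg for o in schedule.onsets]
    )
    envelope = Envelope(np.sort(env_centers), w, rate_ms)

    base = replace(spec, model_kind="R", envelope_spec=None)
    # candidates from the un-modulated model R, boosted by the envelope bound
    grid = np.arange(0.0, T, max(w / 4.0, 1.0))
    env_bound = float(envelope(grid).max()) * 1.2 + 0.1
    boosted = replace(base, amplitude=np.asarray(spec.amplitude, dtype=float) * env_bound)
    t, i = _sample_window(boosted, schedule, np.random.default_rng(seed + 1), 0.0, T)
    accept = np.random.default_rng(seed + 2).random(t.size) * env_bound <= envelope(t)
    ts = _flat_to_set(t[accept], i[accept], spec, T)
    rates = _rate_functions(base, schedule, seed + 1)
    rates.envelope = envelope
    return ts, rates


def generate(spec: PatternSpec, schedule: PresentationSchedule, seed: int) -> SpikeTrainSet:
    """Dispatch to the generator matching ``spec.model_kind``."""
    if spec.model_kind in SPIKE_MODELS:
        return gen_spike_pattern(spec, schedule, seed)
    if spec.model_kind == "R":
        return gen_rate_pattern(spec, schedule, seed)[0]
    if spec.model_kind in BIMODAL_MODELS:
        return gen_bimodal_pattern(spec, schedule, seed)
    return gen_envelope_pattern(spec, schedule, seed)[0]


# ---------------------------------------------------------------------------
# persistence (delimited text)
# ---------------------------------------------------------------------------

def write_spikes(train_set: SpikeTrainSet, path) -> None:
    """Tab-delimited spike file: ``afferent_id<TAB>time_ms``, sorted by (afferent, time)."""
    with open(path, "w") as fh:
        fh.write("afferent_id\ttime_ms\n")
        for i, train in enumerate(train_set.trains):
            for t in train:
                fh.write(f"{i}\t{t:.6f}\n")


def read_spikes(path, n_afferents: int | None = None, total_duration: float | None = None) -> SpikeTrainSet:
    ids, times = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("afferent_id"):
            raise ValueError("missing spike-file header")
        for line in fh:
            a, t = line.split("\t")
            ids.append(int(a))
            times.append(float(t))
    ids_a = np.array(ids, dtype=np.int64)
    times_a = np.array(times)
    n = n_afferents if n_afferents is not None else (int(ids_a.max()) + 1 if ids_a.size else 0)
    counts = np.bincount(ids_a, minlength=n)
    order = np.lexsort((times_a, ids_a))
    trains = np.split(times_a[order], np.cumsum(counts)[:-1])
    T = total_duration if total_duration is not None else (float(times_a.max()) + 1.0 if times_a.size else 0.0)
    return SpikeTrainSet(list(trains), T, np.zeros(n, dtype=bool))


def write_schedule(schedule: PresentationSchedule, path) -> None:
    with open(path, "w") as fh:
        for o in schedule.onsets:
            fh.write(f"{o:.6f}\n")


def read_schedule(path, total_duration: float, pattern_duration: float) -> PresentationSchedule:
    onsets = np.loadtxt(path, ndmin=1) if _nonempty(path) else np.empty(0)
    return PresentationSchedule(onsets, total_duration, pattern_duration)


def _nonempty(path) -> bool:
    import os

    return os.path.getsize(path) > 0
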