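"""Online pair-based STDP with homeostatic rate terms, and the learning loop.

Every presynaptic spike contributes a fixed increment ``eta * w_in``, every
postsynaptic spike ``eta * w_out``, and every pre/post pair contributes once
through the exponential learning window (lag convention u = t_pre - t_post):

    W(u) = f_plus(w)  * A_plus  * exp(u / tau_plus),   u < 0  (causal, LTP)
    W(u) = -f_minus(w) * A_minus * exp(-u / tau_minus), u > 0  (LTD)

Additive STDP uses constant scaling functions and hard clipping to
[0, w_max]; the weight-dependent variant uses the soft-bound scalings
``f_plus = (1 - w/w_max)^mu`` and ``f_minus = alpha (w/w_max)^mu`` (and then
runs without the homeostatic rate terms).  The all-to-all pair sum is
implemented with exponential traces, which is exact for this window.

The closed learning loop alternates chunked input generation, stochastic
neuron simulation and online plasticity; the convergence index (the mean
distance of the weights to their nearest bound) tracks the emergence of the
bimodal weight distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .neurons import NeuronParams, OutputTrace
from .patterns import (
    BIMODAL_MODELS,
    PatternSpec,
    PresentationSchedule,
    SpikeTrainSet,
    _flat_to_set,
    _sample_window,
    make_schedule,
    resolve_bimodal,
)

__all__ = [
    "STDPParams",
    "SynapseState",
    "LearningResult",
    "window_W",
    "apply_stdp_stream",
    "run_learning",
    "convergence_index",
    "classify_weights",
    "write_snapshots",
    "write_convergence_log",
]


@dataclass
class STDPParams:
    """STDP and homeostasis parameters (amplitudes in weight units, taus ms).

    Defaults realize a depression-dominated window (integral
    ``A_plus tau_plus - A_minus tau_minus < 0``) with the LTP/LTD integral
    ratio at 0.82, plus homeostatic per-spike terms sized for a stable
    low-rate equilibrium of the mean weight.
    """

    learning_rate: float = 2.5e-3
    ltp_amp: float = 1.0
    ltd_amp: float = 0.61
    ltp_tau: float = 16.8
    ltd_tau: float = 33.7
    rate_in: float = 0.055
    rate_out: float = -0.2
    w_max: float = 1.0
    mode: str = "additive"
    wd_exponent: float = 0.05
    wd_asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.ltp_tau <= 0 or self.ltd_tau <= 0:
            raise ValueError("window time constants must be > 0")
        if not (0.0 <= self.wd_exponent <= 1.0):
            raise ValueError("wd_exponent must lie in [0, 1]")
        if self.mode not in ("additive", "weight_dependent"):
            raise ValueError("mode must be 'additive' or 'weight_dependent'")

    @property
    def window_integral(self) -> float:
        """Integral of the additive window, A+tau+ - A-tau- (weight * ms)."""
        return self.ltp_amp * self.ltp_tau - self.ltd_amp * self.ltd_tau

    @property
    def mode_flag(self) -> int:
        return _kernels.ADDITIVE if self.mode == "additive" else _kernels.WEIGHT_DEPENDENT

    def effective_rate_terms(self) -> tuple[float, float]:
        """Homeostatic per-spike terms actually applied (disabled in
        weight-dependent mode, where the soft bounds provide homeostasis)."""
        if self.mode == "weight_dependent":
            return 0.0, 0.0
        return self.rate_in, self.rate_out


@dataclass
class SynapseState:
    """Plastic weights with their STDP traces and optional snapshot log."""

    weights: np.ndarray
    pre_traces: np.ndarray
    pre_trace_times: np.ndarray
    post_trace: float = 0.0
    post_trace_time: float = 0.0
    snapshots: list = field(default_factory=list)  # (time_s, weights copy)

    @classmethod
    def init(cls, n: int, w_init_max: float, seed: int | None = None) -> "SynapseState":
        """Initial weights uniform on [0, w_init_max] (below the upper bound)."""
        rng = np.random.default_rng(seed)
        return cls(
            weights=rng.random(n) * w_init_max,
            pre_traces=np.zeros(n),
            pre_trace_times=np.zeros(n),
        )


def window_W(lag, params: STDPParams, weight: float | None = None):
    """Learning window W(u) at lag u = t_pre - t_post (weight units).

    Negative lags (pre before post) potentiate, positive lags depress;
    W(0) = 0 by the tie convention.  ``weight`` engages the soft-bound
    scaling functions in weight-dependent mode.
    """
    u = np.asarray(lag, dtype=float)
    if weight is None or params.mode == "additive":
        fp, fm = 1.0, 1.0
    else:
        fp = (1.0 - weight / params.w_max) ** params.wd_exponent
        fm = params.wd_asymmetry * (weight / params.w_max) ** params.wd_exponent
    pot = fp * params.ltp_amp * np.exp(u / params.ltp_tau)
    dep = -fm * params.ltd_amp * np.exp(-u / params.ltd_tau)
    return np.where(u < 0, pot, np.where(u > 0, dep, 0.0))


def apply_stdp_stream(
    pre_times: np.ndarray,
    pre_syns: np.ndarray,
    post_times: np.ndarray,
    state: SynapseState,
    params: STDPParams,
) -> SynapseState:
    """Apply the online trace rule to externally supplied event streams.

    Reference implementation (plain Python), exactly equivalent to the
    all-pairs double sum for the exponential window; used when pre and post
    spikes are given rather than generated in the closed loop.  Events must
    be time-sorted; at equal times the presynaptic event is applied first.
    """
    pre_times = np.asarray(pre_times, dtype=float)
    post_times = np.asarray(post_times, dtype=float)
    if np.any(np.diff(pre_times) < 0) or np.any(np.diff(post_times) < 0):
        raise ValueError("event streams must be time-sorted")
    eta = params.learning_rate
    w_in, w_out = params.effective_rate_terms()
    w = state.weights
    x, tx = state.pre_traces, state.pre_trace_times
    y, ty = state.post_trace, state.post_trace_time
    additive = params.mode == "additive"
    mu, alpha, wmax = params.wd_exponent, params.wd_asymmetry, params.w_max
    ip = 0
    events = []  # merged (t, kind, syn); pre sorts before post at ties
    for t, s in zip(pre_times, pre_syns):
        events.append((t, 0, int(s)))
    for t in post_times:
        events.append((t, 1, -1))
    events.sort()
    for t, kind, s in events:
        if kind == 0:
            yv = y * np.exp(-(t - ty) / params.ltd_tau)  # carries the A_minus amplitudes
            fm = 1.0 if additive else alpha * (w[s] / wmax) ** mu
            w[s] += eta * (w_in - fm * yv)
            if additive:
                w[s] = min(max(w[s], 0.0), wmax)
            x[s] = x[s] * np.exp(-(t - tx[s]) / params.ltp_tau) + params.ltp_amp
            tx[s] = t
        else:
            y = y * np.exp(-(t - ty) / params.ltd_tau) + params.ltd_amp
            ty = t
            xv = x * np.exp(-(t - tx) / params.ltp_tau)
            x[:] = xv
            tx[:] = t
            fp = 1.0 if additive else (1.0 - w / wmax) ** mu
            w += eta * (w_out + fp * xv)
            if additive:
                np.clip(w, 0.0, wmax, out=w)
    state.post_trace, state.post_trace_time = y, ty
    return state


def convergence_index(weights: np.ndarray, w_max: float) -> float:
    """Mean distance of the weights to their nearest bound, in units of w_max.

    Positive, maximal (0.5) for weights at w_max/2, and vanishing exactly
    when every synapse sits at 0 or w_max (fully bimodal distribution).
    """
    w = np.asarray(weights, dtype=float)
    return float(np.mean(np.minimum(w, w_max - w)) / w_max)


def classify_weights(
    weights: np.ndarray, threshold: float | None = None, w_max: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition synapses into (potentiated, depressed) index arrays.

    The default threshold is w_max/2, robust once the distribution is
    bimodal (almost no mass sits mid-range after convergence).
    """
    w = np.asarray(weights, dtype=float)
    thr = w_max / 2.0 if threshold is None else threshold
    pot = np.flatnonzero(w > thr)
    dep = np.flatnonzero(w <= thr)
    return pot, dep


@dataclass
class LearningResult:
    state: SynapseState
    output: OutputTrace
    schedule: PresentationSchedule
    spec: PatternSpec
    conv_times: np.ndarray  # s
    conv_raw: np.ndarray
    conv_smooth: np.ndarray  # running mean of the last 4 raw points

    @property
    def weights(self) -> np.ndarray:
        return self.state.weights


def run_learning(
    spec: PatternSpec,
    neuron: NeuronParams,
    stdp: STDPParams,
    duration_s: float,
    seed: int,
    snapshot_every_s: float = 50.0,
    chunk_s: float = 10.0,
    w_init_max: float = 0.25,
    neuron_model: str = "poisson",
    schedule: PresentationSchedule | None = None,
    initial_weights: np.ndarray | None = None,
) -> LearningResult:
    """Closed-loop training: generate inputs, fire the neuron, adapt weights.

    Inputs are generated in ``chunk_s`` chunks (much longer than the EPSP and
    STDP supports; boundary traces are carried across chunks exactly for the
    Poisson neuron).  The convergence index is logged every 50 simulated
    seconds with a 4-point running average, and weight snapshots are taken
    every ``snapshot_every_s``.
    """
    from .theory import homeostatic_equilibrium  # local import; no cycle at module load

    T = duration_s * 1000.0
    if spec.model_kind in BIMODAL_MODELS:
        spec = resolve_bimodal(spec, seed + 101)
    if spec.latencies is None:
        spec = spec.with_random_latencies(seed + 103)
    eq = homeostatic_equilibrium(stdp, neuron, spec)
    if stdp.mode == "additive" and not eq.realizable:
        warnings.warn(
            "homeostatic equilibrium not realizable (w_eq outside the weight "
            "bounds); training may depress or saturate all synapses",
            stacklevel=2,
        )
    if schedule is None:
        schedule = make_schedule(
            T, spec.presentation_rate, spec.pattern_duration, seed=seed + 104
        )
    state = SynapseState.init(spec.n_total, w_init_max, seed + 105)
    if initial_weights is not None:
        state.weights = np.asarray(initial_weights, dtype=float).copy()
    w_in, w_out = stdp.effective_rate_terms()

    if neuron_model == "lif" and neuron.lif_threshold is None:
        raise ValueError("neuron.lif_threshold required for LIF training")

    y_state = np.zeros(2)
    epsp_state = np.zeros(3)
    post_all: list[np.ndarray] = []
    conv_t: list[float] = []
    conv_v: list[float] = []
    hold_t = np.empty(0)
    hold_i = np.empty(0, dtype=np.int64)
    log_every_ms = 50.0 * 1000.0
    next_log = log_every_ms
    next_snap = snapshot_every_s * 1000.0
    n_chunks = int(np.ceil(T / (chunk_s * 1000.0)))
    rng_root = np.random.SeedSequence(seed)
    chunk_seeds = rng_root.generate_state(2 * n_chunks + 2)

    for c in range(n_chunks):
        t0 = c * chunk_s * 1000.0
        t1 = min(T, t0 + chunk_s * 1000.0)
        rng = np.random.default_rng(chunk_seeds[2 * c])
        t, i = _sample_window(spec, schedule, rng, t0, t1)
        t = np.concatenate([hold_t, t])
        i = np.concatenate([hold_i, i])
        keep = t >= t0
        t, i = t[keep], i[keep]
        late = t >= t1
        hold_t, hold_i = t[late], i[late]
        t, i = t[~late], i[~late]
        order = np.argsort(t, kind="stable")
        t = np.ascontiguousarray(t[order])
        i = np.ascontiguousarray(i[order].astype(np.int64))
        kseed = int(chunk_seeds[2 * c + 1] % (2**31 - 1))
        cap = max(int(t.size * 0.5) + 4096, 65536)
        while True:
            buf = np.empty(cap)
            w_bak = state.weights.copy()
            x_bak = state.pre_traces.copy()
            tx_bak = state.pre_trace_times.copy()
            y_bak = y_state.copy()
            e_bak = epsp_state.copy()
            if neuron_model == "poisson":
                n = _kernels.run_closed_loop(
                    t, i, t0, t1,
                    neuron.rho0_ms, neuron.epsp_decay, neuron.epsp_rise,
                    stdp.learning_rate, stdp.ltp_amp, stdp.ltd_amp,
                    stdp.ltp_tau, stdp.ltd_tau, w_in, w_out, stdp.w_max,
                    stdp.mode_flag, stdp.wd_exponent, stdp.wd_asymmetry,
                    state.weights, state.pre_traces, state.pre_trace_times,
                    y_state, epsp_state, kseed, buf,
                )
            else:
                n = _kernels.run_closed_loop_lif(
                    t, i, t0, t1,
                    neuron.rho0_ms, neuron.epsp_decay, neuron.epsp_rise,
                    neuron.lif_threshold / 1000.0, neuron.lif_refractory, 0.1,
                    stdp.learning_rate, stdp.ltp_amp, stdp.ltd_amp,
                    stdp.ltp_tau, stdp.ltd_tau, w_in, w_out, stdp.w_max,
                    stdp.mode_flag, stdp.wd_exponent, stdp.wd_asymmetry,
                    state.weights, state.pre_traces, state.pre_trace_times,
                    y_state, buf,
                )
            if n >= 0:
                post_all.append(buf[:n].copy())
                break
            state.weights[:] = w_bak
            state.pre_traces[:] = x_bak
            state.pre_trace_times[:] = tx_bak
            y_state[:] = y_bak
            epsp_state[:] = e_bak
            cap *= 4
        while next_log <= t1 + 1e-9:
            conv_t.append(next_log / 1000.0)
            conv_v.append(convergence_index(state.weights, stdp.w_max))
            next_log += log_every_ms
        while next_snap <= t1 + 1e-9:
            state.snapshots.append((next_snap / 1000.0, state.weights.copy()))
            next_snap += snapshot_every_s * 1000.0

    post = np.concatenate(post_all) if post_all else np.empty(0)
    conv_t_arr = np.asarray(conv_t)
    conv_raw = np.asarray(conv_v)
    smooth = np.array(
        [conv_raw[max(0, k - 3): k + 1].mean() for k in range(conv_raw.size)]
    )
    return LearningResult(
        state=state,
        output=OutputTrace(post),
        schedule=schedule,
        spec=spec,
        conv_times=conv_t_arr,
        conv_raw=conv_raw,
        conv_smooth=smooth,
    )


def write_snapshots(result: LearningResult, path) -> None:
    """Weight snapshots: ``time_s<TAB>synapse_id<TAB>weight``."""
    with open(path, "w") as fh:
        fh.write("time_s\tsynapse_id\tweight\n")
        for t_s, w in result.state.snapshots:
            for i, wi in enumerate(w):
                fh.write(f"{t_s:.1f}\t{i}\t{wi:.8f}\n")


def write_convergence_log(result: LearningResult, path) -> None:
    """Convergence log: ``time_s<TAB>index<TAB>running_avg``."""
    with open(path, "w") as fh:
        fh.write("time_s\tindex\trunning_avg\n")
        for t_s, v, s in zip(result.conv_times, result.conv_raw, result.conv_smooth):
            fh.write(f"{t_s:.1f}\t{v:.8f}\t{s:.8f}\n")
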