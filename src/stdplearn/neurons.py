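"""Postsynaptic neuron models: stochastic Poisson neuron and a LIF stand-in.

The Poisson neuron fires as an inhomogeneous Poisson process whose intensity
is the rectified lumped-EPSP drive

    lam(t) = [ rho0 + sum_i w_i sum_k eps(t - t_ik) ]_+ ,

with the normalized causal kernel
``eps(t) = H(t) (exp(-t/tau_m) - exp(-t/tau_r)) / (tau_m - tau_r)``
(so the stationary mean rate is ``rho0 + sum_i w_i r_i``).  The constant
drive ``rho0`` lumps all non-plastic inputs and is typically negative
(net inhibition), putting the neuron in a low-rate subthreshold regime.

The LIF neuron is a reconstruction (its exact published dynamics are not
available): a current-based integrate-and-fire unit whose free membrane
potential equals the same lumped-EPSP drive; crossing the threshold emits a
spike, clears the synaptic state back to the ``rho0`` baseline and imposes a
1 ms refractory period.  It satisfies the qualitative contract of the
original: deterministic, threshold-based, and driven by the identical
synaptic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .patterns import SpikeTrainSet

__all__ = [
    "NeuronParams",
    "OutputTrace",
    "epsp_kernel",
    "epsp_peak_time",
    "simulate_poisson_neuron",
    "simulate_lif_neuron",
    "lumped_epsp_trace",
    "calibrate_lif_threshold",
]


@dataclass
class NeuronParams:
    """Postsynaptic neuron parameters.

    ``base_drive`` is rho0 in Hz (negative = net inhibition); ``epsp_decay``
    and ``epsp_rise`` are the EPSP time constants tau_m > tau_r in ms.
    ``lif_threshold`` is in the same Hz-equivalent potential units as the
    lumped drive; ``lif_refractory`` in ms.
    """

    base_drive: float = -2050.0
    epsp_decay: float = 10.0
    epsp_rise: float = 1.0
    lif_threshold: float | None = None
    lif_refractory: float = 1.0

    def __post_init__(self) -> None:
        if not (self.epsp_decay > self.epsp_rise > 0):
            raise ValueError("need epsp_decay > epsp_rise > 0")

    @property
    def rho0_ms(self) -> float:
        return self.base_drive / 1000.0

    @property
    def epsp_sq_integral(self) -> float:
        """integral of eps(t)^2 dt (1/ms); sets the lumped-drive variance."""
        tm, tr = self.epsp_decay, self.epsp_rise
        return (tm / 2 + tr / 2 - 2 * tm * tr / (tm + tr)) / (tm - tr) ** 2


@dataclass
class OutputTrace:
    """Postsynaptic spikes (ms) plus an optional sampled lumped-EPSP path."""

    spikes: np.ndarray
    trace_times: np.ndarray | None = None
    trace_values: np.ndarray | None = None  # Hz-equivalent, unrectified


def epsp_kernel(t, params: NeuronParams):
    """Normalized causal EPSP kernel (1/ms): zero for t < 0, unit area."""
    tm, tr = params.epsp_decay, params.epsp_rise
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (np.exp(-t / tm) - np.exp(-np.minimum(t, 700 * tr) / tr)), 0.0)
    return out / (tm - tr)


def epsp_peak_time(params: NeuronParams) -> float:
    """Argmax of the EPSP kernel: tau_r tau_m / (tau_m - tau_r) * ln(tau_m/tau_r)."""
    tm, tr = params.epsp_decay, params.epsp_rise
    return tr * tm / (tm - tr) * np.log(tm / tr)


def _merged(inputs: SpikeTrainSet) -> tuple[np.ndarray, np.ndarray]:
    times, ids = inputs.merged()
    return np.ascontiguousarray(times), np.ascontiguousarray(ids)


def simulate_poisson_neuron(
    inputs: SpikeTrainSet,
    weights: np.ndarray,
    params: NeuronParams,
    seed: int,
) -> OutputTrace:
    """Sample the Poisson neuron's output spikes by exact thinning.

    Between input events the drive bound ``rho0 + E_m/(tau_m - tau_r)`` only
    decays, making the rejection sampling exact; the result is deterministic
    for a fixed seed.
    """
    weights = np.asarray(weights, dtype=float)
    times, ids = _merged(inputs)
    T = inputs.total_duration
    rates_ms = inputs.rates() / 1000.0
    mean_rate = max(params.rho0_ms + float(weights @ rates_ms), 0.0)
    cap = int(5 * max(mean_rate, 0.001) * T + 10000)
    while True:
        buf = np.empty(cap)
        st = _fresh_state(len(weights))
        n = _kernels.run_closed_loop(
            times, ids, 0.0, T,
            params.rho0_ms, params.epsp_decay, params.epsp_rise,
            0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0,
            _kernels.ADDITIVE, 0.0, 1.0,
            weights.copy(), st["x"], st["tx"], st["y"], st["epsp"],
            seed % (2**31 - 1), buf,
        )
        if n >= 0:
            return OutputTrace(buf[:n].copy())
        cap *= 4


def _fresh_state(n: int) -> dict:
    return {
        "w": np.zeros(n),
        "x": np.zeros(n),
        "tx": np.zeros(n),
        "y": np.zeros(2),
        "epsp": np.zeros(3),
    }


def lumped_epsp_trace(
    inputs: SpikeTrainSet,
    weights: np.ndarray,
    params: NeuronParams,
    grid_step: float = 0.1,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrectified drive ``rho0 + sum w_i eps`` (Hz) on a uniform grid.

    Rectification only shapes spike generation; this is the raw soma-potential
    proxy plotted against presentations.
    """
    weights = np.asarray(weights, dtype=float)
    times, ids = _merged(inputs)
    t_stop = inputs.total_duration if t_stop is None else t_stop
    n_steps = int(round((t_stop - t_start) / grid_step))
    vals = _kernels.lumped_trace(
        times, ids, weights, params.rho0_ms,
        params.epsp_decay, params.epsp_rise, t_start, grid_step, n_steps,
    )
    grid = t_start + np.arange(n_steps) * grid_step
    return grid, vals * 1000.0


def simulate_lif_neuron(
    inputs: SpikeTrainSet,
    weights: np.ndarray,
    params: NeuronParams,
    grid_step: float = 0.1,
) -> OutputTrace:
    """Deterministic LIF stand-in driven by the lumped-EPSP free potential."""
    if params.lif_threshold is None:
        raise ValueError("params.lif_threshold must be set (see calibrate_lif_threshold)")
    weights = np.asarray(weights, dtype=float)
    times, ids = _merged(inputs)
    T = inputs.total_duration
    cap = int(T / max(params.lif_refractory, grid_step)) + 16
    buf = np.empty(cap)
    n = _kernels.lif_run(
        times, ids, weights, params.rho0_ms,
        params.epsp_decay, params.epsp_rise,
        params.lif_threshold / 1000.0, params.lif_refractory, T, grid_step, buf,
    )
    return OutputTrace(buf[:max(n, 0)].copy())


def calibrate_lif_threshold(
    inputs: SpikeTrainSet,
    weights: np.ndarray,
    params: NeuronParams,
    target_rate: float,
    grid_step: float = 0.5,
) -> float:
    """Threshold (Hz-equivalent units) whose free-potential upcrossing rate
    matches ``target_rate`` (Hz), estimated from a trace quantile."""
    _, v = lumped_epsp_trace(inputs, weights, params, grid_step)
    frac = min(max(target_rate * params.epsp_decay / 1000.0, 1e-6), 0.5)
    return float(np.quantile(v, 1.0 - frac))
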