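"""Numba event-loop kernels shared by the neuron simulators and the learner.

All kernels work in internal units: time in ms, rates in spikes/ms, weights
dimensionless.  The lumped EPSP drive is carried by two exponential state
sums ``E_m = sum_k w_k exp(-(t - t_k)/tau_m)`` (and ``E_r`` alike), so the
instantaneous Poisson intensity is

    lam(t) = max(rho0 + (E_m - E_r)/(tau_m - tau_r), 0).

Between input events ``E_m`` only decays, hence
``rho0 + E_m/(tau_m - tau_r)`` is a valid running upper bound for thinning.
Plasticity uses exponential pre/post traces with lazily applied decay, which
reproduces the all-pairs double sum exactly for the exponential window.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ADDITIVE = 0
WEIGHT_DEPENDENT = 1


@njit(cache=True)
def _f_plus(w, w_max, mode, mu):
    if mode == ADDITIVE:
        return 1.0
    base = 1.0 - w / w_max
    if base < 0.0:
        base = 0.0
    return base**mu


@njit(cache=True)
def _f_minus(w, w_max, mode, mu, alpha):
    if mode == ADDITIVE:
        return 1.0
    base = w / w_max
    if base < 0.0:
        base = 0.0
    return alpha * base**mu


@njit(cache=True)
def run_closed_loop(
    ev_times,
    ev_syns,
    t_start,
    t_end,
    # neuron
    rho0,  # per ms
    tau_m,
    tau_r,
    # plasticity (eta <= 0 disables plasticity entirely)
    eta,
    a_plus,
    a_minus,
    tau_p,
    tau_d,
    w_in,
    w_out,
    w_max,
    mode,
    mu,
    alpha,
    # state (modified in place)
    w,
    x_pre,
    tx_last,
    y_state,  # (y, ty_last) as a 2-array
    epsp_state,  # (E_m, E_r, t_state) as a 3-array
    seed,
    out_spikes,
):
    """Advance the plastic Poisson neuron over one chunk of input events.

    Returns the number of postsynaptic spikes written to ``out_spikes``, or
    -1 if the buffer overflowed (caller must retry with a copy of the state).
    """
    np.random.seed(seed)
    n_syn = w.shape[0]
    inv_cm = 1.0 / (tau_m - tau_r)
    plastic = eta > 0.0

    E_m = epsp_state[0]
    E_r = epsp_state[1]
    t_cur = epsp_state[2]
    y = y_state[0]
    ty = y_state[1]

    n_out = 0
    n_ev = ev_times.shape[0]
    cap = out_spikes.shape[0]

    for k in range(n_ev + 1):
        t_next = ev_times[k] if k < n_ev else t_end
        # --- thinning for postsynaptic spikes on (t_cur, t_next) ----------
        while True:
            bound = rho0 + E_m * inv_cm
            if bound <= 1e-12:
                dt = t_next - t_cur
                E_m *= np.exp(-dt / tau_m)
                E_r *= np.exp(-dt / tau_r)
                t_cur = t_next
                break
            dt = -np.log(np.random.random()) / bound
            if t_cur + dt >= t_next:
                dt = t_next - t_cur
                E_m *= np.exp(-dt / tau_m)
                E_r *= np.exp(-dt / tau_r)
                t_cur = t_next
                break
            t_cur += dt
            E_m *= np.exp(-dt / tau_m)
            E_r *= np.exp(-dt / tau_r)
            lam = rho0 + (E_m - E_r) * inv_cm
            if lam > 0.0 and np.random.random() * bound <= lam:
                # postsynaptic spike
                if n_out >= cap:
                    return -1
                out_spikes[n_out] = t_cur
                n_out += 1
                if plastic:
                    y = y * np.exp(-(t_cur - ty) / tau_d) + a_minus
                    ty = t_cur
                    for i in range(n_syn):
                        xi = x_pre[i] * np.exp(-(t_cur - tx_last[i]) / tau_p)
                        x_pre[i] = xi
                        tx_last[i] = t_cur
                        wi = w[i] + eta * (
                            w_out + _f_plus(w[i], w_max, mode, mu) * xi
                        )
                        if mode == ADDITIVE:
                            if wi < 0.0:
                                wi = 0.0
                            elif wi > w_max:
                                wi = w_max
                        w[i] = wi
        if k == n_ev:
            break
        # --- presynaptic event -------------------------------------------
        i = ev_syns[k]
        if plastic:
            yv = y * np.exp(-(t_cur - ty) / tau_d)
            wi = w[i] + eta * (
                w_in - _f_minus(w[i], w_max, mode, mu, alpha) * yv
            )
            if mode == ADDITIVE:
                if wi < 0.0:
                    wi = 0.0
                elif wi > w_max:
                    wi = w_max
            w[i] = wi
            x_pre[i] = x_pre[i] * np.exp(-(t_cur - tx_last[i]) / tau_p) + a_plus
            tx_last[i] = t_cur
        E_m += w[i]
        E_r += w[i]

    epsp_state[0] = E_m
    epsp_state[1] = E_r
    epsp_state[2] = t_cur
    y_state[0] = y
    y_state[1] = ty
    return n_out


@njit(cache=True)
def lumped_trace(
    ev_times, ev_syns, weights, rho0, tau_m, tau_r, t_start, dt, n_steps
):
    """Unrectified lumped-EPSP drive sampled on a uniform grid (per ms)."""
    out = np.empty(n_steps)
    E_m = 0.0
    E_r = 0.0
    inv_cm = 1.0 / (tau_m - tau_r)
    k = 0
    n_ev = ev_times.shape[0]
    while k < n_ev and ev_times[k] < t_start:
        # warm-up: fold in earlier spikes exactly
        d = t_start - ev_times[k]
        wgt = weights[ev_syns[k]]
        E_m += wgt * np.exp(-d / tau_m)
        E_r += wgt * np.exp(-d / tau_r)
        k += 1
    for s in range(n_steps):
        t_grid = t_start + s * dt
        while k < n_ev and ev_times[k] <= t_grid:
            d = t_grid - ev_times[k]
            wgt = weights[ev_syns[k]]
            E_m += wgt * np.exp(-d / tau_m)
            E_r += wgt * np.exp(-d / tau_r)
            k += 1
        out[s] = rho0 + (E_m - E_r) * inv_cm
        # decay state to the next grid point
        E_m *= np.exp(-dt / tau_m)
        E_r *= np.exp(-dt / tau_r)
    return out


@njit(cache=True)
def lif_run(
    ev_times,
    ev_syns,
    weights,
    rho0,
    tau_m,
    tau_r,
    theta,
    refractory,
    t_end,
    dt,
    out_spikes,
):
    """Grid-stepped integrate-and-fire on the lumped-EPSP free potential.

    The free potential equals the Poisson neuron's unrectified drive; a
    threshold crossing emits a spike, clears the synaptic state (reset to the
    rho0 baseline) and enforces an absolute refractory period.
    """
    E_m = 0.0
    E_r = 0.0
    inv_cm = 1.0 / (tau_m - tau_r)
    k = 0
    n_ev = ev_times.shape[0]
    n_out = 0
    cap = out_spikes.shape[0]
    t_allow = -1e30
    n_steps = int(t_end / dt)
    for s in range(n_steps):
        t_grid = (s + 1) * dt
        while k < n_ev and ev_times[k] <= t_grid:
            d = t_grid - ev_times[k]
            wgt = weights[ev_syns[k]]
            E_m += wgt * np.exp(-d / tau_m)
            E_r += wgt * np.exp(-d / tau_r)
            k += 1
        v = rho0 + (E_m - E_r) * inv_cm
        if v >= theta and t_grid >= t_allow:
            if n_out >= cap:
                return -1
            out_spikes[n_out] = t_grid
            n_out += 1
            E_m = 0.0
            E_r = 0.0
            t_allow = t_grid + refractory
        E_m *= np.exp(-dt / tau_m)
        E_r *= np.exp(-dt / tau_r)
    return n_out


@njit(cache=True)
def run_closed_loop_lif(
    ev_times,
    ev_syns,
    t_start,
    t_end,
    rho0,
    tau_m,
    tau_r,
    theta,
    refractory,
    dt,
    eta,
    a_plus,
    a_minus,
    tau_p,
    tau_d,
    w_in,
    w_out,
    w_max,
    mode,
    mu,
    alpha,
    w,
    x_pre,
    tx_last,
    y_state,
    out_spikes,
):
    """Grid-stepped LIF driven by plastic synapses (STDP as in run_closed_loop).

    Plasticity traces persist across chunks; the membrane state restarts at
    each chunk boundary, a transient of order tau_m that is negligible for
    chunks much longer than tau_m.
    """
    E_m = 0.0
    E_r = 0.0
    inv_cm = 1.0 / (tau_m - tau_r)
    k = 0
    n_ev = ev_times.shape[0]
    n_syn = w.shape[0]
    n_out = 0
    cap = out_spikes.shape[0]
    y = y_state[0]
    ty = y_state[1]
    t_allow = -1.0e30
    n_steps = int((t_end - t_start) / dt)
    for s in range(n_steps):
        t_grid = t_start + (s + 1) * dt
        while k < n_ev and ev_times[k] <= t_grid:
            i = ev_syns[k]
            if eta > 0.0:
                t_ev = ev_times[k]
                yv = y * np.exp(-(t_ev - ty) / tau_d)
                wi = w[i] + eta * (w_in - _f_minus(w[i], w_max, mode, mu, alpha) * yv)
                if mode == ADDITIVE:
                    if wi < 0.0:
                        wi = 0.0
                    elif wi > w_max:
                        wi = w_max
                w[i] = wi
                x_pre[i] = x_pre[i] * np.exp(-(t_ev - tx_last[i]) / tau_p) + a_plus
                tx_last[i] = t_ev
            d = t_grid - ev_times[k]
            E_m += w[i] * np.exp(-d / tau_m)
            E_r += w[i] * np.exp(-d / tau_r)
            k += 1
        v = rho0 + (E_m - E_r) * inv_cm
        if v >= theta and t_grid >= t_allow:
            if n_out >= cap:
                return -1
            out_spikes[n_out] = t_grid
            n_out += 1
            E_m = 0.0
            E_r = 0.0
            t_allow = t_grid + refractory
            if eta > 0.0:
                y = y * np.exp(-(t_grid - ty) / tau_d) + a_minus
                ty = t_grid
                for i in range(n_syn):
                    xi = x_pre[i] * np.exp(-(t_grid - tx_last[i]) / tau_p)
                    x_pre[i] = xi
                    tx_last[i] = t_grid
                    wi = w[i] + eta * (w_out + _f_plus(w[i], w_max, mode, mu) * xi)
                    if mode == ADDITIVE:
                        if wi < 0.0:
                            wi = 0.0
                        elif wi > w_max:
                            wi = w_max
                    w[i] = wi
        E_m *= np.exp(-dt / tau_m)
        E_r *= np.exp(-dt / tau_r)
    y_state[0] = y
    y_state[1] = ty
    return n_out
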