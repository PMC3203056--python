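"""Analytic weight-drift theory: effective kernel, drift matrix, spectrum.

Averaged over a period long against spikes but short against learning, the
expected weight drift is linear in the weights,

    dw_i/dt = eta * ( k_i + sum_j A_ij w_j ),       (internal time unit: ms)

with

    k_i  = r_i w_in + (w_out + Wtot r_i) rho0,
    A_ij = (w_out + Wtot r_i) r_j + e_ij + delta_ij r_i Phi_0(0),

where ``Wtot`` is the learning-window integral and the correlation
coefficients absorb the pattern structure through the effective kernel
``Phi_sigma`` — the learning window smoothed by the EPSP kernel and by the
pattern's temporal width:

    Phi_sigma = (W * eps) * g_sigma,
    e_ij = nu p^2 sum_{m,n} a_i^m a_j^n Phi_st(lam_i^m - lam_j^n),
    st = sqrt(sigma_i^2 + sigma_j^2).

Negative arguments of ``Phi`` (input i earlier than j) contribute
potentiation, which is why early-latency afferents tend to win the
competition.  The rank-one rate part carries a single large negative
eigenvalue (the homeostatic equilibrium of the mean weight); eigenvalues of
the correlation part with positive real part drive the weight
specialization, and their principal eigenvectors predict which synapses end
up potentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg
import scipy.signal

from .neurons import NeuronParams, epsp_kernel
from .patterns import BIMODAL_MODELS, PatternSpec, resolve_bimodal
from .plasticity import STDPParams, window_W

__all__ = [
    "PhiKernel",
    "kernel_phi",
    "correlation_coefficients",
    "coefficients_from_correlogram",
    "TheoryModel",
    "build_drift_matrix",
    "HomeostaticEquilibrium",
    "homeostatic_equilibrium",
    "integrate_drift_ode",
    "spectral_predict",
    "prediction_agreement",
]


class PhiKernel:
    """Effective learning kernel Phi_sigma on a fine lag grid.

    Computed by grid convolution (step ``du``) of the learning window with
    the EPSP kernel and, for sigma > 0, with the unit Gaussian of the
    pattern's temporal width; evaluated elsewhere by linear interpolation.
    The grid convolution is validated against direct quadrature in the test
    suite; the integral identity  int Phi_sigma = int W  holds for every
    sigma (convolution with unit-area kernels preserves the integral).
    """

    def __init__(
        self,
        stdp: STDPParams,
        neuron: NeuronParams,
        width: float = 0.0,
        du: float = 0.02,
        span: float = 400.0,
    ) -> None:
        if width < 0:
            raise ValueError("width must be >= 0")
        self.width = float(width)
        self.du = du
        grid = np.arange(-span, span + du / 2, du)
        w_vals = window_W(grid, stdp)
        # midpoint convention at the window's jump keeps the grid quadrature
        # of the discontinuity unbiased
        j0 = int(np.argmin(np.abs(grid)))
        if abs(grid[j0]) < du / 2:
            w_vals[j0] = 0.5 * (stdp.ltp_amp - stdp.ltd_amp)
        eps_vals = epsp_kernel(grid, neuron)
        phi = scipy.signal.fftconvolve(w_vals, eps_vals, mode="same") * du
        if width > 0:
            g = np.exp(-0.5 * (grid / width) ** 2) / (width * np.sqrt(2 * np.pi))
            phi = scipy.signal.fftconvolve(phi, g, mode="same") * du
        self.grid = grid
        self.values = phi

    def __call__(self, lag) -> np.ndarray:
        return np.interp(np.asarray(lag, dtype=float), self.grid, self.values)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))

    @property
    def at_zero(self) -> float:
        return float(self(0.0))


def kernel_phi(
    lag,
    width: float,
    stdp: STDPParams,
    neuron: NeuronParams,
) -> np.ndarray:
    """Evaluate Phi_sigma(lag) (weight units; lag in ms)."""
    return PhiKernel(stdp, neuron, width)(lag)


def correlation_coefficients(
    spec: PatternSpec,
    stdp: STDPParams,
    neuron: NeuronParams,
    phi_cache: dict | None = None,
) -> np.ndarray:
    """Pattern-correlation coefficients e_ij (per ms), N x N.

    Row i collects the drift that input j's correlated firing exerts on
    weight i; entries vanish for non-pattern afferents.  The diagonal keeps
    the cross-latency (m != n) terms; for rate-modulated patterns it also
    includes the m = n term (the intensity's own covariance), which spike
    patterns do not have (a spike cannot pair with itself).
    """
    if spec.model_kind in BIMODAL_MODELS:
        raise ValueError("resolve the bimodal spec first (resolve_bimodal)")
    if spec.latencies is None:
        raise ValueError("spec.latencies required")
    N, M = spec.n_total, spec.n_pattern
    e = np.zeros((N, N))
    lat_sizes = [l.size for l in spec.latencies]
    if sum(lat_sizes) == 0:
        return e
    nu_ms = spec.presentation_rate / 1000.0
    p2 = spec.occurrence_prob**2
    lat = np.concatenate(spec.latencies)
    owner = np.repeat(np.arange(M), lat_sizes)
    sig = np.asarray(spec.jitter_width, dtype=float)
    amp = np.asarray(spec.amplitude, dtype=float)
    sig_o = sig[owner] if sig.ndim else np.full(owner.size, float(sig))
    amp_o = amp[owner] if amp.ndim else np.full(owner.size, float(amp))
    rate_model = spec.model_kind == "R"

    phi_cache = {} if phi_cache is None else phi_cache

    def phi_for(width: float) -> PhiKernel:
        key = round(float(width), 9)
        if key not in phi_cache:
            phi_cache[key] = PhiKernel(stdp, neuron, width)
        return phi_cache[key]

    widths = np.hypot(sig_o[:, None], sig_o[None, :])
    diffs = lat[:, None] - lat[None, :]
    pair_amp = amp_o[:, None] * amp_o[None, :]
    vals = np.zeros_like(diffs)
    for wv in np.unique(np.round(widths, 9)):
        mask = np.round(widths, 9) == wv
        vals[mask] = phi_for(wv)(diffs[mask])
    contrib = nu_ms * p2 * pair_amp * vals
    if not rate_model:
        np.fill_diagonal(contrib, 0.0)  # same-latency term: no self-pairs
    np.add.at(e, (owner[:, None], owner[None, :]), contrib)
    return e


def coefficients_from_correlogram(
    corr_lags: np.ndarray,
    corr_values_hz: np.ndarray,
    stdp: STDPParams,
    neuron: NeuronParams,
) -> float:
    """Numerically integrate an (empirical) correlogram against Phi_0.

    ``e_ij = int C_ji(v) Phi_0(v) dv``: the correlogram must be given in the
    j -> i orientation (lags of train i relative to train j).  Values in
    Hz/ms are converted to the internal per-ms density.
    """
    phi = PhiKernel(stdp, neuron, 0.0)
    c_ms = np.asarray(corr_values_hz, dtype=float) / 1000.0
    lags = np.asarray(corr_lags, dtype=float)
    return float(np.trapezoid(c_ms * phi(lags), lags))


class HomeostaticEquilibrium(NamedTuple):
    w_eq: float
    nu_out_eq: float  # Hz
    stable: bool
    realizable: bool


def homeostatic_equilibrium(
    stdp: STDPParams,
    neuron: NeuronParams,
    spec: PatternSpec,
) -> HomeostaticEquilibrium:
    """Correlation-free fixed point of the mean weight and output rate.

    With uniform input rates ``r`` the averaged drift of the mean weight
    vanishes at

        nu_out* = -w_in r / (w_out + Wtot r),
        w_eq    = (nu_out* - rho0) / (N r),

    stable iff ``w_out + Wtot r < 0`` (each output spike then pushes the
    rate back); realizable iff 0 < w_eq < w_max.
    """
    r = spec.background_rate / 1000.0
    w_in, w_out = stdp.effective_rate_terms()
    denom = w_out + stdp.window_integral * r
    stable = denom < 0
    if denom == 0:
        return HomeostaticEquilibrium(np.nan, np.nan, False, False)
    nu_out = -w_in * r / denom
    w_eq = (nu_out - neuron.rho0_ms) / (spec.n_total * r)
    realizable = stable and nu_out > 0 and 0 < w_eq < stdp.w_max
    return HomeostaticEquilibrium(float(w_eq), float(nu_out * 1000.0), stable, realizable)


@dataclass
class TheoryModel:
    """Drift-matrix model of the expected weight dynamics."""

    spec: PatternSpec
    stdp: STDPParams
    neuron: NeuronParams
    rates: np.ndarray  # Hz
    corr: np.ndarray  # e_ij, per ms
    drift_matrix: np.ndarray  # A, per ms
    drift_const: np.ndarray  # k, per ms
    w_eq: float
    nu_out_eq: float  # Hz
    eigenvalues: np.ndarray = field(default=None)
    right_vectors: np.ndarray = field(default=None)
    left_vectors: np.ndarray = field(default=None)

    def eig(self) -> None:
        if self.eigenvalues is None:
            vals, vl, vr = scipy.linalg.eig(self.drift_matrix, left=True, right=True)
            self.eigenvalues, self.left_vectors, self.right_vectors = vals, vl, vr

    @property
    def homeostatic_eigenvalue(self) -> complex:
        self.eig()
        return self.eigenvalues[int(np.argmin(self.eigenvalues.real))]


def build_drift_matrix(
    spec: PatternSpec,
    stdp: STDPParams,
    neuron: NeuronParams,
    corr: np.ndarray | None = None,
    include_self_term: bool = True,
) -> TheoryModel:
    """Assemble the full drift matrix A and constant k from the pattern.

    Combines the rank-one homeostatic rate structure with the correlation
    coefficients and the Poisson self-term (an input spike transiently
    raises the output rate, adding ``r_i Phi_0(0)`` on the diagonal — a
    uniform shift that moves the whole spectrum but no eigenvector).
    """
    if spec.model_kind in BIMODAL_MODELS:
        raise ValueError("resolve the bimodal spec first (resolve_bimodal)")
    N = spec.n_total
    r = np.full(N, spec.background_rate / 1000.0)
    if corr is None:
        corr = correlation_coefficients(spec, stdp, neuron)
    w_in, w_out = stdp.effective_rate_terms()
    wtot = stdp.window_integral
    phi0 = PhiKernel(stdp, neuron, 0.0).at_zero if include_self_term else 0.0
    A = np.outer(w_out + wtot * r, r) + corr + np.diag(r * phi0)
    k = r * w_in + (w_out + wtot * r) * neuron.rho0_ms
    eq = homeostatic_equilibrium(stdp, neuron, spec)
    return TheoryModel(
        spec=spec, stdp=stdp, neuron=neuron, rates=r * 1000.0, corr=corr,
        drift_matrix=A, drift_const=k, w_eq=eq.w_eq, nu_out_eq=eq.nu_out_eq,
    )


def integrate_drift_ode(
    model: TheoryModel,
    w0: np.ndarray,
    duration_s: float,
    eta: float | None = None,
    n_record: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dw/dt = eta (k + A w) with clipping to [0, w_max].

    Explicit Euler with the step chosen from the stiffest (homeostatic)
    eigenvalue; the hard clip mirrors the additive rule's bounds.  Returns
    (times_s, trajectory) with ``n_record`` snapshots.
    """
    eta = model.stdp.learning_rate if eta is None else eta
    A, k = model.drift_matrix, model.drift_const
    w = np.asarray(w0, dtype=float).copy()
    wmax = model.stdp.w_max
    if np.any(w < 0) or np.any(w > wmax):
        raise ValueError("w0 outside bounds")
    T = duration_s * 1000.0
    lam_fast = float(np.max(np.abs(np.linalg.eigvals(A).real))) * eta
    dt = min(0.1 / max(lam_fast, 1e-12), T / 10.0)
    n_steps = max(int(np.ceil(T / dt)), 1)
    dt = T / n_steps
    rec_every = max(n_steps // n_record, 1)
    times = [0.0]
    traj = [w.copy()]
    for s in range(n_steps):
        w += eta * dt * (k + A @ w)
        np.clip(w, 0.0, wmax, out=w)
        if (s + 1) % rec_every == 0 or s == n_steps - 1:
            times.append((s + 1) * dt / 1000.0)
            traj.append(w.copy())
    return np.asarray(times), np.asarray(traj)


def spectral_predict(
    model: TheoryModel,
    n_target: int | None = None,
    matrix: str = "correlation",
) -> tuple[np.ndarray, dict]:
    """Predict the potentiated set from the unstable modes of the drift.

    ``matrix='correlation'`` uses the e_ij coefficients alone (rate effects
    neglected); ``matrix='full'`` uses the whole drift matrix A.  When the
    dominant positive-real-part eigenvalue is real, afferents are ranked by
    their component in its eigenvector (oriented by the projection of the
    uniform initial condition).  The dominant mode is typically a complex
    conjugate pair, whose growing solution rotates: the phase at which it
    saturates is fixed by the weight bounds, not by the linear theory.  The
    ranking then comes from the bound-constrained drift flow
    ``w <- clip(w + dt (M w - mean(M w)), 0, w_max)`` started from the
    homogeneous state (the mean subtraction expresses the homeostatic
    sum constraint), iterated until ``n_target`` weights saturate — the
    nonlinear analogue of the principal-eigenvector projection.  Ties break
    toward earlier mean latency.  If no eigenvalue has positive real part,
    no specialization is expected and the prediction is empty.
    """
    spec = model.spec
    if n_target is None:
        n_target = int(round(spec.n_total * model.w_eq / model.stdp.w_max))
    mat = model.corr if matrix == "correlation" else model.drift_matrix
    vals = scipy.linalg.eigvals(mat)
    pos = vals.real > 1e-15
    info = {"eigenvalues": vals, "n_target": n_target}
    if not np.any(pos):
        info["no_specialization"] = True
        return np.empty(0, dtype=int), info
    dom = int(np.argmax(np.where(pos, vals.real, -np.inf)))
    lam = vals[dom]
    info["dominant_eigenvalue"] = lam
    wmax = model.stdp.w_max
    n = mat.shape[0]
    if abs(lam.imag) < 1e-12 * max(abs(lam.real), 1.0):
        _, vl, vr = scipy.linalg.eig(mat, left=True, right=True)
        v = vr[:, dom]
        c = np.vdot(vl[:, dom], np.ones(n))
        score = (np.conj(c if abs(c) > 1e-12 else 1.0) * v).real
        if score.sum() < 0:
            score = -score
    else:
        w = np.full(n, min(model.w_eq, 0.5 * wmax))
        dt = 0.1 / lam.real
        for _ in range(5000):
            dw = mat @ w
            dw -= dw.mean()
            w = np.clip(w + dt * dw, 0.0, wmax)
            if int((w > 0.9 * wmax).sum()) >= n_target:
                break
        score = w
    mean_lat = np.full(spec.n_total, spec.pattern_duration)
    for i in range(spec.n_pattern):
        if spec.latencies[i].size:
            mean_lat[i] = float(np.mean(spec.latencies[i]))
    order = np.lexsort((mean_lat, -score))
    predicted = np.sort(order[:n_target])
    info["score"] = score
    return predicted, info


def prediction_agreement(predicted: Sequence[int], simulated: Sequence[int]) -> float:
    """|predicted intersect simulated| / |simulated|."""
    sim = set(int(i) for i in simulated)
    if not sim:
        raise ValueError("empty simulated set")
    pred = set(int(i) for i in predicted)
    return len(pred & sim) / len(sim)


def export_matrix(mat: np.ndarray, path) -> None:
    np.savetxt(path, mat, delimiter="\t")


def export_spectrum(vals: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("real\timag\n")
        for v in np.asarray(vals, dtype=complex):
            fh.write(f"{v.real:.8e}\t{v.imag:.8e}\n")
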