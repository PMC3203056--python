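"""Experiment configuration, validation and preset protocols.

A single :class:`ExperimentConfig` serializes every pattern, neuron and STDP
parameter to YAML; a run is reproducible from the config plus one global
seed, which fans out into independent per-component streams.  The presets
mirror the standard protocols: correlogram comparison, baseline training,
bimodal group competition, theory-vs-simulation comparison, jitter sweeps,
the enveloped long pattern, and robustness sweeps.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .correlograms import empirical_correlogram, predicted_correlogram, write_correlogram
from .detection import build_detection_table, mutual_information, write_detection_report
from .neurons import NeuronParams
from .patterns import (
    EnvelopeSpec,
    GroupSpec,
    PatternSpec,
    gen_envelope_pattern,
    generate,
    make_schedule,
    write_schedule,
    write_spikes,
)
from .plasticity import (
    STDPParams,
    classify_weights,
    run_learning,
    write_convergence_log,
    write_snapshots,
)
from .theory import (
    build_drift_matrix,
    export_matrix,
    export_spectrum,
    homeostatic_equilibrium,
    prediction_agreement,
    spectral_predict,
)

__all__ = [
    "ExperimentConfig",
    "baseline_config",
    "validate_config",
    "run_experiment",
    "PRESETS",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run (plus a seed)."""

    # pattern
    model_kind: str = "R"
    n_total: int = 1000
    n_pattern: int = 500
    pattern_duration: float = 50.0
    presentation_rate: float = 1.5
    background_rate: float = 20.0
    occurrence_prob: float = 1.0
    jitter_width: float = 1.0
    amplitude: float = 1.0
    group_sizes: tuple[int, int] | None = None
    group_latencies: tuple[float, float] | None = None
    group_widths: tuple[float, float] | None = None
    envelope_peak_width: float = 20.0
    envelope_center_rate: float = 20.0
    # neuron
    base_drive: float = -2050.0
    epsp_decay: float = 10.0
    epsp_rise: float = 1.0
    lif_threshold: float | None = None
    lif_refractory: float = 1.0
    # stdp
    learning_rate: float = 2.5e-3
    ltp_amp: float = 1.0
    ltd_amp: float = 0.61
    ltp_tau: float = 16.8
    ltd_tau: float = 33.7
    rate_in: float = 0.055
    rate_out: float = -0.2
    w_max: float = 1.0
    stdp_mode: str = "additive"
    wd_exponent: float = 0.05
    wd_asymmetry: float = 1.0
    w_init_max: float = 0.25
    # protocol
    duration_s: float = 2000.0
    snapshot_every_s: float = 50.0

    # -- conversions -------------------------------------------------------
    def pattern_spec(self) -> PatternSpec:
        groups = None
        if self.group_sizes is not None:
            groups = (
                GroupSpec(self.group_sizes[0], self.group_latencies[0], self.group_widths[0]),
                GroupSpec(self.group_sizes[1], self.group_latencies[1], self.group_widths[1]),
            )
        return PatternSpec(
            model_kind=self.model_kind,
            n_total=self.n_total,
            n_pattern=self.n_pattern,
            pattern_duration=self.pattern_duration,
            presentation_rate=self.presentation_rate,
            background_rate=self.background_rate,
            occurrence_prob=self.occurrence_prob,
            jitter_width=self.jitter_width,
            amplitude=self.amplitude,
            group_spec=groups,
            envelope_spec=EnvelopeSpec(self.envelope_peak_width, self.envelope_center_rate)
            if self.model_kind == "R_envelope"
            else None,
        )

    def neuron_params(self) -> NeuronParams:
        return NeuronParams(
            base_drive=self.base_drive,
            epsp_decay=self.epsp_decay,
            epsp_rise=self.epsp_rise,
            lif_threshold=self.lif_threshold,
            lif_refractory=self.lif_refractory,
        )

    def stdp_params(self) -> STDPParams:
        return STDPParams(
            learning_rate=self.learning_rate,
            ltp_amp=self.ltp_amp,
            ltd_amp=self.ltd_amp,
            ltp_tau=self.ltp_tau,
            ltd_tau=self.ltd_tau,
            rate_in=self.rate_in,
            rate_out=self.rate_out,
            w_max=self.w_max,
            mode=self.stdp_mode,
            wd_exponent=self.wd_exponent,
            wd_asymmetry=self.wd_asymmetry,
        )

    # -- persistence -------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("group_sizes", "group_latencies", "group_widths"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def baseline_config(
    n_total: int = 1000,
    n_pattern: int | None = None,
    model_kind: str = "R",
    w_eq_target: float = 0.078,
    **overrides,
) -> ExperimentConfig:
    """Baseline configuration with the inhibitory drive set homeostatically.

    At the reference size N = 1000 this is the stock configuration (the
    dataclass defaults).  For other sizes ``rho0`` is recalibrated so the
    operating point is preserved: the neuron runs deeply subthreshold, and
    with ``n = w_eq_target * N`` winners at ``w_max`` the lumped drive is
    approximately Gaussian with std ``s = sqrt(n r0 w_max^2 int eps^2)``;
    the mean drive ``mu*`` solving ``E[(mu + s Z)_+] = nu_out*`` fixes
    ``rho0 = mu* - n w_max r0`` (homeostasis scales weights with 1/N).
    """
    cfg = ExperimentConfig(
        model_kind=model_kind,
        n_total=n_total,
        n_pattern=n_pattern if n_pattern is not None else n_total // 2,
        **overrides,
    )
    if "base_drive" not in overrides and n_total != 1000:
        stdp = cfg.stdp_params()
        neuron = cfg.neuron_params()
        r = cfg.background_rate / 1000.0
        denom = stdp.rate_out + stdp.window_integral * r
        nu_out = -stdp.rate_in * r / denom if denom < 0 else 0.0
        n_win = w_eq_target * cfg.n_total
        s = np.sqrt(n_win * r * stdp.w_max**2 * neuron.epsp_sq_integral)
        mu_star = _gaussian_mean_drive(nu_out, s)
        rho0_ms = mu_star - n_win * stdp.w_max * r
        cfg = replace(cfg, base_drive=rho0_ms * 1000.0)
    return cfg


def _gaussian_mean_drive(target_rate: float, s: float) -> float:
    """Mean mu with E[(mu + s Z)_+] = target_rate for standard normal Z."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    if s <= 0 or target_rate <= 0:
        return target_rate

    def f(mu):
        z = mu / s
        return mu * norm.cdf(z) + s * norm.pdf(z) - target_rate

    return float(brentq(f, -30 * s, max(target_rate, s) * 30))


def validate_config(config: ExperimentConfig) -> dict:
    """Machine-readable invariant checks (report-only; never raises)."""
    checks: dict[str, bool] = {}
    notes: dict[str, str] = {}
    nu_delta = config.presentation_rate * config.pattern_duration / 1000.0
    checks["low_frequency_regime"] = nu_delta < 1.0
    checks["pattern_subset"] = 0 < config.n_pattern <= config.n_total
    checks["occurrence_prob_range"] = 0.0 <= config.occurrence_prob <= 1.0
    checks["jitter_nonnegative"] = config.jitter_width >= 0
    checks["epsp_time_constants"] = config.epsp_decay > config.epsp_rise > 0
    checks["window_time_constants"] = config.ltp_tau > 0 and config.ltd_tau > 0
    checks["weights_bounded"] = 0 < config.w_init_max < config.w_max
    try:
        eq = homeostatic_equilibrium(
            config.stdp_params(), config.neuron_params(), config.pattern_spec()
        )
        checks["equilibrium_stable"] = bool(eq.stable)
        checks["equilibrium_realizable"] = bool(eq.realizable)
        notes["w_eq"] = f"{eq.w_eq:.4f}"
        notes["nu_out_eq_hz"] = f"{eq.nu_out_eq:.3f}"
        # slow learning: mean drift per presentation well below w_max
        per_pres = (
            config.learning_rate
            * abs(config.rate_in + config.rate_out)
            * config.background_rate
            / 1000.0
            * config.pattern_duration
        )
        checks["slow_learning"] = per_pres < 0.01 * config.w_max
    except (ValueError, ZeroDivisionError) as exc:  # invalid spec
        checks["equilibrium_stable"] = False
        checks["equilibrium_realizable"] = False
        checks["slow_learning"] = False
        notes["error"] = str(exc)
    return {"checks": checks, "notes": notes, "passed": all(checks.values())}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _outpath(outdir, name, cfg):
    os.makedirs(outdir, exist_ok=True)
    return os.path.join(outdir, name)


def _train(cfg: ExperimentConfig, seed: int, duration_s: float | None = None):
    spec = cfg.pattern_spec()
    return run_learning(
        spec,
        cfg.neuron_params(),
        cfg.stdp_params(),
        duration_s if duration_s is not None else cfg.duration_s,
        seed,
        snapshot_every_s=cfg.snapshot_every_s,
        w_init_max=cfg.w_init_max,
    )


def _preset_correlograms(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    s1, s2, s3 = _seeds(seed, 3)
    spec = cfg.pattern_spec().with_random_latencies(s1)
    T = min(cfg.duration_s, 1000.0) * 1000.0
    sched = make_schedule(T, spec.presentation_rate, spec.pattern_duration, s2)
    ts = generate(spec, sched, s3)
    pair = _first_populated_pair(spec)
    sig = float(np.hypot(spec.sigma_of(pair[0]), spec.sigma_of(pair[1])))
    bin_width = 1.0 if sig == 0 else min(1.0, max(sig / 2.0, 0.1))
    emp = empirical_correlogram(
        ts.trains[pair[0]], ts.trains[pair[1]], bin_width=bin_width,
        duration=T, pair=pair,
    )
    pred = predicted_correlogram(spec, pair, bin_width=bin_width)
    write_correlogram(emp, _outpath(outdir, "correlogram_empirical.tsv", cfg))
    write_correlogram(pred, _outpath(outdir, "correlogram_predicted.tsv", cfg))
    err = float(np.max(np.abs(emp.values - pred.values)))
    return {"pair": list(pair), "max_abs_error_hz": err}


def _first_populated_pair(spec) -> tuple[int, int]:
    idx = [i for i in range(spec.n_pattern) if spec.latencies[i].size]
    return (idx[0], idx[1]) if len(idx) >= 2 else (0, 1)


def _preset_train_baseline(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    res = _train(cfg, seed)
    write_snapshots(res, _outpath(outdir, "weight_snapshots.tsv", cfg))
    write_convergence_log(res, _outpath(outdir, "convergence.tsv", cfg))
    write_schedule(res.schedule, _outpath(outdir, "schedule.tsv", cfg))
    pot, dep = classify_weights(res.weights, w_max=cfg.w_max)
    table = build_detection_table(res.output.spikes, res.schedule)
    write_detection_report(
        table, cfg.presentation_rate, _outpath(outdir, "detection.tsv", cfg)
    )
    return {
        "n_potentiated": int(pot.size),
        "n_depressed": int(dep.size),
        "mean_weight": float(res.weights.mean()),
        "mutual_information_bits": mutual_information(table),
    }


def _preset_bimodal(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    if cfg.group_sizes is None:
        m = cfg.n_pattern // 2
        cfg = replace(
            cfg,
            model_kind="SB" if cfg.model_kind in ("S", "SB") else "RB",
            group_sizes=(m, m),
            group_latencies=(10.0, 25.0),
            group_widths=(2.0, 2.0),
        )
    res = _train(cfg, seed)
    pot, _ = classify_weights(res.weights, w_max=cfg.w_max)
    g1 = int(np.sum(pot < cfg.group_sizes[0]))
    g2 = int(np.sum((pot >= cfg.group_sizes[0]) & (pot < sum(cfg.group_sizes))))
    write_snapshots(res, _outpath(outdir, "weight_snapshots.tsv", cfg))
    return {"n_potentiated": int(pot.size), "early_group": g1, "late_group": g2}


def _preset_theory_compare(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    res = _train(cfg, seed)
    model = build_drift_matrix(res.spec, cfg.stdp_params(), cfg.neuron_params())
    pot, _ = classify_weights(res.weights, w_max=cfg.w_max)
    pred, info = spectral_predict(model)
    agree = prediction_agreement(pred, pot) if pot.size else float("nan")
    export_matrix(model.corr, _outpath(outdir, "correlation_matrix.tsv", cfg))
    model.eig()
    export_spectrum(model.eigenvalues, _outpath(outdir, "spectrum.tsv", cfg))
    with open(_outpath(outdir, "agreement.tsv", cfg), "w") as fh:
        fh.write("agreement_fraction\n")
        fh.write(f"{agree:.6f}\n")
    return {"agreement": agree, "n_predicted": int(pred.size), "n_potentiated": int(pot.size)}


def _preset_jitter_sweep(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    sigmas = (0.0, 5.0, 10.0, 20.0)
    rows = []
    for k, sig in enumerate(sigmas):
        c = replace(cfg, jitter_width=sig)
        res = _train(c, seed + k)
        table = build_detection_table(res.output.spikes, res.schedule)
        rows.append((sig, mutual_information(table)))
    with open(_outpath(outdir, "jitter_sweep.tsv", cfg), "w") as fh:
        fh.write("sigma_ms\tmutual_information_bits\n")
        for sig, mi in rows:
            fh.write(f"{sig:.1f}\t{mi:.6f}\n")
    return {"sigma_ms": [r[0] for r in rows], "mi_bits": [r[1] for r in rows]}


def _preset_envelope(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    s1, s2, s3 = _seeds(seed, 3)
    cfg = replace(cfg, model_kind="R_envelope", pattern_duration=100.0)
    spec = cfg.pattern_spec().with_random_latencies(s1)
    T = min(cfg.duration_s, 200.0) * 1000.0
    sched = make_schedule(T, spec.presentation_rate, spec.pattern_duration, s2)
    ts, rates = gen_envelope_pattern(spec, sched, s3)
    write_spikes(ts, _outpath(outdir, "spikes.tsv", cfg))
    return {"n_spikes": int(sum(t.size for t in ts.trains)), "duration_s": T / 1000.0}


def _preset_robustness_sweep(cfg: ExperimentConfig, seed: int, outdir: str) -> dict:
    rows = []
    for k, drive in enumerate((cfg.base_drive, 0.0)):
        c = replace(cfg, base_drive=drive)
        res = _train(c, seed + k)
        table = build_detection_table(res.output.spikes, res.schedule)
        rows.append((drive, mutual_information(table)))
    with open(_outpath(outdir, "robustness.tsv", cfg), "w") as fh:
        fh.write("base_drive_hz\tmutual_information_bits\n")
        for d, mi in rows:
            fh.write(f"{d:.1f}\t{mi:.6f}\n")
    return {"base_drive_hz": [r[0] for r in rows], "mi_bits": [r[1] for r in rows]}


PRESETS = {
    "correlograms": _preset_correlograms,
    "train_baseline": _preset_train_baseline,
    "bimodal": _preset_bimodal,
    "theory_compare": _preset_theory_compare,
    "jitter_sweep": _preset_jitter_sweep,
    "envelope": _preset_envelope,
    "robustness_sweep": _preset_robustness_sweep,
}


def run_experiment(
    preset: str,
    seed: int,
    outdir: str = "results",
    config: ExperimentConfig | None = None,
    **overrides,
) -> dict:
    """Run one preset protocol and write its artifact bundle.

    Artifacts carry the generating config (YAML, with its hash) alongside the
    preset outputs; the returned dict summarizes the headline numbers.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = config if config is not None else baseline_config()
    if overrides:
        cfg = replace(cfg, **overrides)
    os.makedirs(outdir, exist_ok=True)
    cfg.to_yaml(os.path.join(outdir, f"config_{cfg.digest()}.yaml"))
    report = validate_config(cfg)
    summary = PRESETS[preset](cfg, seed, outdir)
    summary["config_hash"] = cfg.digest()
    summary["config_valid"] = report["passed"]
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
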