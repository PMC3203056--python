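"""Pattern-detection quality via stimulus/response mutual information.

Time is discretized into bins (default 25 ms).  A bin is a stimulus bin
(S = 1) iff it contains a presentation onset, and a response bin (R = 1) iff
the postsynaptic neuron fires at least ``threshold`` spikes (default 2)
inside the — optionally backward-shifted — bin window.  The mutual
information of the resulting 2x2 joint distribution quantifies detection;
its cells are the hits, misses, false alarms and correct rejections of
signal-detection language.  A perfect detector attains the stimulus entropy
H(nu * bin), which is therefore the upper bound on the attainable
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import PresentationSchedule

__all__ = [
    "DetectionTable",
    "build_detection_table",
    "mutual_information",
    "mi_upper_bound",
    "write_detection_report",
]


@dataclass
class DetectionTable:
    """Joint (stimulus, response) counts over all time bins."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    bin_width: float = 25.0
    threshold: int = 2
    lif_shift: float = 0.0
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections

    def joint(self) -> np.ndarray:
        """P(S, R) as a 2x2 array, rows S in {1, 0}, cols R in {1, 0}."""
        n = self.n_bins
        return np.array(
            [
                [self.hits, self.misses],
                [self.false_alarms, self.correct_rejections],
            ]
        ) / max(n, 1)


def build_detection_table(
    post_spikes: np.ndarray,
    schedule: PresentationSchedule,
    bin_width: float = 25.0,
    threshold: int = 2,
    lif_shift: float = 0.0,
) -> DetectionTable:
    """Tabulate per-bin stimulus and response labels.

    The stimulus rows are the first ``bin_width`` of each presentation
    (aligned with the pattern onset, so the response is judged on the
    pattern's actual beginning); the non-stimulus rows are the bins of the
    fixed tiling of [0, total_duration) whose start does not fall inside any
    stimulus window.  Exactly one tiling bin is displaced per presentation,
    so the total row count equals floor(T/bin) and the stimulus probability
    is nu * bin.  ``lif_shift`` moves every spike-counting window backward
    (used for the LIF neuron, whose potential rise begins before the nominal
    pattern start).
    """
    spikes = np.sort(np.asarray(post_spikes, dtype=float))
    T = schedule.total_duration
    n_bins = int(T // bin_width)
    degenerate = len(schedule) == 0
    on = schedule.onsets

    def counts(starts: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(spikes, starts - lif_shift)
        hi = np.searchsorted(spikes, starts + bin_width - lif_shift)
        return hi - lo

    resp_stim = counts(on) >= threshold
    hits = int(resp_stim.sum())
    misses = int(len(on) - hits)
    # background bins are judged on background activity only: spikes falling
    # inside a stimulus counting window are not re-counted against them
    if len(on):
        k = np.searchsorted(on, spikes + lif_shift, side="right") - 1
        v = k >= 0
        in_stim = np.zeros(spikes.size, dtype=bool)
        in_stim[v] = spikes[v] + lif_shift < on[k[v]] + bin_width
        spikes_bg = spikes[~in_stim]
    else:
        spikes_bg = spikes

    def counts_bg(starts: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(spikes_bg, starts - lif_shift)
        hi = np.searchsorted(spikes_bg, starts + bin_width - lif_shift)
        return hi - lo

    starts = np.arange(n_bins) * bin_width
    # drop tiling bins whose start lies inside a stimulus window
    inside = np.zeros(n_bins, dtype=bool)
    if len(on):
        k = np.searchsorted(on, starts, side="right") - 1
        valid = k >= 0
        inside[valid] = starts[valid] < on[k[valid]] + bin_width
    noise_starts = starts[~inside]
    resp_noise = counts_bg(noise_starts) >= threshold
    fa = int(resp_noise.sum())
    cr = int(len(noise_starts) - fa)
    return DetectionTable(hits, misses, fa, cr, bin_width, threshold, lif_shift, degenerate)


def mutual_information(table: DetectionTable) -> float:
    """I(S; R) in bits over the 2x2 table, with 0 log 0 = 0."""
    p = table.joint()
    ps = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (ps * pr))
    return float(np.nansum(terms))


def mi_upper_bound(presentation_rate: float, bin_width: float = 25.0) -> float:
    """Binary entropy of the stimulus variable, H(nu * bin), in bits.

    ``presentation_rate`` in Hz, ``bin_width`` in ms; the occupancy
    probability p = nu * bin must lie in (0, 1).  A perfect detector's
    mutual information equals this stimulus entropy.
    """
    p = presentation_rate * bin_width / 1000.0
    if not (0.0 < p < 1.0):
        raise ValueError("presentation_rate * bin_width must lie in (0, 1)")
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def write_detection_report(
    table: DetectionTable, presentation_rate: float, path
) -> None:
    """Structured-text report: the four cells, I in bits, and the bound."""
    mi = mutual_information(table)
    bound = mi_upper_bound(presentation_rate, table.bin_width)
    with open(path, "w") as fh:
        fh.write(f"bin_ms\t{table.bin_width:.1f}\n")
        fh.write(f"threshold_spikes\t{table.threshold}\n")
        fh.write(f"lif_shift_ms\t{table.lif_shift:.1f}\n")
        fh.write(f"hits\t{table.hits}\n")
        fh.write(f"misses\t{table.misses}\n")
        fh.write(f"false_alarms\t{table.false_alarms}\n")
        fh.write(f"correct_rejections\t{table.correct_rejections}\n")
        fh.write(f"mutual_information_bits\t{mi:.6f}\n")
        fh.write(f"upper_bound_bits\t{bound:.6f}\n")
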