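"""Time-resolved auROC response detection and temporal metrics.

For each source-odor pair the per-bin discriminability of the evoked signal
against its pre-odor baseline is measured with the area under the ROC curve
(auROC): 0.5 means the two distributions overlap completely, 1 means every
evoked value exceeds every baseline value, 0 the reverse.  Sustained
excursions above 0.75 are called excitatory, below 0.25 inhibitory; onset
latency, peak latency and response duration are read off the auROC trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .io import ValidationError
from .preprocess import TrialMatrix

__all__ = [
    "AurocTrace",
    "ResponseCall",
    "auroc",
    "auroc_timecourse",
    "classify_response",
    "temporal_metrics",
    "detect_response",
    "summarize_response_proportions",
]

CLASSES = ("excitatory", "inhibitory", "none")


@dataclass
class AurocTrace:
    """Per-bin auROC of evoked values vs the per-trial baseline means."""

    values: np.ndarray           # one auROC per post-onset bin, in [0, 1]
    bin_width: float
    lo: float = 0.25
    hi: float = 0.75
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValidationError("auROC values must lie in [0, 1]")

    def bin_times(self) -> np.ndarray:
        """Left edges of the post-onset bins (s after odor onset)."""
        return self.bin_width * np.arange(self.values.size)


@dataclass(frozen=True)
class ResponseCall:
    """Response class plus temporal metrics (defined only for responses)."""

    response_class: str
    onset_latency: Optional[float] = None
    peak_latency: Optional[float] = None
    duration: Optional[float] = None
    scalar_auroc: Optional[float] = None


def auroc(sample_a, sample_b) -> float:
    """auROC of ``sample_b`` against ``sample_a``.

    Equals the fraction of cross pairs (a, b) with b > a, ties credited as
    half: 0.5 for identical distributions, 1.0 when every b exceeds every a.
    Computed from the Mann-Whitney rank statistic, which is exactly the
    tie-halved pair count.
    """
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("auroc requires two non-empty samples")
    ranks = rankdata(np.concatenate([a, b]))
    u_b = ranks[a.size:].sum() - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def _auroc_many(baseline: np.ndarray, evoked: np.ndarray) -> np.ndarray:
    """auROC of each evoked column against the shared baseline sample."""
    n_base = baseline.size
    n_tr, n_bins = evoked.shape
    stacked = np.concatenate([np.tile(baseline[:, None], (1, n_bins)), evoked], axis=0)
    ranks = rankdata(stacked, axis=0)
    u_b = ranks[n_base:].sum(axis=0) - n_tr * (n_tr + 1) / 2.0
    return u_b / (n_base * n_tr)


def auroc_timecourse(tm: TrialMatrix, lo: float = 0.25, hi: float = 0.75,
                     smooth: bool = False) -> AurocTrace:
    """Per-bin auROC of the post-onset bins against the baseline distribution.

    The baseline sample pools the individual baseline-bin values across
    trials, so it is measured on the same footing (one bin of one trial) as
    each post-onset sample.  With discrete data — e.g. sparse spike counts,
    where a 50-ms bin is usually zero — the shared atoms tie against each
    other and tie-halving keeps the null at 0.5 regardless of the rate; a
    continuous summary baseline (such as per-trial means) would instead bias
    low-rate pairs toward spurious sub-0.25 values.  An all-constant matrix
    yields a flat 0.5 trace.
    """
    if tm.n_trials < 2:
        raise ValidationError("auroc_timecourse needs >= 2 trials")
    if tm.n_baseline_bins < 1:
        raise ValidationError("auroc_timecourse needs a baseline window")
    pre, _ = tm.window
    i_on = int(round(pre / tm.bin_width))
    baseline = tm.values[:, : tm.n_baseline_bins].ravel()
    vals = _auroc_many(baseline, tm.values[:, i_on:])
    if smooth and vals.size >= 3:
        vals = np.convolve(vals, np.ones(3) / 3.0, mode="same")
    return AurocTrace(vals, tm.bin_width, lo=lo, hi=hi, n_trials=tm.n_trials)


def _threshold_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, stop) index pairs of runs of True at least ``min_len`` long."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def classify_response(trace: AurocTrace, min_consecutive_bins: int = 3) -> str:
    """Excitatory if >= ``min_consecutive_bins`` consecutive bins exceed the
    upper threshold, inhibitory if that many fall below the lower one; when
    both occur the earlier-onset run decides; otherwise 'none'."""
    exc = _threshold_runs(trace.values > trace.hi, min_consecutive_bins)
    inh = _threshold_runs(trace.values < trace.lo, min_consecutive_bins)
    if exc and (not inh or exc[0][0] <= inh[0][0]):
        return "excitatory"
    if inh:
        return "inhibitory"
    return "none"


def temporal_metrics(trace: AurocTrace, response_class: str,
                     min_consecutive_bins: int = 3) -> tuple[float, float, float]:
    """Onset latency, peak latency and duration from the auROC trace.

    Onset is the left edge of the first qualifying supra/sub-threshold run;
    the response ends at the left edge of the first bin after onset where the
    trace re-enters the (lo, hi) band for >= ``min_consecutive_bins`` bins
    (or at the trace end); the peak is the max (excitatory) or min
    (inhibitory) auROC bin within the response, earliest bin winning ties.
    """
    if response_class == "none":
        raise ValidationError("temporal metrics are defined only for responses")
    if response_class == "excitatory":
        out_mask = trace.values > trace.hi
    elif response_class == "inhibitory":
        out_mask = trace.values < trace.lo
    else:
        raise ValidationError(f"unknown response class {response_class!r}")
    runs = _threshold_runs(out_mask, min_consecutive_bins)
    if not runs:
        raise ValidationError("no qualifying threshold run for the stated class")
    start = runs[0][0]
    inside = (trace.values > trace.lo) & (trace.values < trace.hi)
    back_runs = _threshold_runs(inside[start:], min_consecutive_bins)
    end = start + back_runs[0][0] if back_runs else trace.values.size
    seg = trace.values[start:end]
    k = int(np.argmax(seg) if response_class == "excitatory" else np.argmin(seg))
    bw = trace.bin_width
    onset = start * bw
    peak = (start + k) * bw
    duration = (end - start) * bw
    return onset, peak, duration


def detect_response(tm: TrialMatrix, lo: float = 0.25, hi: float = 0.75,
                    min_consecutive_bins: int = 3, smooth: bool = False,
                    baseline_window: float = 2.0, evoked_window: float = 2.0) -> ResponseCall:
    """Full per-pair readout: class, latencies, duration, and the scalar
    baseline-vs-evoked (2-s window means) auROC."""
    trace = auroc_timecourse(tm, lo=lo, hi=hi, smooth=smooth)
    cls = classify_response(trace, min_consecutive_bins)
    pre, _ = tm.window
    i_on = int(round(pre / tm.bin_width))
    nb = int(round(baseline_window / tm.bin_width))
    ne = int(round(evoked_window / tm.bin_width))
    scalar = auroc(tm.values[:, i_on - nb: i_on].mean(axis=1),
                   tm.values[:, i_on: i_on + ne].mean(axis=1))
    if cls == "none":
        return ResponseCall("none", scalar_auroc=scalar)
    onset, peak, duration = temporal_metrics(trace, cls, min_consecutive_bins)
    return ResponseCall(cls, onset, peak, duration, scalar)


def summarize_response_proportions(calls: list[ResponseCall]) -> dict:
    """Counts and fractions of excitatory / inhibitory / no-response calls."""
    if not calls:
        raise ValidationError("no response calls to summarize")
    counts = {c: 0 for c in CLASSES}
    for call in calls:
        counts[call.response_class] += 1
    n = len(calls)
    return {
        "n": n,
        "counts": counts,
        "fractions": {c: counts[c] / n for c in CLASSES},
    }
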