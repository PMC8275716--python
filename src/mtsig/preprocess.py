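"""Trial segmentation, dF/F, Morlet band power, firing-rate binning, unit QC.

Every signal ends up as a :class:`TrialMatrix` on a common grid: trials x
half-open 50-ms bins spanning (-pre, +post) seconds around odor onset, with
the first ``n_baseline_bins`` bins forming the 2-s baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .io import OdorEvent, ValidationError

__all__ = [
    "TrialMatrix",
    "UnitQC",
    "segment_trials",
    "compute_dff",
    "wavelet_band_power",
    "normalize_baseline_power",
    "bin_firing_rate",
    "spontaneous_and_evoked_rate",
    "qc_unit",
    "downsample_to_bins",
]

SIGNAL_KINDS = ("dff", "theta_power", "beta_power", "low_gamma_power",
                "high_gamma_power", "mfr")

# analytic Morlet with omega0 = 6: cmorB-C with B = 2, C = 6 / (2 pi)
_MORLET = "cmor2.0-0.9549296585513721"
_ISI_THRESHOLD_S = 1e-3          # ISIs below 1 ms count as violations
_ISI_VIOLATION_PCT_MAX = 0.75    # single unit iff violation % is below this


@dataclass
class TrialMatrix:
    """One signal for one source and odor, segmented into trials x bins."""

    signal_kind: str
    values: np.ndarray           # (n_trials, n_bins)
    bin_width: float
    window: tuple                # (pre, post), seconds around onset
    odor_id: int
    source: str                  # mouse id or unit id
    n_baseline_bins: int

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(f"unknown signal kind {self.signal_kind!r}")
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValidationError("TrialMatrix values must be 2-D (trials x bins)")
        if not np.isfinite(self.values).all():
            raise ValidationError("TrialMatrix contains non-finite values")
        pre, post = self.window
        expect = int(round((pre + post) / self.bin_width))
        if self.values.shape[1] != expect:
            raise ValidationError(
                f"bin count {self.values.shape[1]} != (pre+post)/bin_width = {expect}"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_times(self) -> np.ndarray:
        """Left edges of the bins, seconds relative to odor onset."""
        pre, _ = self.window
        return -pre + self.bin_width * np.arange(self.n_bins)

    def baseline_means(self) -> np.ndarray:
        """Per-trial mean over the baseline window (one value per trial)."""
        return self.values[:, : self.n_baseline_bins].mean(axis=1)

    def crop_pre(self, new_pre: float) -> "TrialMatrix":
        """Drop leading bins so the window starts ``new_pre`` s before onset."""
        pre, post = self.window
        drop = int(round((pre - new_pre) / self.bin_width))
        if drop < 0:
            raise ValidationError("cannot extend the pre-onset window by cropping")
        return TrialMatrix(self.signal_kind, self.values[:, drop:], self.bin_width,
                           (new_pre, post), self.odor_id, self.source,
                           min(self.n_baseline_bins, int(round(new_pre / self.bin_width))))


@dataclass(frozen=True)
class UnitQC:
    """Interspike-interval quality check for one sorted unit.

    A unit counts as a single unit when fewer than 0.75% of its ISIs are
    shorter than 1 ms.
    """

    unit_id: str
    n_spikes: int
    isi_violation_pct: float
    is_single_unit: bool
    low_count: bool = False


def segment_trials(trace: np.ndarray, sample_rate: float, events: list[OdorEvent],
                   pre: float, post: float) -> np.ndarray:
    """Extract one fixed-length window per event, time-locked to odor onset.

    Returns an (n_events, round((pre+post)*fs)) array; raises listing the
    offending events if any window would run past the recording edges.
    """
    trace = np.asarray(trace, float)
    n = trace.size
    n_pre = int(round(pre * sample_rate))
    n_post = int(round(post * sample_rate))
    bad = []
    starts = []
    for ev in events:
        i_on = int(round(ev.onset_time * sample_rate))
        if i_on - n_pre < 0 or i_on + n_post > n:
            bad.append(ev)
        starts.append(i_on - n_pre)
    if bad:
        raise ValidationError(
            f"{len(bad)} events lack full ({pre}s pre, {post}s post) coverage: "
            + ", ".join(f"t={e.onset_time:.2f}" for e in bad[:5])
        )
    return np.stack([trace[s: s + n_pre + n_post] for s in starts])


def compute_dff(segment: np.ndarray, n_baseline_samples: int) -> np.ndarray:
    """dF/F = (F - F0) / F0 with F0 the mean over the pre-onset baseline window.

    Works on a single segment or a (trials x samples) stack; the baseline-
    window mean of the output is 0 by construction.
    """
    seg = np.atleast_2d(np.asarray(segment, float))
    f0 = seg[:, :n_baseline_samples].mean(axis=1, keepdims=True)
    if (f0 <= 0).any():
        raise ValidationError("baseline fluorescence F0 must be positive")
    out = (seg - f0) / f0
    return out[0] if np.ndim(segment) == 1 else out


@lru_cache(maxsize=32)
def _band_scales(sample_rate: float, low: float, high: float, n_scales: int):
    freqs = np.geomspace(low, high, n_scales)
    scales = pywt.frequency2scale(_MORLET, freqs / sample_rate)
    return freqs, scales


@lru_cache(maxsize=32)
def _band_calibration(sample_rate: float, low: float, high: float, n_scales: int):
    """Numeric calibration so the operator returns in-band mean-square amplitude.

    Stage 1: per scale, the mean |W|^2 response to a unit-amplitude sinusoid
    at that scale's own center frequency (flattens the CWT's scale-dependent
    normalization).  Stage 2: one probe at the geometric band center fixes the
    overall gain so a unit-amplitude in-band sinusoid reads ~0.5 (its mean
    square).  Deterministic; cached per (sample rate, band).
    """
    freqs, scales = _band_scales(sample_rate, low, high, n_scales)
    span = max(6.0, 40.0 / low)              # >= ~40 cycles of the slowest scale
    t = np.arange(int(span * sample_rate)) / sample_rate
    lo_i, hi_i = t.size // 4, 3 * t.size // 4
    gains = np.empty(n_scales)
    for k, (fc, s) in enumerate(zip(freqs, scales)):
        coef, _ = pywt.cwt(np.cos(2 * np.pi * fc * t), [s], _MORLET,
                           sampling_period=1.0 / sample_rate, method="fft")
        gains[k] = (np.abs(coef[0, lo_i:hi_i]) ** 2).mean()
    f_mid = float(np.sqrt(low * high))
    coef, _ = pywt.cwt(np.cos(2 * np.pi * f_mid * t), scales, _MORLET,
                       sampling_period=1.0 / sample_rate, method="fft")
    p_mid = ((np.abs(coef[:, lo_i:hi_i]) ** 2) / (2 * gains[:, None])).mean(axis=0).mean()
    return gains, p_mid / 0.5


def wavelet_band_power(segment: np.ndarray, band: tuple, sample_rate: float,
                       n_scales: int = 10, average_scales: bool = True) -> np.ndarray:
    """Time-resolved band power via the continuous Morlet wavelet transform.

    The squared modulus is combined across ``n_scales`` log-spaced center
    frequencies covering the band (averaged by default) and calibrated so the
    result estimates the signal's in-band mean-square amplitude: a sinusoid
    ``A*cos(2*pi*f*t)`` with f mid-band reads ~``A**2/2`` and white noise
    reads ~its PSD x bandwidth.  Accepts one segment or a stack of segments.
    """
    low, high = band
    if not (0 < low < high):
        raise ValidationError(f"band edges must satisfy 0 < low < high, got {band}")
    if high > sample_rate / 2:
        raise ValidationError(f"band {band} exceeds Nyquist {sample_rate / 2} Hz")
    _, scales = _band_scales(sample_rate, low, high, n_scales)
    gains, band_gain = _band_calibration(sample_rate, low, high, n_scales)
    seg = np.atleast_2d(np.asarray(segment, float))
    out = np.empty_like(seg)
    for i, row in enumerate(seg):
        coef, _ = pywt.cwt(row, scales, _MORLET,
                           sampling_period=1.0 / sample_rate, method="fft")
        p = (np.abs(coef) ** 2) / (2 * gains[:, None])
        combined = p.mean(axis=0) if average_scales else p.sum(axis=0)
        if not average_scales:
            combined = combined / n_scales   # keep calibration consistent
        out[i] = combined / band_gain
    return out[0] if np.ndim(segment) == 1 else out


def normalize_baseline_power(power_segment: np.ndarray, n_baseline_samples: int) -> np.ndarray:
    """Divide each trial's power trace by its own baseline-window mean.

    After normalization the baseline mean of every trial is 1, so trials with
    different absolute power are comparable before averaging within odor.
    """
    seg = np.atleast_2d(np.asarray(power_segment, float))
    base = seg[:, :n_baseline_samples].mean(axis=1, keepdims=True)
    if (base <= 0).any():
        raise ValidationError("baseline power must be positive for normalization")
    out = seg / base
    return out[0] if np.ndim(power_segment) == 1 else out


def bin_firing_rate(timestamps: np.ndarray, events: list[OdorEvent],
                    pre: float, post: float, bin_width: float = 0.05,
                    odor_id: int = 0, source: str = "unit") -> TrialMatrix:
    """Mean firing rate in half-open bins: counts per [t, t+dt) divided by dt (Hz)."""
    ts = np.asarray(timestamps, float)
    if ts.size > 1 and not (np.diff(ts) >= 0).all():
        raise ValidationError("spike timestamps must be ascending")
    n_bins = int(round((pre + post) / bin_width))
    rows = np.zeros((len(events), n_bins))
    for i, ev in enumerate(events):
        start = ev.onset_time - pre
        # half-open bins [t, t+dt); the 1e-9 (bin units) slack keeps spikes
        # lying exactly on an edge in the bin that starts there despite
        # floating-point representation of the edge
        idx = np.floor((ts - start) / bin_width + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(rows[i], idx, 1.0)
    rows /= bin_width
    return TrialMatrix("mfr", rows, bin_width, (pre, post),
                       odor_id=odor_id, source=source,
                       n_baseline_bins=int(round(pre / bin_width)))


def spontaneous_and_evoked_rate(tm: TrialMatrix, baseline_window: float = 2.0,
                                evoked_window: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spontaneous (2 s pre-onset) and evoked (2 s post-onset) rates."""
    pre, post = tm.window
    if baseline_window > pre + 1e-9 or evoked_window > post + 1e-9:
        raise ValidationError("trial window does not cover the requested rate windows")
    nb = int(round(baseline_window / tm.bin_width))
    ne = int(round(evoked_window / tm.bin_width))
    i_on = int(round(pre / tm.bin_width))
    spont = tm.values[:, i_on - nb: i_on].mean(axis=1)
    evoked = tm.values[:, i_on: i_on + ne].mean(axis=1)
    return spont, evoked


def qc_unit(timestamps: np.ndarray, unit_id: str = "unit") -> UnitQC:
    """ISI-violation screen: single unit iff <0.75% of ISIs are below 1 ms."""
    ts = np.asarray(timestamps, float)
    if ts.size < 2:
        return UnitQC(unit_id, int(ts.size), 0.0, True, low_count=True)
    isi = np.diff(ts)
    pct = 100.0 * float((isi < _ISI_THRESHOLD_S).sum()) / isi.size
    return UnitQC(unit_id, int(ts.size), pct, pct < _ISI_VIOLATION_PCT_MAX)


def downsample_to_bins(segment: np.ndarray, sample_rate: float,
                       bin_width: float = 0.05) -> np.ndarray:
    """Mean within consecutive half-open bins; bin width must be a whole
    number of sample intervals."""
    per = bin_width * sample_rate
    if abs(per - round(per)) > 1e-9:
        raise ValidationError(
            f"bin width {bin_width}s is not a multiple of the {1/sample_rate}s sample interval"
        )
    per = int(round(per))
    seg = np.atleast_2d(np.asarray(segment, float))
    n_bins = seg.shape[1] // per
    out = seg[:, : n_bins * per].reshape(seg.shape[0], n_bins, per).mean(axis=2)
    return out[0] if np.ndim(segment) == 1 else out
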