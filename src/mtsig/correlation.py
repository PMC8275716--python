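"""Trial-to-trial correlation analysis.

All correlations are the absolute value of Pearson's r between single-trial
binned response vectors on the common (-2, +6) s / 50-ms grid.  Three
summaries mirror the study's reliability questions: the matched-trial
correlation between the calcium signal and each electrophysiological signal,
the mean pairwise correlation among a stimulus's own trials (within-odor),
and the mean correlation of those trials against every other stimulus's
trials (between-odors), combined into the specificity index (W - B) / W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .preprocess import TrialMatrix

__all__ = [
    "CorrelationMatrix",
    "CorrelationSummary",
    "pearson_abs",
    "cross_signal_correlation",
    "within_odor_correlation",
    "between_odor_correlation",
    "wb_statistic",
    "reliability_summary",
]


@dataclass
class CorrelationMatrix:
    """|r| between trial pairs; NaN marks pairs excluded for zero variance."""

    values: np.ndarray
    signal_pair: str

    def __post_init__(self) -> None:
        v = self.values
        ok = np.isfinite(v)
        if ((v[ok] < -1e-12) | (v[ok] > 1 + 1e-12)).any():
            raise ValidationError("absolute correlations must lie in [0, 1]")

    def diagonal_mean(self) -> float:
        d = np.diagonal(self.values)
        d = d[np.isfinite(d)]
        return float(d.mean()) if d.size else float("nan")

    def offdiag_mean(self) -> float:
        iu = np.triu_indices_from(self.values, k=1)
        v = self.values[iu]
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")


@dataclass(frozen=True)
class CorrelationSummary:
    """Within-odor mean, between-odors mean, and (W - B) / W."""

    within_mean: float
    between_mean: float
    wb_ratio: float


def pearson_abs(x, y) -> float:
    """|Pearson r| between two equal-length vectors; NaN if either is constant."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_abs needs two equal-length vectors of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0 or sy <= 0:
        return float("nan")
    return float(abs((xc @ yc) / np.sqrt(sx * sy)))


def _abs_corr_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|r| between every row of ``a`` and every row of ``b`` (NaN for
    zero-variance rows), vectorized."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac ** 2).sum(axis=1))
    nb = np.sqrt((bc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(na, nb)
    r[na == 0, :] = np.nan
    r[:, nb == 0] = np.nan
    return np.abs(np.clip(r, -1.0, 1.0))


def _check_grid(a: TrialMatrix, b: TrialMatrix) -> None:
    if a.values.shape[1] != b.values.shape[1] or abs(a.bin_width - b.bin_width) > 1e-12 \
            or a.window != b.window:
        raise ValidationError(
            f"trial-matrix grids differ: {a.window}/{a.values.shape[1]} vs "
            f"{b.window}/{b.values.shape[1]}"
        )


def cross_signal_correlation(ca: TrialMatrix, ephys: TrialMatrix) -> CorrelationMatrix:
    """Trial-by-trial |r| between the calcium matrix and an ephys matrix.

    Entry (i, j) correlates calcium trial i with ephys trial j; the headline
    summary is the mean of the matched-trial diagonal.
    """
    _check_grid(ca, ephys)
    if ca.odor_id != ephys.odor_id:
        raise ValidationError("cross-signal correlation requires the same odor")
    vals = _abs_corr_block(ca.values, ephys.values)
    return CorrelationMatrix(vals, f"{ca.signal_kind}~{ephys.signal_kind}")


def within_odor_correlation(tm: TrialMatrix) -> tuple[CorrelationMatrix, float]:
    """All pairwise |r| among one odor's trials; summary is the mean over the
    off-diagonal upper triangle."""
    if tm.n_trials < 2:
        raise ValidationError("within-odor correlation needs >= 2 trials")
    vals = _abs_corr_block(tm.values, tm.values)
    cm = CorrelationMatrix(vals, f"{tm.signal_kind}~{tm.signal_kind}")
    return cm, cm.offdiag_mean()


def between_odor_correlation(tm_target: TrialMatrix,
                             tm_others: list[TrialMatrix]) -> float:
    """Mean |r| between the target odor's trials and all other odors' trials
    (with the full design: a 20 x 140 block of 2800 values)."""
    if not tm_others:
        raise ValidationError("between-odor correlation needs at least one other odor")
    blocks = []
    for other in tm_others:
        _check_grid(tm_target, other)
        blocks.append(_abs_corr_block(tm_target.values, other.values).ravel())
    v = np.concatenate(blocks)
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else float("nan")


def wb_statistic(within_mean: float, between_mean: float) -> float:
    """Stimulus-specificity index (W - B) / W; NaN when W <= 0."""
    if not np.isfinite(within_mean) or within_mean <= 0:
        return float("nan")
    return (within_mean - between_mean) / within_mean


def reliability_summary(tms_by_odor: dict[int, TrialMatrix]) -> CorrelationSummary:
    """Cohort summary for one source: mean within-odor correlation across odors,
    mean between-odor correlation, and their specificity index."""
    odors = sorted(tms_by_odor)
    if len(odors) < 2:
        raise ValidationError("reliability summary needs >= 2 odors")
    withins, betweens = [], []
    for o in odors:
        _, w = within_odor_correlation(tms_by_odor[o])
        b = between_odor_correlation(tms_by_odor[o],
                                     [tms_by_odor[p] for p in odors if p != o])
        withins.append(w)
        betweens.append(b)
    w = float(np.nanmean(withins))
    b = float(np.nanmean(betweens))
    return CorrelationSummary(w, b, wb_statistic(w, b))
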