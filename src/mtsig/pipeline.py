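"""Cohort-level orchestration: raw sessions -> trial matrices -> tables.

These drivers glue the per-operation modules together on the study's grid
(50-ms bins, 2-s baseline, analysis window -2 to +6 s around odor onset; LFP
segmented with 4-s pre-onset padding and cropped to the common window after
wavelet power extraction) and emit tidy tables keyed by mouse, source, odor,
and signal kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import (cross_signal_correlation, reliability_summary)
from .decoding import DecodingCurve, decoding_curve, pair_auroc
from .io import AnalysisConfig, SessionRecording
from .preprocess import (TrialMatrix, bin_firing_rate, compute_dff,
                         downsample_to_bins, normalize_baseline_power, qc_unit,
                         segment_trials, wavelet_band_power)
from .response import detect_response

__all__ = [
    "SessionFeatures",
    "preprocess_session",
    "write_features",
    "response_table",
    "cross_signal_table",
    "reliability_table",
    "pair_auroc_table",
    "decode_signal",
]

FOCUS_BANDS = ("beta", "high_gamma")


@dataclass
class SessionFeatures:
    """All trial matrices for one session, on the common analysis grid."""

    mouse_id: str
    dff: dict = field(default_factory=dict)          # odor -> TrialMatrix
    power: dict = field(default_factory=dict)        # band -> odor -> TrialMatrix
    mfr: dict = field(default_factory=dict)          # unit_id -> odor -> TrialMatrix
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def odors(self) -> list[int]:
        return sorted(self.dff)


def _split_by_odor(values: np.ndarray, events, kind: str, bin_width: float,
                   window: tuple, n_base: int, source: str) -> dict[int, TrialMatrix]:
    odor_ids = np.array([e.odor_id for e in events])
    out = {}
    for o in np.unique(odor_ids):
        out[int(o)] = TrialMatrix(kind, values[odor_ids == o], bin_width, window,
                                  odor_id=int(o), source=source, n_baseline_bins=n_base)
    return out


def preprocess_session(rec: SessionRecording, cfg: AnalysisConfig | None = None,
                       bands: tuple = FOCUS_BANDS) -> SessionFeatures:
    """Segment, transform, bin, and QC one session.

    Calcium -> dF/F; LFP -> per-band normalized wavelet power (each trial's
    baseline mean scaled to 1); spikes -> per-unit mean firing rate, with
    units failing the ISI single-unit criterion dropped from all downstream
    analysis.
    """
    cfg = cfg or AnalysisConfig()
    cfg.validate_bands(rec.lfp_rate_hz)
    bw = cfg.bin_width
    pre, post = cfg.segment_pre, cfg.segment_post
    window = (pre, post)
    n_base_bins = int(round(cfg.baseline_window / bw))
    feat = SessionFeatures(mouse_id=rec.mouse_id)

    # calcium: segment -> dF/F -> 50-ms bins
    seg = segment_trials(rec.ca_trace, rec.ca_rate_hz, rec.events, pre, post)
    n_base_samp = int(round(cfg.baseline_window * rec.ca_rate_hz))
    dff = compute_dff(seg, n_base_samp)
    binned = downsample_to_bins(dff, rec.ca_rate_hz, bw)
    feat.dff = _split_by_odor(binned, rec.events, "dff", bw, window,
                              n_base_bins, rec.mouse_id)

    # LFP: 4-s pre padding absorbs wavelet edge effects, then crop to -2 s
    lfp_seg = segment_trials(rec.lfp_trace, rec.lfp_rate_hz, rec.events,
                             cfg.lfp_segment_pre, post)
    lfp_base_samp = int(round(cfg.baseline_window * rec.lfp_rate_hz))
    base_start = int(round((cfg.lfp_segment_pre - cfg.baseline_window) * rec.lfp_rate_hz))
    for band in bands:
        power = wavelet_band_power(lfp_seg, cfg.band_edges[band], rec.lfp_rate_hz,
                                   average_scales=cfg.band_scale_average)
        base = power[:, base_start: base_start + lfp_base_samp].mean(axis=1, keepdims=True)
        norm = power / base
        binned = downsample_to_bins(norm, rec.lfp_rate_hz, bw)
        drop = int(round((cfg.lfp_segment_pre - pre) / bw))
        feat.power[band] = _split_by_odor(binned[:, drop:], rec.events,
                                          f"{band}_power", bw, window,
                                          n_base_bins, rec.mouse_id)

    # spikes: QC then per-unit MFR matrices
    qc_rows = []
    for k, ts in enumerate(rec.units):
        uid = f"{rec.mouse_id}/u{k:03d}"
        q = qc_unit(ts, uid)
        qc_rows.append({"unit_id": uid, "n_spikes": q.n_spikes,
                        "isi_violation_pct": q.isi_violation_pct,
                        "is_single_unit": q.is_single_unit})
        if not q.is_single_unit:
            continue
        tm_all = bin_firing_rate(ts, rec.events, pre, post, bw, source=uid)
        feat.mfr[uid] = _split_by_odor(tm_all.values, rec.events, "mfr", bw,
                                       window, n_base_bins, uid)
    feat.qc = pd.DataFrame(qc_rows)
    return feat


def _iter_matrices(feat: SessionFeatures):
    for o, tm in feat.dff.items():
        yield "dff", feat.mouse_id, o, tm
    for band, per_odor in feat.power.items():
        for o, tm in per_odor.items():
            yield f"{band}_power", feat.mouse_id, o, tm
    for uid, per_odor in feat.mfr.items():
        for o, tm in per_odor.items():
            yield "mfr", uid, o, tm


def write_features(feat: SessionFeatures, path) -> None:
    """Persist trial matrices into the session container under
    /derived/<signal>/<source>/<odor>."""
    import h5py

    with h5py.File(path, "a") as f:
        if "derived" in f:
            del f["derived"]
        g = f.create_group("derived")
        for kind, source, odor, tm in _iter_matrices(feat):
            d = g.create_dataset(f"{kind}/{source.replace('/', '_')}/odor{odor}",
                                 data=tm.values)
            d.attrs["bin_width"] = tm.bin_width
            d.attrs["window"] = tm.window
            d.attrs["n_baseline_bins"] = tm.n_baseline_bins


def response_table(feats: list[SessionFeatures], cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """auROC response calls for every mouse/cell-odor pair and signal kind."""
    cfg = cfg or AnalysisConfig()
    rows = []

    def _detect(tm: TrialMatrix, mouse: str, source: str, kind: str, odor: int):
        call = detect_response(tm, lo=cfg.auroc_lo, hi=cfg.auroc_hi,
                               min_consecutive_bins=cfg.min_consecutive_bins,
                               smooth=cfg.smooth_auroc,
                               baseline_window=cfg.baseline_window,
                               evoked_window=cfg.evoked_window)
        rows.append({"mouse_id": mouse, "source": source, "signal_kind": kind,
                     "odor_id": odor, "response_class": call.response_class,
                     "onset_latency": call.onset_latency,
                     "peak_latency": call.peak_latency,
                     "duration": call.duration,
                     "scalar_auroc": call.scalar_auroc})

    for feat in feats:
        for o, tm in feat.dff.items():
            _detect(tm, feat.mouse_id, feat.mouse_id, "dff", o)
        for band, per_odor in feat.power.items():
            for o, tm in per_odor.items():
                _detect(tm, feat.mouse_id, feat.mouse_id, f"{band}_power", o)
        for uid, per_odor in feat.mfr.items():
            for o, tm in per_odor.items():
                _detect(tm, feat.mouse_id, uid, "mfr", o)
    return pd.DataFrame(rows)


def cross_signal_table(feats: list[SessionFeatures]) -> pd.DataFrame:
    """Matched-trial |r| between calcium and each ephys signal, per mouse-odor.

    For spikes the per-mouse value is the mean over that mouse's single units.
    """
    rows = []
    for feat in feats:
        for o, ca_tm in feat.dff.items():
            for band, per_odor in feat.power.items():
                cm = cross_signal_correlation(ca_tm, per_odor[o])
                rows.append({"mouse_id": feat.mouse_id, "odor_id": o,
                             "signal_pair": f"dff~{band}_power",
                             "matched_mean": cm.diagonal_mean()})
            unit_means = [cross_signal_correlation(ca_tm, per_odor[o]).diagonal_mean()
                          for per_odor in feat.mfr.values()]
            if unit_means:
                rows.append({"mouse_id": feat.mouse_id, "odor_id": o,
                             "signal_pair": "dff~mfr",
                             "matched_mean": float(np.nanmean(unit_means))})
    return pd.DataFrame(rows)


def reliability_table(feats: list[SessionFeatures]) -> pd.DataFrame:
    """Within-odor vs between-odors reliability per source and signal kind."""
    rows = []

    def _add(mouse, source, kind, tms_by_odor):
        s = reliability_summary(tms_by_odor)
        rows.append({"mouse_id": mouse, "source": source, "signal_kind": kind,
                     "within_mean": s.within_mean, "between_mean": s.between_mean,
                     "wb_ratio": s.wb_ratio})

    for feat in feats:
        _add(feat.mouse_id, feat.mouse_id, "dff", feat.dff)
        for band, per_odor in feat.power.items():
            _add(feat.mouse_id, feat.mouse_id, f"{band}_power", per_odor)
        for uid, per_odor in feat.mfr.items():
            _add(feat.mouse_id, uid, "mfr", per_odor)
    return pd.DataFrame(rows)


def pair_auroc_table(feats: list[SessionFeatures]) -> pd.DataFrame:
    """Folded odor-pair auROC for every signal and unordered odor pair."""
    from itertools import combinations
    rows = []

    def _pairs(mouse, source, kind, tms_by_odor):
        for a, b in combinations(sorted(tms_by_odor), 2):
            pd_ = pair_auroc(tms_by_odor[a], tms_by_odor[b])
            rows.append({"mouse_id": mouse, "source": source, "signal_kind": kind,
                         "odor_a": a, "odor_b": b,
                         "auroc_raw": pd_.auroc_raw,
                         "auroc_folded": pd_.auroc_folded})

    for feat in feats:
        _pairs(feat.mouse_id, feat.mouse_id, "dff", feat.dff)
        for band, per_odor in feat.power.items():
            _pairs(feat.mouse_id, feat.mouse_id, f"{band}_power", per_odor)
        for uid, per_odor in feat.mfr.items():
            _pairs(feat.mouse_id, uid, "mfr", per_odor)
    return pd.DataFrame(rows)


def decode_signal(feat: SessionFeatures, signal_kind: str,
                  cfg: AnalysisConfig | None = None, seed: int = 0,
                  t_grid: np.ndarray | None = None) -> DecodingCurve:
    """Cumulative-window 28-pair decoding for one mouse and signal.

    Calcium and band power contribute one feature channel; spikes contribute
    one channel per single unit (population decoding).
    """
    cfg = cfg or AnalysisConfig()
    if signal_kind == "dff":
        tms = {o: [tm] for o, tm in feat.dff.items()}
    elif signal_kind.endswith("_power"):
        band = signal_kind[: -len("_power")]
        tms = {o: [tm] for o, tm in feat.power[band].items()}
    elif signal_kind == "mfr":
        odors = feat.odors()
        tms = {o: [feat.mfr[uid][o] for uid in sorted(feat.mfr)] for o in odors}
    else:
        raise ValueError(f"unknown signal kind {signal_kind!r}")
    return decoding_curve(tms, signal_kind, feature_end=cfg.feature_end,
                          bin_width=cfg.bin_width, folds=cfg.cv_folds, seed=seed,
                          C=cfg.decoder_C, tol=cfg.decoder_tol, t_grid=t_grid)
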