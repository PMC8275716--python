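"""Session data model and HDF5 container I/O.

A session holds the three co-registered signals recorded from the olfactory
bulb of one head-fixed mouse — a fiber-photometry population calcium trace
(500 Hz), a local-field-potential trace (1 kHz), and sorted single-unit spike
timestamps — together with the odor-presentation event schedule.  All
timestamps are seconds from recording start; bins downstream are half-open
``[t, t + dt)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OdorEvent",
    "SessionRecording",
    "AnalysisConfig",
    "GroundTruthManifest",
    "read_session",
    "write_session",
    "FormatError",
    "ValidationError",
]


class FormatError(Exception):
    """The on-disk container is missing a required group or dataset."""


class ValidationError(Exception):
    """A session violates a structural invariant."""


@dataclass(frozen=True)
class OdorEvent:
    """One odor presentation: onset (s), odor identity (1..n_odors), duration (s)."""

    onset_time: float
    odor_id: int
    duration: float = 2.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(f"odor duration must be > 0, got {self.duration}")
        if self.odor_id < 1:
            raise ValidationError(f"odor_id must be >= 1, got {self.odor_id}")


@dataclass
class GroundTruthManifest:
    """Ground truth for a synthetic session.

    ``cell_odor`` has one row per cell-odor pair with the true response class
    ('excitatory' | 'inhibitory' | 'none'), onset/peak latency and duration in
    seconds from odor onset, and the fractional rate-modulation depth.
    ``odor`` has one row per odor with the beta-band amplitude gain (>1) and
    high-gamma amplitude gain (<1) applied during the odor response, and a
    population response template id.  ``kernel`` holds the calcium impulse
    kernel's rise/decay time constants (s).
    """

    cell_odor: pd.DataFrame
    odor: pd.DataFrame
    kernel: dict = field(default_factory=dict)

    _CELL_COLS = ("cell", "odor_id", "true_class", "true_onset_latency",
                  "true_peak_latency", "true_duration", "depth")
    _ODOR_COLS = ("odor_id", "beta_gain", "high_gamma_gain", "template_id")

    def validate(self, segment_post: float = 6.0) -> None:
        co = self.cell_odor
        for c in self._CELL_COLS:
            if c not in co.columns:
                raise ValidationError(f"manifest cell_odor lacks column {c!r}")
        resp = co[co["true_class"] != "none"]
        if not np.isfinite(resp["depth"].to_numpy(float)).all():
            raise ValidationError("modulation depths must be finite")
        lat = resp["true_onset_latency"].to_numpy(float)
        if ((lat < 0) | (lat >= segment_post)).any():
            raise ValidationError("onset latencies must lie in [0, segment_post)")
        gains = self.odor[["beta_gain", "high_gamma_gain"]].to_numpy(float)
        if (gains <= 0).any():
            raise ValidationError("band gain factors must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruthManifest):
            return NotImplemented
        return (
            self.cell_odor.reset_index(drop=True).equals(other.cell_odor.reset_index(drop=True))
            and self.odor.reset_index(drop=True).equals(other.odor.reset_index(drop=True))
            and self.kernel == other.kernel
        )


@dataclass
class SessionRecording:
    """Raw co-registered traces, spike trains, and odor events for one mouse."""

    mouse_id: str
    ca_trace: np.ndarray
    lfp_trace: np.ndarray
    units: list[np.ndarray]
    events: list[OdorEvent]
    ca_rate_hz: float = 500.0
    lfp_rate_hz: float = 1000.0
    ground_truth: Optional[GroundTruthManifest] = None

    @property
    def duration(self) -> float:
        """Session length in seconds (from the calcium trace)."""
        return len(self.ca_trace) / self.ca_rate_hz

    def validate(self, min_pre: float = 2.0, min_post: float = 6.0) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure.

        Every event must have at least ``min_pre`` seconds of recorded signal
        before onset and ``min_post`` after, so trial segmentation never runs
        off the edge of the recording.
        """
        dur_ca = len(self.ca_trace) / self.ca_rate_hz
        dur_lfp = len(self.lfp_trace) / self.lfp_rate_hz
        if abs(dur_ca - dur_lfp) > 0.5:
            raise ValidationError(
                f"trace durations disagree: ca {dur_ca:.3f}s vs lfp {dur_lfp:.3f}s"
            )
        for k, ts in enumerate(self.units):
            ts = np.asarray(ts, float)
            if ts.size and not (np.diff(ts) > 0).all():
                raise ValidationError(f"unit {k}: spike timestamps not strictly ascending")
            if ts.size and (ts[0] < 0 or ts[-1] > dur_ca + 1.0):
                raise ValidationError(f"unit {k}: spike timestamps outside recording span")
        dur = min(dur_ca, dur_lfp)
        last_end = -np.inf
        bad = []
        for ev in self.events:
            if ev.onset_time < last_end:
                raise ValidationError("events overlap or are out of order")
            last_end = ev.onset_time + ev.duration
            if ev.onset_time - min_pre < 0 or ev.onset_time + min_post > dur:
                bad.append(ev)
        if bad:
            raise ValidationError(
                f"{len(bad)} events lack {min_pre}s pre / {min_post}s post coverage; "
                f"first offender at t={bad[0].onset_time:.2f}s"
            )


@dataclass
class AnalysisConfig:
    """Analysis parameters shared across the pipeline.

    Defaults follow the study design: 50-ms bins, 2-s baseline and evoked
    windows, calcium/spike segments from 2 s before to 6 s after odor onset,
    LFP segments from 4 s before (the extra pre-onset padding absorbs wavelet
    edge effects), LFP bands theta 2-12, beta 15-35, low gamma 36-65, high
    gamma 66-95 Hz, auROC response thresholds 0.25/0.75 with a 3-consecutive-
    bin persistence rule, and a 10-fold CV logistic decoder on cumulative
    0-5 s features.
    """

    bin_width: float = 0.05
    baseline_window: float = 2.0
    evoked_window: float = 2.0
    segment_pre: float = 2.0
    segment_post: float = 6.0
    lfp_segment_pre: float = 4.0
    band_edges: dict = field(default_factory=lambda: {
        "theta": (2.0, 12.0),
        "beta": (15.0, 35.0),
        "low_gamma": (36.0, 65.0),
        "high_gamma": (66.0, 95.0),
    })
    auroc_lo: float = 0.25
    auroc_hi: float = 0.75
    min_consecutive_bins: int = 3
    smooth_auroc: bool = False
    cv_folds: int = 10
    feature_end: float = 5.0
    decoder_C: float = 1.0
    decoder_tol: float = 1e-6
    band_scale_average: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.auroc_lo < 0.5 < self.auroc_hi < 1):
            raise ValidationError(
                f"need 0 < auroc_lo < 0.5 < auroc_hi < 1, got {self.auroc_lo}/{self.auroc_hi}"
            )
        for name, (lo, hi) in self.band_edges.items():
            if not (0 < lo < hi):
                raise ValidationError(f"band {name}: edges must satisfy 0 < low < high")

    def validate_bands(self, lfp_rate_hz: float) -> None:
        nyq = lfp_rate_hz / 2.0
        for name, (lo, hi) in self.band_edges.items():
            if hi > nyq:
                raise ValidationError(f"band {name} upper edge {hi} Hz exceeds Nyquist {nyq} Hz")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_edges" in raw:
            raw["band_edges"] = {k: tuple(v) for k, v in raw["band_edges"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band_edges"] = {k: list(v) for k, v in d["band_edges"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# HDF5 container layout:
#   /ca        dataset, attr sample_rate_hz
#   /lfp       dataset, attr sample_rate_hz
#   /units/u000 ... one dataset of ascending spike times per unit
#   /events/{onset_time, odor_id, duration}
#   /ground_truth/cell_odor/<col>, /ground_truth/odor/<col>, attrs: kernel JSON
#   root attrs: mouse_id
# ---------------------------------------------------------------------------


def write_session(rec: SessionRecording, path) -> None:
    """Write a validated session to an HDF5 container (rereadable bit-identically)."""
    rec.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["mouse_id"] = rec.mouse_id
        ca = f.create_dataset("ca", data=np.asarray(rec.ca_trace, np.float64))
        ca.attrs["sample_rate_hz"] = float(rec.ca_rate_hz)
        lfp = f.create_dataset("lfp", data=np.asarray(rec.lfp_trace, np.float64))
        lfp.attrs["sample_rate_hz"] = float(rec.lfp_rate_hz)
        ug = f.create_group("units")
        for k, ts in enumerate(rec.units):
            ug.create_dataset(f"u{k:03d}", data=np.asarray(ts, np.float64))
        eg = f.create_group("events")
        eg.create_dataset("onset_time", data=np.array([e.onset_time for e in rec.events]))
        eg.create_dataset("odor_id", data=np.array([e.odor_id for e in rec.events], np.int64))
        eg.create_dataset("duration", data=np.array([e.duration for e in rec.events]))
        if rec.ground_truth is not None:
            gt = f.create_group("ground_truth")
            for name, df in (("cell_odor", rec.ground_truth.cell_odor),
                             ("odor", rec.ground_truth.odor)):
                g = gt.create_group(name)
                g.attrs["columns"] = json.dumps(list(df.columns))
                for col in df.columns:
                    vals = df[col].to_numpy()
                    if vals.dtype == object:
                        g.create_dataset(col, data=np.array(vals, dtype=h5py.string_dtype()))
                    else:
                        g.create_dataset(col, data=vals)
            gt.attrs["kernel"] = json.dumps(rec.ground_truth.kernel)


def read_session(path) -> SessionRecording:
    """Read and validate a session container written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for req in ("ca", "lfp", "units", "events"):
            if req not in f:
                raise FormatError(f"container {path.name} lacks required element '/{req}'")
        for req in ("onset_time", "odor_id", "duration"):
            if req not in f["events"]:
                raise FormatError(f"container {path.name} lacks '/events/{req}'")
        events = [
            OdorEvent(float(t), int(o), float(d))
            for t, o, d in zip(f["events/onset_time"][...],
                               f["events/odor_id"][...],
                               f["events/duration"][...])
        ]
        units = [f["units"][k][...] for k in sorted(f["units"])]
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            frames = {}
            for name in ("cell_odor", "odor"):
                cols = json.loads(g[name].attrs["columns"])
                data = {}
                for col in cols:
                    v = g[name][col][...]
                    if v.dtype.kind in ("S", "O"):
                        v = np.array([s.decode() if isinstance(s, bytes) else s for s in v])
                    data[col] = v
                frames[name] = pd.DataFrame(data, columns=cols)
            gt = GroundTruthManifest(frames["cell_odor"], frames["odor"],
                                     json.loads(g.attrs["kernel"]))
        rec = SessionRecording(
            mouse_id=str(f.attrs["mouse_id"]),
            ca_trace=f["ca"][...],
            ca_rate_hz=float(f["ca"].attrs["sample_rate_hz"]),
            lfp_trace=f["lfp"][...],
            lfp_rate_hz=float(f["lfp"].attrs["sample_rate_hz"]),
            units=units,
            events=events,
            ground_truth=gt,
        )
    rec.validate()
    return rec
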