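"""Synthetic cohort generator.

Emulates the study design: per mouse, 8 odors x 20 trials of a 2-s odor
presentation, with three co-registered signals generated from one common
ground truth so that the cross-signal structure the analysis looks for exists
by construction:

* single-unit spikes are inhomogeneous-Poisson trains whose rate is modulated
  (up for excitatory, down for inhibitory cell-odor pairs) by a piecewise-
  linear response profile with a known onset latency, peak latency and
  duration;
* the LFP is 1/f background noise plus band-limited beta (15-35 Hz) and
  high-gamma (66-95 Hz) carriers whose envelopes are scaled by per-odor gain
  factors (beta gain > 1, high-gamma gain < 1) during the odor response;
* the population calcium trace is the summed spike train convolved with a
  GCaMP6s-like double-exponential kernel, plus shot noise.

A single per-trial amplitude scalar multiplies the spike-rate modulation and
both LFP envelopes, so trial-to-trial amplitude covaries across signals.
No quantitative response-amplitude distributions are published for this
preparation; the defaults below are free parameters of the generator and are
documented as such in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, fftconvolve, sosfiltfilt

from .io import GroundTruthManifest, OdorEvent, SessionRecording, ValidationError

__all__ = [
    "SimConfig",
    "make_manifest",
    "make_event_schedule",
    "response_profile",
    "simulate_spikes",
    "simulate_lfp",
    "simulate_calcium",
    "simulate_session",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Generator parameters.

    Desk-scale defaults shrink the inter-trial interval (30 s in vivo -> 8 s)
    and the mouse count (11 -> 3) but never the 8-odor x 20-trial design,
    since the downstream statistics key on trial and odor counts.
    ``full_scale()`` restores the in-vivo schedule.
    """

    n_mice: int = 3
    n_cells_per_mouse: int = 6
    n_odors: int = 8
    n_trials: int = 20
    iti: float = 8.0
    odor_duration: float = 2.0

    # spikes -------------------------------------------------------------
    baseline_rate_range: tuple = (5.0, 20.0)
    p_excitatory: float = 0.35
    p_inhibitory: float = 0.25
    exc_depth_range: tuple = (2.0, 4.0)
    inh_depth_range: tuple = (0.70, 0.95)
    # onset latencies on the 50-ms analysis grid, spanning the ~0.1-0.6 s
    # range typical of odor-evoked olfactory-bulb responses
    onset_latency_choices: tuple = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35,
                                    0.40, 0.45, 0.50, 0.55, 0.60)
    duration_choices: tuple = (1.5, 2.0, 2.5)
    response_rise: float = 0.10
    response_fall: float = 0.25
    refractory_s: float = 0.0015

    # shared trial-to-trial amplitude scalar (lognormal, sigma below)
    amp_jitter_sd: float = 0.15

    # LFP ----------------------------------------------------------------
    lfp_rate_hz: float = 1000.0
    lfp_background_rms: float = 50.0   # uV
    beta_band: tuple = (15.0, 35.0)
    high_gamma_band: tuple = (66.0, 95.0)
    beta_rms: float = 30.0             # uV, baseline carrier amplitude
    high_gamma_rms: float = 20.0
    beta_gain_range: tuple = (1.8, 2.4)
    high_gamma_gain_range: tuple = (0.4, 0.6)
    lfp_response_onset: float = 0.2
    lfp_response_rise: float = 0.2

    # calcium ------------------------------------------------------------
    ca_rate_hz: float = 500.0
    ca_offset: float = 1.0             # baseline fluorescence F0, a.u.
    ca_coupling: float = 0.5           # fractional F change per fractional rate change
    ca_noise_sd: float = 0.005         # Gaussian noise SD, fraction of F0
    ca_rise_tau: float = 0.2           # s, GCaMP6s-like
    ca_decay_tau: float = 1.5          # s

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValidationError("n_trials must be >= 2")
        if self.p_excitatory + self.p_inhibitory > 1 + 1e-12:
            raise ValidationError("class mixture proportions exceed 1")
        if self.ca_offset <= 0:
            raise ValidationError("calcium baseline offset must be positive")
        if self.iti < 6.0:
            raise ValidationError("iti must leave >= 6 s post-odor coverage before the next trial")

    @property
    def p_none(self) -> float:
        return 1.0 - self.p_excitatory - self.p_inhibitory

    @classmethod
    def high_snr(cls, **over) -> "SimConfig":
        """Preset for parameter-recovery studies: strong, fast, clean responses."""
        kw = dict(
            baseline_rate_range=(15.0, 25.0),
            exc_depth_range=(3.0, 4.0),
            inh_depth_range=(0.90, 0.98),
            response_rise=0.05,
            amp_jitter_sd=0.05,
            ca_noise_sd=0.002,
        )
        kw.update(over)
        return cls(**kw)

    @classmethod
    def full_scale(cls, **over) -> "SimConfig":
        """The in-vivo schedule: 11 mice, 30-s inter-trial interval."""
        kw = dict(n_mice=11, iti=30.0)
        kw.update(over)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def make_manifest(cfg: SimConfig, rng: np.random.Generator) -> GroundTruthManifest:
    """Draw one mouse's ground truth.

    Response classes are assigned, not sampled: when proportion x pair-count
    is integral the realized class mixture matches the request exactly.
    """
    n_pairs = cfg.n_cells_per_mouse * cfg.n_odors
    n_exc = int(round(cfg.p_excitatory * n_pairs))
    n_inh = int(round(cfg.p_inhibitory * n_pairs))
    classes = np.array(
        ["excitatory"] * n_exc + ["inhibitory"] * n_inh
        + ["none"] * (n_pairs - n_exc - n_inh)
    )
    rng.shuffle(classes)

    cells = np.repeat(np.arange(cfg.n_cells_per_mouse), cfg.n_odors)
    odors = np.tile(np.arange(1, cfg.n_odors + 1), cfg.n_cells_per_mouse)
    onset = rng.choice(cfg.onset_latency_choices, n_pairs)
    dur = rng.choice(cfg.duration_choices, n_pairs)
    depth = np.where(
        classes == "excitatory",
        rng.uniform(*cfg.exc_depth_range, n_pairs),
        np.where(classes == "inhibitory", rng.uniform(*cfg.inh_depth_range, n_pairs), 0.0),
    )
    mask_none = classes == "none"
    onset = np.where(mask_none, 0.0, onset)
    dur = np.where(mask_none, 0.0, dur)
    cell_odor = pd.DataFrame({
        "cell": cells,
        "odor_id": odors,
        "true_class": classes,
        "true_onset_latency": onset,
        "true_peak_latency": np.where(mask_none, 0.0, onset + cfg.response_rise),
        "true_duration": dur,
        "depth": depth,
        "baseline_rate": np.repeat(
            rng.uniform(*cfg.baseline_rate_range, cfg.n_cells_per_mouse), cfg.n_odors
        ),
    })
    odor = pd.DataFrame({
        "odor_id": np.arange(1, cfg.n_odors + 1),
        "beta_gain": rng.uniform(*cfg.beta_gain_range, cfg.n_odors),
        "high_gamma_gain": rng.uniform(*cfg.high_gamma_gain_range, cfg.n_odors),
        "template_id": np.arange(1, cfg.n_odors + 1),
    })
    man = GroundTruthManifest(
        cell_odor, odor,
        kernel={"rise_tau": cfg.ca_rise_tau, "decay_tau": cfg.ca_decay_tau},
    )
    man.validate()
    return man


def make_event_schedule(cfg: SimConfig, rng: np.random.Generator,
                        pre_pad: float = 6.0) -> list[OdorEvent]:
    """Randomized interleaved order of n_odors x n_trials presentations."""
    order = rng.permutation(np.repeat(np.arange(1, cfg.n_odors + 1), cfg.n_trials))
    step = cfg.odor_duration + cfg.iti
    return [OdorEvent(pre_pad + k * step, int(o), cfg.odor_duration)
            for k, o in enumerate(order)]


def response_profile(t: np.ndarray, onset: float, peak: float, end: float,
                     fall: float = 0.0) -> np.ndarray:
    """Trapezoidal response profile, times relative to odor onset: 0 before
    ``onset``, linear rise to 1 at ``peak``, plateau, then linear fall over
    the final ``fall`` seconds so the profile is 0 again at ``end``.
    With ``peak == onset`` and ``fall == 0`` the profile is rectangular."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    if end <= onset:
        return out
    fall = min(fall, end - peak)
    fall_start = end - fall
    if peak > onset:
        rise = (t - onset) / (peak - onset)
        out = np.where((t >= onset) & (t < peak), rise, out)
    out = np.where((t >= peak) & (t < fall_start), 1.0, out)
    if fall > 0:
        out = np.where((t >= fall_start) & (t < end), (end - t) / fall, out)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# signal generators
# ---------------------------------------------------------------------------


def _enforce_refractory(ts: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy deletion of spikes closer than ``refractory`` to the last kept one."""
    if ts.size < 2:
        return ts
    keep = np.ones(ts.size, bool)
    last = ts[0]
    for i in range(1, ts.size):
        if ts[i] - last < refractory:
            keep[i] = False
        else:
            last = ts[i]
    return ts[keep]


def simulate_spikes(cfg: SimConfig, manifest: GroundTruthManifest,
                    events: list[OdorEvent], trial_amps: np.ndarray,
                    duration: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains for one mouse's cells.

    During each presentation of odor o, cell c's rate is
    ``base * (1 + depth * amp * profile(t))`` for excitatory pairs and
    ``base * (1 - depth * amp * profile(t))`` (floored at 0) for inhibitory
    pairs, where ``amp`` is the trial's shared amplitude scalar.  Excitatory
    modulation is realized by superposing an extra thinned Poisson process on
    the homogeneous baseline train; inhibitory modulation by thinning the
    baseline train inside the response window.  Spikes closer than the
    refractory interval (1.5 ms) are deleted, which guarantees every generated
    unit passes the <1-ms ISI single-unit criterion.
    """
    co = manifest.cell_odor
    units: list[np.ndarray] = []
    for cell in range(cfg.n_cells_per_mouse):
        rows = co[co["cell"] == cell].set_index("odor_id")
        base = float(rows["baseline_rate"].iloc[0])
        n_base = rng.poisson(base * duration)
        ts = np.sort(rng.uniform(0.0, duration, n_base))
        keep = np.ones(ts.size, bool)
        extra: list[np.ndarray] = []
        for ev, amp in zip(events, trial_amps):
            r = rows.loc[ev.odor_id]
            if r["true_class"] == "none":
                continue
            on = ev.onset_time + r["true_onset_latency"]
            pk = ev.onset_time + r["true_peak_latency"]
            end = on + r["true_duration"]
            mod = float(r["depth"]) * float(amp)
            if r["true_class"] == "excitatory":
                lam = base * mod                     # peak extra rate
                n = rng.poisson(lam * (end - on))
                cand = rng.uniform(on, end, n)
                p = response_profile(cand - ev.onset_time,
                                     on - ev.onset_time, pk - ev.onset_time,
                                     end - ev.onset_time, cfg.response_fall)
                extra.append(cand[rng.random(n) < p])
            else:
                in_win = (ts >= on) & (ts < end)
                if in_win.any():
                    p = response_profile(ts[in_win] - ev.onset_time,
                                         on - ev.onset_time, pk - ev.onset_time,
                                         end - ev.onset_time, cfg.response_fall)
                    # retain probability 1 - depth*amp*profile, floored at 0
                    retain = np.clip(1.0 - mod * p, 0.0, 1.0)
                    keep[np.where(in_win)[0]] &= rng.random(in_win.sum()) < retain
        ts = np.sort(np.concatenate([ts[keep]] + extra)) if extra else ts[keep]
        ts = _enforce_refractory(ts, cfg.refractory_s)
        units.append(ts)
    return units


def _one_over_f_noise(n: int, fs: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** -0.5          # amplitude ~ f^-1/2 -> power ~ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(n: int, fs: float, band: tuple, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_lfp(cfg: SimConfig, manifest: GroundTruthManifest,
                 events: list[OdorEvent], trial_amps: np.ndarray,
                 duration: float, rng: np.random.Generator) -> np.ndarray:
    """1/f background plus beta and high-gamma carriers with odor-gated envelopes.

    During each odor response the band carrier amplitude is scaled by
    ``1 + (gain - 1) * amp * profile(t)``, so a beta gain of 2 doubles the
    envelope (quadruples band power) at the response peak of an average trial.
    """
    fs = cfg.lfp_rate_hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lfp = _one_over_f_noise(n, fs, cfg.lfp_background_rms, rng)
    odor_tab = manifest.odor.set_index("odor_id")
    for band, rms, gain_col in (
        (cfg.beta_band, cfg.beta_rms, "beta_gain"),
        (cfg.high_gamma_band, cfg.high_gamma_rms, "high_gamma_gain"),
    ):
        carrier = _band_noise(n, fs, band, rms, rng)
        env = np.ones(n)
        on_rel = cfg.lfp_response_onset
        pk_rel = on_rel + cfg.lfp_response_rise
        end_rel = on_rel + cfg.odor_duration
        for ev, amp in zip(events, trial_amps):
            g = float(odor_tab.loc[ev.odor_id, gain_col])
            i0 = int(round((ev.onset_time + on_rel) * fs))
            i1 = int(round((ev.onset_time + end_rel) * fs))
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 <= i0:
                continue
            p = response_profile(t[i0:i1] - ev.onset_time, on_rel, pk_rel, end_rel,
                                 cfg.response_fall)
            env[i0:i1] += (g - 1.0) * float(amp) * p
        lfp = lfp + carrier * np.clip(env, 0.0, None)
    return lfp


def calcium_kernel(rise_tau: float, decay_tau: float, dt: float) -> np.ndarray:
    """Peak-normalized double-exponential impulse response."""
    t = np.arange(0.0, decay_tau * 8.0, dt)
    h = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = h.max()
    if peak <= 0:
        raise ValidationError("degenerate calcium kernel (rise_tau >= decay_tau?)")
    return h / peak


def simulate_calcium(cfg: SimConfig, manifest: GroundTruthManifest,
                     units: list[np.ndarray], duration: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Population fluorescence: summed spikes convolved with the calcium kernel.

    F(t) = F0 * (1 + coupling * D(t)) + noise, where D(t) is the kernel-
    filtered population spike train normalized so its baseline level is ~1.
    A fractional population-rate change of delta therefore moves dF/F by
    about coupling * delta / (1 + coupling).
    """
    fs = cfg.ca_rate_hz
    dt = 1.0 / fs
    n = int(round(duration * fs))
    counts = np.zeros(n)
    for ts in units:
        idx = np.floor(ts * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    h = calcium_kernel(cfg.ca_rise_tau, cfg.ca_decay_tau, dt)
    drive = fftconvolve(counts, h)[:n]
    base_total = float(manifest.cell_odor.groupby("cell")["baseline_rate"].first().sum())
    norm = base_total * dt * h.sum()
    if norm > 0:
        drive = drive / norm
    f = cfg.ca_offset * (1.0 + cfg.ca_coupling * drive)
    if cfg.ca_noise_sd > 0:
        f = f + cfg.ca_offset * cfg.ca_noise_sd * rng.standard_normal(n)
    return f


# ---------------------------------------------------------------------------
# session / cohort
# ---------------------------------------------------------------------------


def simulate_session(cfg: SimConfig, mouse_id: str,
                     rng: np.random.Generator) -> SessionRecording:
    manifest = make_manifest(cfg, rng)
    events = make_event_schedule(cfg, rng)
    n_ev = len(events)
    trial_amps = np.exp(rng.normal(0.0, cfg.amp_jitter_sd, n_ev))
    duration = events[-1].onset_time + cfg.odor_duration + 8.0
    units = simulate_spikes(cfg, manifest, events, trial_amps, duration, rng)
    lfp = simulate_lfp(cfg, manifest, events, trial_amps, duration, rng)
    ca = simulate_calcium(cfg, manifest, units, duration, rng)
    rec = SessionRecording(
        mouse_id=mouse_id, ca_trace=ca, lfp_trace=lfp, units=units,
        events=events, ca_rate_hz=cfg.ca_rate_hz, lfp_rate_hz=cfg.lfp_rate_hz,
        ground_truth=manifest,
    )
    rec.validate()
    return rec


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> list[SessionRecording]:
    """Simulate ``cfg.n_mice`` sessions; identical seed yields an identical cohort."""
    seed = cfg.rng_seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(cfg.n_mice)
    return [
        simulate_session(cfg, f"m{i:02d}", np.random.default_rng(child))
        for i, child in enumerate(children)
    ]
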