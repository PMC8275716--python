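"""Generator checks: Poisson mechanics, band-power gains, calcium kernel,
event schedule, and determinism."""

import numpy as np
import pytest
from scipy import stats

from mtsig.io import OdorEvent, ValidationError
from mtsig.preprocess import bin_firing_rate, qc_unit, wavelet_band_power
from mtsig.synth import (SimConfig, calcium_kernel, make_event_schedule,
                         make_manifest, response_profile, simulate_calcium,
                         simulate_cohort, simulate_lfp, simulate_spikes)


def _rect_spike_cfg(base, depth, kind, **over):
    """One cell, one response class, rectangular modulation over the 2-s odor."""
    kw = dict(n_cells_per_mouse=1, baseline_rate_range=(base, base),
              p_excitatory=1.0 if kind == "excitatory" else 0.0,
              p_inhibitory=1.0 if kind == "inhibitory" else 0.0,
              exc_depth_range=(depth, depth), inh_depth_range=(depth, depth),
              onset_latency_choices=(0.0,), duration_choices=(2.0,),
              response_rise=0.0, response_fall=0.0, amp_jitter_sd=0.0)
    kw.update(over)
    cfg = SimConfig(**kw)
    return cfg


def _simulate_pair(cfg, n_trials=20, seed=0):
    rng = np.random.default_rng(seed)
    man = make_manifest(cfg, rng)
    man.cell_odor["true_peak_latency"] = man.cell_odor["true_onset_latency"]
    events = [OdorEvent(6.0 + 10.0 * k, 1, 2.0) for k in range(n_trials)]
    dur = events[-1].onset_time + 8.0
    units = simulate_spikes(cfg, man, events, np.ones(n_trials), dur, rng)
    return bin_firing_rate(units[0], events, 2.0, 6.0, 0.05)


def test_homogeneous_train_isi_is_exponential():
    """1000 s at 10 Hz (refractoriness off) -> ISIs follow Exp(10) by K-S."""
    cfg = SimConfig(n_cells_per_mouse=1, baseline_rate_range=(10.0, 10.0),
                    p_excitatory=0.0, p_inhibitory=0.0, refractory_s=0.0)
    rng = np.random.default_rng(0)
    man = make_manifest(cfg, rng)
    ts = simulate_spikes(cfg, man, [], np.array([]), 1000.0, rng)[0]
    p = stats.kstest(np.diff(ts), "expon", args=(0, 0.1)).pvalue
    assert p > 0.01


def test_null_modulation_leaves_evoked_rate_at_baseline():
    cfg = _rect_spike_cfg(10.0, 0.0, "excitatory", refractory_s=0.0)
    cfg.p_excitatory, cfg.p_inhibitory = 0.0, 0.0
    tm = _simulate_pair(cfg, n_trials=40, seed=1)
    evoked = tm.values[:, 40:80].mean()
    se = np.sqrt(10.0 / (40 * 2.0))
    assert abs(evoked - 10.0) < 3 * se


def test_excitatory_depth_doubles_evoked_rate():
    """Baseline 10 Hz, depth 1.0, rectangular 2-s window: evoked ~ 20 Hz."""
    cfg = _rect_spike_cfg(10.0, 1.0, "excitatory", refractory_s=0.0)
    tm = _simulate_pair(cfg, seed=2)
    evoked = tm.values[:, 40:80].mean()
    se = np.sqrt(20.0 / (20 * 2.0))
    assert abs(evoked - 20.0) < 3 * se


def test_inhibitory_depth_suppresses_evoked_rate():
    cfg = _rect_spike_cfg(20.0, 0.9, "inhibitory", refractory_s=0.0)
    tm = _simulate_pair(cfg, seed=3)
    evoked = tm.values[:, 40:80].mean()
    se = np.sqrt(2.0 / (20 * 2.0))
    assert abs(evoked - 2.0) < 3 * se


def test_refractory_deletion_guarantees_single_unit_qc(desk_session):
    for k, ts in enumerate(desk_session.units):
        isi = np.diff(ts)
        assert (isi >= 0.0015 - 1e-12).all()
        assert qc_unit(ts, f"u{k}").is_single_unit


def test_manifest_class_mixture_is_exact():
    cfg = SimConfig(n_cells_per_mouse=5, n_odors=8,
                    p_excitatory=0.30, p_inhibitory=0.30)   # 40 pairs: 12/12/16
    man = make_manifest(cfg, np.random.default_rng(4))
    counts = man.cell_odor["true_class"].value_counts()
    assert counts["excitatory"] == 12 and counts["inhibitory"] == 12 and counts["none"] == 16


def test_response_profile_is_trapezoid():
    t = np.array([0.0, 0.1, 0.2, 1.0, 1.8, 1.95, 2.1])
    p = response_profile(t, onset=0.1, peak=0.2, end=2.0, fall=0.2)
    np.testing.assert_allclose(p, [0.0, 0.0, 1.0, 1.0, 1.0, 0.25, 0.0])


def test_event_schedule_interleaves_all_odors():
    cfg = SimConfig()
    ev = make_event_schedule(cfg, np.random.default_rng(5))
    assert len(ev) == 160
    odors = np.array([e.odor_id for e in ev])
    assert all((odors == o).sum() == 20 for o in range(1, 9))
    onsets = np.array([e.onset_time for e in ev])
    np.testing.assert_allclose(np.diff(onsets), cfg.odor_duration + cfg.iti)


def test_cohort_is_deterministic_under_fixed_seed():
    cfg = SimConfig(n_mice=1, n_cells_per_mouse=2, n_odors=2, n_trials=2)
    a = simulate_cohort(cfg, seed=6)[0]
    b = simulate_cohort(cfg, seed=6)[0]
    np.testing.assert_array_equal(a.ca_trace, b.ca_trace)
    np.testing.assert_array_equal(a.lfp_trace, b.lfp_trace)
    for ua, ub in zip(a.units, b.units):
        np.testing.assert_array_equal(ua, ub)
    assert a.events == b.events
    assert a.ground_truth == b.ground_truth


def _lfp_gain_setup(beta_gain, hg_gain, seed):
    cfg = SimConfig(n_cells_per_mouse=1, amp_jitter_sd=0.0, lfp_background_rms=3.0,
                    beta_gain_range=(beta_gain, beta_gain),
                    high_gamma_gain_range=(hg_gain, hg_gain),
                    lfp_response_onset=0.0, lfp_response_rise=0.0, response_fall=0.0)
    rng = np.random.default_rng(seed)
    man = make_manifest(cfg, rng)
    events = [OdorEvent(6.0 + 10.0 * k, 1 + k % 8, 2.0) for k in range(40)]
    lfp = simulate_lfp(cfg, man, events, np.ones(40), 420.0, rng)
    return lfp, events


def _band_ratio(lfp, events, band):
    bp = wavelet_band_power(lfp, band, 1000.0)
    base, odor = [], []
    for ev in events:
        i = int(ev.onset_time * 1000)
        base.append(bp[i - 2000: i].mean())
        odor.append(bp[i + 200: i + 1800].mean())
    return np.mean(odor) / np.mean(base)


def test_lfp_unit_gains_leave_band_power_flat():
    lfp, events = _lfp_gain_setup(1.0, 1.0, seed=7)
    assert abs(_band_ratio(lfp, events, (15.0, 35.0)) - 1.0) < 0.15
    assert abs(_band_ratio(lfp, events, (66.0, 95.0)) - 1.0) < 0.15


def test_lfp_amplitude_gain_squares_into_power():
    """Beta amplitude gain 2 -> ~4x power; high-gamma gain 0.5 -> ~0.25x."""
    lfp, events = _lfp_gain_setup(2.0, 0.5, seed=8)
    assert abs(_band_ratio(lfp, events, (15.0, 35.0)) - 4.0) < 0.8
    assert abs(_band_ratio(lfp, events, (66.0, 95.0)) - 0.25) < 0.05


def test_lfp_background_spectrum_has_unit_negative_slope():
    from scipy.signal import welch
    cfg = SimConfig(n_cells_per_mouse=1, beta_rms=0.0, high_gamma_rms=0.0)
    rng = np.random.default_rng(9)
    man = make_manifest(cfg, rng)
    lfp = simulate_lfp(cfg, man, [], np.array([]), 120.0, rng)
    f, p = welch(lfp, fs=1000.0, nperseg=4096)
    sel = (f >= 2.0) & (f <= 100.0)
    slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
    assert abs(slope + 1.0) < 0.25


def test_calcium_without_spikes_or_noise_is_flat_baseline():
    cfg = SimConfig(n_cells_per_mouse=2, ca_noise_sd=0.0)
    man = make_manifest(cfg, np.random.default_rng(10))
    f = simulate_calcium(cfg, man, [np.array([]), np.array([])], 20.0,
                         np.random.default_rng(10))
    np.testing.assert_allclose(f, cfg.ca_offset)


def test_calcium_burst_decays_with_manifest_tau():
    """Log-linear fit on the tail of a synchronous-burst transient recovers
    the decay time constant within 10%."""
    cfg = SimConfig(n_cells_per_mouse=5, ca_noise_sd=0.0)
    man = make_manifest(cfg, np.random.default_rng(11))
    f = simulate_calcium(cfg, man, [np.array([10.0])] * 5, 30.0,
                         np.random.default_rng(11))
    f0 = f[:4000].mean()
    dff = (f - f0) / f0
    t = np.arange(f.size) / 500.0
    sel = (t > 11.0) & (t < 16.0) & (dff > 1e-8)
    slope = np.polyfit(t[sel], np.log(dff[sel]), 1)[0]
    assert abs(-1.0 / slope - cfg.ca_decay_tau) / cfg.ca_decay_tau < 0.10


def test_inhibitory_population_gives_negative_dff():
    cfg = SimConfig(n_cells_per_mouse=4, p_excitatory=0.0, p_inhibitory=1.0,
                    inh_depth_range=(0.9, 0.9), ca_noise_sd=0.0, amp_jitter_sd=0.0,
                    baseline_rate_range=(20.0, 20.0), duration_choices=(2.0,))
    rng = np.random.default_rng(12)
    man = make_manifest(cfg, rng)
    events = [OdorEvent(6.0 + 10.0 * k, 1 + k % 8, 2.0) for k in range(40)]
    units = simulate_spikes(cfg, man, events, np.ones(40), 420.0, rng)
    f = simulate_calcium(cfg, man, units, 420.0, rng)
    dips = []
    for ev in events:
        i = int(ev.onset_time * 500)
        f0 = f[i - 1000: i].mean()
        dips.append((f[i + 250: i + 1000].mean() - f0) / f0)
    assert np.mean(dips) < -0.02


def test_kernel_requires_rise_below_decay():
    with pytest.raises(ValidationError):
        calcium_kernel(1.5, 0.2, 0.002)


def test_config_rejects_bad_mixture_and_trials():
    with pytest.raises(ValidationError):
        SimConfig(p_excitatory=0.7, p_inhibitory=0.5)
    with pytest.raises(ValidationError):
        SimConfig(n_trials=1)
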