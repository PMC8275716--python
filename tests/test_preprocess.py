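import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

from mtsig.io import OdorEvent, ValidationError
from mtsig.preprocess import (bin_firing_rate, compute_dff, downsample_to_bins,
                              normalize_baseline_power, qc_unit, segment_trials,
                              spontaneous_and_evoked_rate, wavelet_band_power)

FS = 500.0


def _events(n, step=10.0, start=6.0):
    return [OdorEvent(start + k * step, 1 + k % 8, 2.0) for k in range(n)]


# ---------------------------------------------------------------- segmentation

def test_segment_counts_and_shape():
    ev = _events(160)
    trace = np.zeros(int((ev[-1].onset_time + 8) * FS))
    seg = segment_trials(trace, FS, ev, pre=2.0, post=6.0)
    assert seg.shape == (160, 4000)     # (2 + 6) s * 500 Hz


def test_segment_zero_pre_starts_at_onset_sample():
    trace = np.arange(int(20 * FS), dtype=float)
    ev = [OdorEvent(10.0, 1, 2.0)]
    seg = segment_trials(trace, FS, ev, pre=0.0, post=2.0)
    assert seg[0, 0] == int(10.0 * FS)


def test_segment_edge_event_raises_and_names_offender():
    trace = np.zeros(int(20 * FS))
    with pytest.raises(ValidationError, match="t=1.00"):
        segment_trials(trace, FS, [OdorEvent(1.0, 1, 2.0)], pre=2.0, post=6.0)


# ------------------------------------------------------------------------ dF/F

def test_dff_of_constant_trace_is_zero():
    seg = np.full((3, 100), 7.5)
    np.testing.assert_array_equal(compute_dff(seg, 40), 0.0)


def test_dff_arithmetic():
    seg = np.concatenate([np.full(40, 2.0), [3.0]])
    assert compute_dff(seg, 40)[-1] == pytest.approx(0.5)


def test_dff_invariant_to_multiplicative_rescaling():
    rng = np.random.default_rng(0)
    seg = 1.0 + 0.1 * rng.standard_normal((4, 200))
    np.testing.assert_allclose(compute_dff(seg, 50), compute_dff(5.3 * seg, 50),
                               atol=1e-12)


def test_dff_rejects_nonpositive_baseline():
    with pytest.raises(ValidationError):
        compute_dff(np.full(100, -1.0), 40)


# ------------------------------------------------------------------ band power

def test_band_power_concentrates_at_the_signal_band():
    t = np.arange(int(12 * 1000)) / 1000.0
    x = np.cos(2 * np.pi * 25.0 * t)
    beta = wavelet_band_power(x, (15.0, 35.0), 1000.0)[3000:9000].mean()
    hg = wavelet_band_power(x, (66.0, 95.0), 1000.0)[3000:9000].mean()
    assert beta / hg > 100


def test_band_power_scales_with_amplitude_squared():
    t = np.arange(int(12 * 1000)) / 1000.0
    x = np.cos(2 * np.pi * 25.0 * t)
    p1 = wavelet_band_power(x, (15.0, 35.0), 1000.0)[3000:9000].mean()
    p2 = wavelet_band_power(2 * x, (15.0, 35.0), 1000.0)[3000:9000].mean()
    assert p2 / p1 == pytest.approx(4.0, rel=0.05)


def test_band_power_matches_hilbert_envelope_oracle():
    """On a stationary mid-band sinusoid the wavelet estimate agrees with the
    bandpass-filter + Hilbert-envelope oracle within 15%."""
    t = np.arange(int(12 * 1000)) / 1000.0
    x = 1.7 * np.cos(2 * np.pi * 25.0 * t)
    wav = wavelet_band_power(x, (15.0, 35.0), 1000.0)[3000:9000].mean()
    sos = butter(4, (15.0, 35.0), btype="bandpass", fs=1000.0, output="sos")
    orc = (np.abs(hilbert(sosfiltfilt(sos, x))) ** 2 / 2)[3000:9000].mean()
    assert wav == pytest.approx(orc, rel=0.15)


def test_band_power_of_white_noise_tracks_bandwidth():
    """Long white-noise run: band power ~ PSD x bandwidth within 25%."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal(int(60 * 1000))
    psd = 1.0 / 1000.0   # one-sided PSD x2 convention: power = 2/fs per Hz... see below
    beta = wavelet_band_power(x, (15.0, 35.0), 1000.0)[5000:-5000].mean()
    theta = wavelet_band_power(x, (2.0, 12.0), 1000.0)[5000:-5000].mean()
    hg = wavelet_band_power(x, (66.0, 95.0), 1000.0)[5000:-5000].mean()
    # absolute: unit-variance noise has 2/fs per Hz one-sided, so 20 Hz -> 0.04
    assert beta == pytest.approx(2 * psd * 20.0, rel=0.25)
    assert hg == pytest.approx(2 * psd * 29.0, rel=0.25)
    # proportionality across bands
    assert beta / theta == pytest.approx(20.0 / 10.0, rel=0.25)


def test_band_power_rejects_band_above_nyquist():
    with pytest.raises(ValidationError, match="Nyquist"):
        wavelet_band_power(np.zeros(1000), (400.0, 600.0), 1000.0)


# --------------------------------------------------------------- normalization

def test_normalized_power_has_unit_baseline_mean():
    rng = np.random.default_rng(2)
    seg = rng.uniform(0.5, 2.0, (6, 400))
    out = normalize_baseline_power(seg, 100)
    np.testing.assert_allclose(out[:, :100].mean(axis=1), 1.0, atol=1e-12)


def test_normalized_power_preserves_odor_to_baseline_ratio():
    seg = np.concatenate([np.full(100, 3.0), np.full(100, 6.0)])
    out = normalize_baseline_power(seg, 100)
    assert out[100:].mean() == pytest.approx(2.0)


def test_normalization_is_scale_invariant():
    rng = np.random.default_rng(3)
    seg = rng.uniform(0.5, 2.0, 300)
    np.testing.assert_allclose(normalize_baseline_power(seg, 100),
                               normalize_baseline_power(10.0 * seg, 100))


# --------------------------------------------------------------------- binning

def test_spike_on_bin_edge_goes_to_right_bin():
    ev = [OdorEvent(2.0, 1, 2.0)]
    tm = bin_firing_rate(np.array([2.05]), ev, pre=2.0, post=6.0, bin_width=0.05)
    i = int(round((2.0 + 0.05) / 0.05))     # bin starting exactly at the spike
    assert tm.values[0, i] == pytest.approx(20.0)
    assert tm.values[0, i - 1] == 0.0


def test_homogeneous_rate_recovered_in_bins():
    rng = np.random.default_rng(4)
    dur = 230.0
    ts = np.sort(rng.uniform(0, dur, rng.poisson(10 * dur)))
    ev = _events(20)
    tm = bin_firing_rate(ts, ev, 2.0, 6.0, 0.05)
    se = np.sqrt(10.0 / (20 * 8.0))
    assert abs(tm.values.mean() - 10.0) < 3 * se


def test_empty_train_gives_zero_matrix():
    tm = bin_firing_rate(np.array([]), _events(5), 2.0, 6.0, 0.05)
    assert (tm.values == 0).all()


def test_spike_count_conserved_between_raw_and_binned():
    rng = np.random.default_rng(5)
    ts = np.sort(rng.uniform(0, 230.0, 2000))
    ev = _events(20)
    tm = bin_firing_rate(ts, ev, 2.0, 6.0, 0.05)
    for i, e in enumerate(ev):
        raw = ((ts >= e.onset_time - 2.0) & (ts < e.onset_time + 6.0)).sum()
        assert tm.values[i].sum() * 0.05 == pytest.approx(raw)


# -------------------------------------------------------- window rates and QC

def test_zero_matrix_has_zero_window_rates():
    tm = bin_firing_rate(np.array([]), _events(4), 2.0, 6.0, 0.05)
    spont, evoked = spontaneous_and_evoked_rate(tm)
    assert (spont == 0).all() and (evoked == 0).all()


def test_window_rates_agree_with_raw_spike_counts():
    rng = np.random.default_rng(6)
    ts = np.sort(rng.uniform(0, 230.0, 3000))
    ev = _events(20)
    tm = bin_firing_rate(ts, ev, 2.0, 6.0, 0.05)
    spont, evoked = spontaneous_and_evoked_rate(tm)
    for i, e in enumerate(ev):
        n_pre = ((ts >= e.onset_time - 2.0) & (ts < e.onset_time)).sum()
        n_post = ((ts >= e.onset_time) & (ts < e.onset_time + 2.0)).sum()
        assert spont[i] == pytest.approx(n_pre / 2.0)
        assert evoked[i] == pytest.approx(n_post / 2.0)


@pytest.mark.parametrize("n_viol, expect_pct, expect_single",
                         [(7, 0.7, True), (8, 0.8, False)])
def test_isi_violation_criterion(n_viol, expect_pct, expect_single):
    """1000 ISIs with n short ones: single unit iff violation % < 0.75."""
    isis = np.full(1000, 0.01)
    isis[:n_viol] = 0.0005
    ts = np.concatenate([[0.0], np.cumsum(isis)])
    q = qc_unit(ts)
    assert q.isi_violation_pct == pytest.approx(expect_pct)
    assert q.is_single_unit is expect_single


def test_qc_single_spike_flagged_low_count():
    q = qc_unit(np.array([1.0]))
    assert q.low_count and q.is_single_unit and q.isi_violation_pct == 0.0


# ---------------------------------------------------------------- downsampling

def test_downsample_constant_is_constant():
    out = downsample_to_bins(np.full(4000, 3.3), FS, 0.05)
    np.testing.assert_allclose(out, 3.3)
    assert out.size == 160                      # 8 s / 0.05 s


def test_downsample_linear_ramp_hits_bin_centers():
    x = np.arange(4000, dtype=float)
    out = downsample_to_bins(x, FS, 0.05)
    per = 25
    centers = per * np.arange(160) + (per - 1) / 2.0
    np.testing.assert_allclose(out, centers, atol=1e-9)


def test_downsample_rejects_non_commensurate_bin():
    with pytest.raises(ValidationError):
        downsample_to_bins(np.zeros(1000), 500.0, 0.0513)
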