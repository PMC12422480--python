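"""Band-limiting and the 26+5 acoustic parameters on constructed signals."""

import numpy as np
import pytest
from scipy.signal import periodogram

from callrep.features import (
    FeatureConfig,
    SilentClipError,
    TooShortError,
    bandpass,
    build_feature_table,
    dominant_contour,
    extract_spectral_params,
    FEATURE_COLUMNS,
    SPECTRAL_COLUMNS,
)
from callrep.synthetic import CallArchetype, CallRecording, synthesize_call

SR = 44100
CFG = FeatureConfig()


def _tone(freq, dur=0.5, call_id="tone"):
    t = np.arange(int(dur * SR)) / SR
    return CallRecording(call_id, 0.5 * np.sin(2 * np.pi * freq * t), SR)


def _sweep(f0, f1, dur=1.0):
    t = np.arange(int(dur * SR)) / SR
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * dur))
    return CallRecording("sweep", 0.5 * np.sin(phase), SR)


def _band_power(x, lo, hi):
    f, p = periodogram(x, SR)
    m = (f >= lo) & (f <= hi)
    return p[m].sum()


def test_stopband_tone_attenuated_40db():
    rec = _tone(100)
    out = bandpass(rec, CFG)
    before = _band_power(rec.waveform, 50, 150)
    after = _band_power(out.waveform, 50, 150)
    assert 10 * np.log10(before / after) >= 40


def test_passband_tone_preserved_within_1db():
    rec = _tone(1000)
    out = bandpass(rec, CFG)
    ratio = np.sqrt(np.mean(out.waveform**2) / np.mean(rec.waveform**2))
    assert abs(20 * np.log10(ratio)) < 1.0


def test_bandpass_white_noise_matches_fft_mask_oracle(rng):
    x = rng.standard_normal(SR)
    rec = CallRecording("wn", x, SR)
    out = bandpass(rec, CFG)
    # oracle: ideal FFT brick-wall mask
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1 / SR)
    X[(f < CFG.highpass) | (f > CFG.lowpass)] = 0
    oracle = np.fft.irfft(X, len(x))
    # compare over the interior passband, away from the Butterworth shoulders
    inband = _band_power(out.waveform, 400, 3200)
    inband_oracle = _band_power(oracle, 400, 3200)
    assert inband == pytest.approx(inband_oracle, rel=0.05)
    out_ratio = _band_power(out.waveform, 0, 150) / inband
    assert out_ratio < 2e-3


def test_bandpass_rejects_lowpass_at_nyquist():
    rec = CallRecording("x", np.zeros(1000) + 0.1, 8000)
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(rec, FeatureConfig(lowpass=4000.0))


def test_stationary_tone_parameters():
    p = extract_spectral_params(bandpass(_tone(1000, 0.5)), CFG)
    assert p["duration"] == pytest.approx(0.5, abs=0.01)
    assert p["peakf"] == pytest.approx(1.0, abs=0.1)  # kHz
    assert p["dfrange"] == pytest.approx(0.0, abs=0.1)
    assert p["modindx"] <= 2.0
    assert p["sfm"] < 0.3  # a line spectrum is far from flat


def test_linear_sweep_dominant_trajectory():
    p = extract_spectral_params(bandpass(_sweep(500, 1500, 1.0)), CFG)
    bin_khz = SR / CFG.window_length / 1000  # one FFT bin
    assert p["startdom"] == pytest.approx(0.5, abs=2 * bin_khz)
    assert p["enddom"] == pytest.approx(1.5, abs=2 * bin_khz)
    assert p["dfslope"] == pytest.approx(1.0, abs=0.15)
    assert p["mindom"] < p["maxdom"]


def test_inband_noise_is_flat_and_entropic(rng):
    x = rng.standard_normal(SR // 2)
    rec = bandpass(CallRecording("n", x, SR), CFG)
    p = extract_spectral_params(rec, CFG)
    assert p["sfm"] > 0.5
    assert p["sp_ent"] > 0.9


def test_all_frequency_features_inside_band(small_table):
    freq_cols = [
        "meanfreq", "freq_median", "freq_q25", "freq_q75",
        "peakf", "meanpeakf", "meandom", "mindom", "maxdom", "startdom", "enddom",
    ]
    lo, hi = CFG.highpass / 1000, CFG.lowpass / 1000
    for c in freq_cols:
        v = small_table[c]
        assert (v >= lo - 1e-9).all() and (v <= hi + 1e-9).all(), c


def test_too_short_clip_error_carries_call_id():
    rec = CallRecording("shorty", np.ones(100) * 0.1, SR)
    with pytest.raises(TooShortError, match="shorty"):
        extract_spectral_params(rec, CFG)


def test_silent_clip_error():
    rec = CallRecording("quiet", np.zeros(SR // 2), SR)
    with pytest.raises(SilentClipError, match="quiet"):
        dominant_contour(rec, CFG)


def test_dominant_contour_of_tone_is_constant():
    c = dominant_contour(bandpass(_tone(1000)), CFG)
    assert len(c) == CFG.contour_points
    assert np.allclose(c, 1000, atol=90)  # within one FFT bin


def test_dominant_contour_of_arch_call_rises_then_falls():
    arch = CallArchetype("arch", 600, 1800, "arch", 0.5, 0.0, 1.0, 1)
    rec = bandpass(synthesize_call(arch, jitter_seed=1, snr_db=None), CFG)
    c = dominant_contour(rec, CFG)
    mid = len(c) // 2
    assert np.argmax(c) in range(mid - 4, mid + 5)
    assert c[mid] > c[0] + 300 and c[mid] > c[-1] + 300


def test_contour_determinism():
    rec = bandpass(_tone(700), CFG)
    assert np.array_equal(dominant_contour(rec, CFG), dominant_contour(rec, CFG))


def test_feature_table_contract(small_table):
    feature_cols = [c for c in small_table.columns if c not in ("call_id", "original_label")]
    assert len(feature_cols) == 31
    assert feature_cols == FEATURE_COLUMNS
    assert len(SPECTRAL_COLUMNS) == 26
    assert not small_table[feature_cols].isna().any().any()


def test_identical_clips_identical_rows():
    rec = _tone(900, 0.4)
    a = rec
    b = CallRecording("tone2", rec.waveform.copy(), SR)
    tab = build_feature_table(
        [a, b, _tone(2000, 0.3, "t3")], FeatureConfig(mds_dims=2)
    )
    ra = tab[tab.call_id == "tone"][SPECTRAL_COLUMNS].to_numpy()
    rb = tab[tab.call_id == "tone2"][SPECTRAL_COLUMNS].to_numpy()
    assert np.allclose(ra, rb)


def test_permuting_input_order_permutes_rows(small_dataset):
    recs, _ = small_dataset
    recs = recs[:12]
    tab1 = build_feature_table(recs).set_index("call_id").sort_index()
    perm = [recs[i] for i in np.random.default_rng(1).permutation(len(recs))]
    tab2 = build_feature_table(perm).set_index("call_id").sort_index()
    assert np.allclose(
        tab1[SPECTRAL_COLUMNS].to_numpy(), tab2[SPECTRAL_COLUMNS].to_numpy()
    )
    # MDS coordinates identical after the sign convention
    mds = [c for c in tab1.columns if c.startswith("dtw_mds")]
    assert np.allclose(tab1[mds].to_numpy(), tab2[mds].to_numpy(), atol=1e-8)


def test_extraction_failure_lists_call_ids(small_dataset):
    recs, _ = small_dataset
    bad = CallRecording("bad_clip", np.ones(50) * 0.1, SR)
    with pytest.raises(ValueError, match="bad_clip"):
        build_feature_table(recs[:3] + [bad])
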