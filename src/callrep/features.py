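"""Per-call acoustic feature construction.

Each call clip is band-limited (default 200–4000 Hz, rejecting low-frequency
rumble and high-frequency insect noise) and summarized as 31 features:

* 26 spectral/temporal parameters of the kind bioacoustic packages such as
  warbleR extract per call — duration, energy-distribution statistics of the
  band-limited spectrum, entropies, flatness, peak- and dominant-frequency
  descriptors, and temporal energy quartiles;
* 5 coordinates from classical MDS of a pairwise dynamic-time-warping
  distance matrix over the calls' dominant-frequency contours, capturing
  contour *shape* similarity that frame-wise statistics miss.

Frequencies are reported in kHz, times in seconds.  Extraction is fully
deterministic: identical samples give identical feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .dtw import pairwise_dtw
from .mds import mds_embed
from .synthetic import CallRecording

__all__ = [
    "FeatureConfig",
    "SPECTRAL_COLUMNS",
    "MDS_COLUMNS",
    "FEATURE_COLUMNS",
    "bandpass",
    "extract_spectral_params",
    "dominant_contour",
    "build_feature_table",
    "feature_matrix",
    "TooShortError",
    "SilentClipError",
]


class TooShortError(ValueError):
    """Clip shorter than two analysis windows."""

    def __init__(self, call_id: str, n_samples: int):
        self.call_id = call_id
        super().__init__(f"call {call_id}: too short for analysis ({n_samples} samples)")


class SilentClipError(ValueError):
    """All frames below the dominant-contour noise floor."""

    def __init__(self, call_id: str):
        self.call_id = call_id
        super().__init__(f"call {call_id}: silent clip, no frames above noise floor")


@dataclass(frozen=True)
class FeatureConfig:
    highpass: float = 200.0  # Hz
    lowpass: float = 4000.0  # Hz
    window_length: int = 512  # samples
    overlap: float = 0.5  # fraction of window
    contour_points: int = 20
    mds_dims: int = 5
    noise_floor_db: float = -60.0  # frames below this (re clip peak frame) dropped

    def __post_init__(self) -> None:
        if not self.highpass < self.lowpass:
            raise ValueError("highpass must be below lowpass")
        if self.mds_dims < 1:
            raise ValueError("mds_dims must be >= 1")
        if self.contour_points < 2:
            raise ValueError("contour_points must be >= 2")


SPECTRAL_COLUMNS = [
    "duration",
    "meanfreq", "sd", "freq_median", "freq_q25", "freq_q75", "freq_iqr",
    "skew", "kurt",
    "sp_ent", "time_ent", "entropy", "sfm",
    "peakf", "meanpeakf",
    "meandom", "mindom", "maxdom", "dfrange", "startdom", "enddom",
    "dfslope", "modindx",
    "time_q25", "time_median", "time_q75",
]
MDS_COLUMNS = ["dtw_mds1", "dtw_mds2", "dtw_mds3", "dtw_mds4", "dtw_mds5"]
FEATURE_COLUMNS = SPECTRAL_COLUMNS + MDS_COLUMNS

assert len(SPECTRAL_COLUMNS) == 26 and len(FEATURE_COLUMNS) == 31


def bandpass(recording: CallRecording, cfg: FeatureConfig = FeatureConfig()) -> CallRecording:
    """Band-limit a clip to [highpass, lowpass]; stop-band rejection > 40 dB."""
    nyq = recording.sample_rate / 2
    if cfg.lowpass >= nyq:
        raise ValueError(
            f"lowpass {cfg.lowpass} Hz must be below Nyquist {nyq} Hz"
        )
    sos = signal.butter(
        5, [cfg.highpass / nyq, cfg.lowpass / nyq], btype="band", output="sos"
    )
    n = len(recording.waveform)
    pad = min(n - 1, 200)
    y = signal.sosfiltfilt(sos, recording.waveform, padlen=pad)
    return replace(recording, waveform=y)


def _stft(recording: CallRecording, cfg: FeatureConfig):
    """Hann-window power spectrogram restricted to the analysis band.

    Returns (freqs_hz, times_s, power) with freqs already masked to
    [highpass, lowpass].
    """
    hop = max(int(cfg.window_length * (1.0 - cfg.overlap)), 1)
    if len(recording.waveform) < cfg.window_length + hop:
        raise TooShortError(recording.call_id, len(recording.waveform))
    f, t, S = signal.spectrogram(
        recording.waveform,
        fs=recording.sample_rate,
        window="hann",
        nperseg=cfg.window_length,
        noverlap=cfg.window_length - hop,
        mode="psd",
    )
    band = (f >= cfg.highpass) & (f <= cfg.lowpass)
    return f[band], t, S[band, :]


def _dominant_track(recording: CallRecording, cfg: FeatureConfig):
    """Per-frame argmax frequency (Hz) over frames above the noise floor."""
    f, t, S = _stft(recording, cfg)
    frame_energy = S.sum(axis=0)
    peak = frame_energy.max()
    if peak <= 0:
        raise SilentClipError(recording.call_id)
    keep = frame_energy >= peak * 10 ** (cfg.noise_floor_db / 10)
    if not keep.any():
        raise SilentClipError(recording.call_id)
    dom = f[np.argmax(S[:, keep], axis=0)]
    return t[keep], dom


def dominant_contour(
    recording: CallRecording, cfg: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Dominant-frequency contour (Hz) resampled to ``contour_points``.

    The per-frame peak-frequency track is linearly time-normalized to a
    fixed number of equally spaced points so that contours of calls with
    different durations are comparable under DTW.
    """
    t, dom = _dominant_track(recording, cfg)
    if len(t) == 1:
        return np.full(cfg.contour_points, dom[0])
    tq = np.linspace(t[0], t[-1], cfg.contour_points)
    return np.interp(tq, t, dom)


def _weighted_moments(freq_khz: np.ndarray, p: np.ndarray):
    mu = float(np.sum(p * freq_khz))
    var = float(np.sum(p * (freq_khz - mu) ** 2))
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.sum(p * (freq_khz - mu) ** 3) / sd**3)
        kurt = float(np.sum(p * (freq_khz - mu) ** 4) / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    return mu, sd, skew, kurt


def _quantile_from_cdf(x: np.ndarray, w: np.ndarray, q: float) -> float:
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, x))


def extract_spectral_params(
    recording: CallRecording, cfg: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """The 26 spectral/temporal parameters of one (band-limited) call.

    All frequency-valued outputs are in kHz and constrained to the analysis
    band; times are in seconds.
    """
    f, t, S = _stft(recording, cfg)
    fk = f / 1000.0

    spec = S.mean(axis=1)
    tot = spec.sum()
    if tot <= 0:
        raise SilentClipError(recording.call_id)
    p = spec / tot

    meanfreq, sd, skew, kurt = _weighted_moments(fk, p)
    q25 = _quantile_from_cdf(fk, p, 0.25)
    q50 = _quantile_from_cdf(fk, p, 0.50)
    q75 = _quantile_from_cdf(fk, p, 0.75)

    nz = p[p > 0]
    sp_ent = float(-(nz * np.log(nz)).sum() / np.log(len(p))) if len(p) > 1 else 0.0

    frame_energy = S.sum(axis=0)
    pe = frame_energy / frame_energy.sum()
    nze = pe[pe > 0]
    time_ent = float(-(nze * np.log(nze)).sum() / np.log(len(pe))) if len(pe) > 1 else 0.0

    # spectral flatness: geometric/arithmetic mean of the band spectrum
    eps = np.finfo(float).tiny
    sfm = float(np.exp(np.mean(np.log(spec + eps))) / np.mean(spec + eps))

    peakf = float(fk[np.argmax(spec)])
    tk, dom_hz = _dominant_track(recording, cfg)
    dom = dom_hz / 1000.0
    meanpeakf = float(np.mean(dom))

    duration = recording.duration
    dfrange = float(dom.max() - dom.min())
    if len(dom) > 1 and dfrange > 0:
        modindx = float(np.sum(np.abs(np.diff(dom))) / dfrange)
    else:
        modindx = 0.0
    dfslope = float((dom[-1] - dom[0]) / duration)

    tq25 = _quantile_from_cdf(t, frame_energy, 0.25)
    tq50 = _quantile_from_cdf(t, frame_energy, 0.50)
    tq75 = _quantile_from_cdf(t, frame_energy, 0.75)

    return {
        "duration": float(duration),
        "meanfreq": meanfreq,
        "sd": sd,
        "freq_median": q50,
        "freq_q25": q25,
        "freq_q75": q75,
        "freq_iqr": q75 - q25,
        "skew": skew,
        "kurt": kurt,
        "sp_ent": sp_ent,
        "time_ent": time_ent,
        "entropy": sp_ent * time_ent,
        "sfm": sfm,
        "peakf": peakf,
        "meanpeakf": meanpeakf,
        "meandom": float(np.mean(dom)),
        "mindom": float(dom.min()),
        "maxdom": float(dom.max()),
        "dfrange": dfrange,
        "startdom": float(dom[0]),
        "enddom": float(dom[-1]),
        "dfslope": dfslope,
        "modindx": modindx,
        "time_q25": tq25,
        "time_median": tq50,
        "time_q75": tq75,
    }


def build_feature_table(
    recordings: list[CallRecording], cfg: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Full feature table: call_id, original_label, 26 spectral + 5 MDS columns.

    Per-call extraction failures are collected and re-raised together with
    the offending call_ids; a row is never silently dropped.
    """
    if len(recordings) < 2:
        raise ValueError("need at least 2 recordings to build a feature table")
    rows: list[dict] = []
    contours: list[np.ndarray] = []
    failures: list[str] = []
    for rec in recordings:
        try:
            bp = bandpass(rec, cfg)
            params = extract_spectral_params(bp, cfg)
            contours.append(dominant_contour(bp, cfg) / 1000.0)  # kHz for DTW
        except (TooShortError, SilentClipError) as e:
            failures.append(f"{rec.call_id}: {e}")
            continue
        rows.append({"call_id": rec.call_id, "original_label": rec.original_label, **params})
    if failures:
        raise ValueError(
            "feature extraction failed for %d call(s):\n%s"
            % (len(failures), "\n".join(failures))
        )
    D = pairwise_dtw(contours)
    X = mds_embed(D, cfg.mds_dims)
    table = pd.DataFrame(rows)
    mds_cols = [f"dtw_mds{k + 1}" for k in range(cfg.mds_dims)]
    for k, col in enumerate(mds_cols):
        table[col] = X[:, k]
    return table[["call_id", "original_label"] + SPECTRAL_COLUMNS + mds_cols]


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) view of a feature table for classifiers."""
    cols = [c for c in table.columns if c not in ("call_id", "original_label")]
    X = table[cols].to_numpy(dtype=np.float64)
    y = table["original_label"].to_numpy()
    return X, y
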