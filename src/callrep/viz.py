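"""Visual summaries: t-SNE call-space maps and per-call spectrograms.

The t-SNE embedding gives a 2-D picture of how calls cluster in the
31-dimensional acoustic feature space (features standardized first); it is
descriptive only and never feeds back into classification or merging.
Spectrograms use a Hann window with a -30 dB display floor and short silent
margins, the usual presentation for call-type catalogues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .features import FeatureConfig, bandpass, extract_spectral_params, feature_matrix
from .synthetic import CallRecording

__all__ = ["VizConfig", "tsne_embed", "plot_tsne", "render_spectrogram"]


@dataclass(frozen=True)
class VizConfig:
    tsne_perplexity: float = 30.0
    tsne_seed: int = 0
    spectro_window: str = "hanning"
    spectro_floor_db: float = -30.0
    margin_s: float = 0.05


def tsne_embed(table: pd.DataFrame, cfg: VizConfig = VizConfig()) -> np.ndarray:
    """2-D t-SNE coordinates of the standardized feature table.

    Deterministic under a fixed ``tsne_seed``.  Requires at least
    ``3 * perplexity`` calls; the error message suggests a workable
    perplexity otherwise.
    """
    X, _ = feature_matrix(table)
    n = X.shape[0]
    if n < 3 * cfg.tsne_perplexity:
        raise ValueError(
            f"{n} calls is too few for perplexity {cfg.tsne_perplexity}; "
            f"try perplexity <= {max(n // 3, 2)}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    ts = TSNE(
        n_components=2,
        perplexity=cfg.tsne_perplexity,
        random_state=cfg.tsne_seed,
        init="pca",
    )
    return ts.fit_transform(Z)


def plot_tsne(
    table: pd.DataFrame, coords: np.ndarray, path: str | Path, label_col: str = "original_label"
) -> Path:
    """Scatter of the embedding, one color per call type."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in sorted(table[label_col].unique()):
        m = (table[label_col] == lab).to_numpy()
        ax.scatter(coords[m, 0], coords[m, 1], s=12, label=lab, alpha=0.75)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=7, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_spectrogram(
    recording: CallRecording,
    cfg: VizConfig = VizConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
    path: str | Path | None = None,
) -> dict:
    """Spectrogram figure plus the descriptive stats catalogues print.

    Returns duration and peak/dominant/mean frequency taken from the same
    feature extractor the classifier uses, so figure captions and feature
    tables can never disagree.
    """
    params = extract_spectral_params(bandpass(recording, feature_cfg), feature_cfg)
    stats = {
        "call_id": recording.call_id,
        "duration_s": params["duration"],
        "peak_khz": params["peakf"],
        "dominant_khz": params["meandom"],
        "mean_khz": params["meanfreq"],
    }
    if path is not None:
        # margins carry a -160 dB floor so log-power display stays finite
        margin = np.full(int(cfg.margin_s * recording.sample_rate), 1e-8)
        x = np.concatenate([margin, recording.waveform, margin])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        _, _, _, im = ax.specgram(
            x,
            NFFT=512,
            Fs=recording.sample_rate,
            noverlap=256,
            window=np.hanning(512),
            cmap="magma",
        )
        # display floor relative to the loudest pixel: quieter pixels blank
        vmax = im.get_clim()[1]
        im.set_clim(vmax + cfg.spectro_floor_db, vmax)
        ax.set_ylim(0, feature_cfg.lowpass * 1.25)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(recording.call_id, fontsize=9)
        fig.colorbar(im, ax=ax, label="dB")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        stats["figure"] = str(path)
    return stats
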