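"""Classical vibration imaging: per-pixel amplitude and dominant-frequency maps.

Involuntary head–neck micro-movements (the vestibulo-emotional reflex
signal) modulate pixel intensities of a fixed camera.  Two hand-crafted
maps summarise them:

* the **amplitude map** ``A(x, y)`` — the mean absolute deviation of each
  pixel's intensity from its within-window mean,

  ``A(x,y) = (1/N) Σ_i |U_{x,y,i} − Ū_{x,y}|``

* the **frequency map** ``F(x, y)`` — the dominant in-band frequency of
  each pixel's intensity time series ``s_{x,y}(t)``, estimated as the
  argmax of the magnitude of its short-time Fourier transform within the
  physiologically relevant band B (default 0.1–10 Hz).

Regional statistics (mean, variance, histogram entropy) and spectral
features (low-frequency energy ratio, normalised spectral entropy) turn
the maps into scalar features; cases are expected to show increased
low-frequency energy and reduced signal complexity relative to controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

from .video import VideoCube

DEFAULT_BAND = (0.1, 10.0)

__all__ = [
    "AmplitudeMap",
    "FrequencyMap",
    "compute_amplitude_map",
    "compute_frequency_map",
    "region_statistics",
    "spectral_features",
    "VibrationFeatureExtractor",
    "DEFAULT_BAND",
]


@dataclass
class AmplitudeMap:
    """H×W map of mean-absolute-deviation amplitudes; all entries >= 0."""

    values: np.ndarray
    window_length: int


@dataclass
class FrequencyMap:
    """H×W map of dominant frequencies in Hz.

    Pixels with no in-band spectral power (e.g. constant series) carry
    the NaN sentinel; every defined entry lies inside ``band``.
    """

    values: np.ndarray
    band: tuple[float, float]

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of pixels with a defined dominant frequency."""
        return ~np.isnan(self.values)


def compute_amplitude_map(video: VideoCube, window: int | None = None) -> AmplitudeMap:
    """Mean absolute deviation of pixel intensities within time windows.

    When the cube is longer than one window, maps from consecutive
    non-overlapping windows are averaged; a trailing partial window is
    dropped.

    Parameters
    ----------
    video : VideoCube
    window : int, optional
        Window length N in frames; defaults to the cube's window_length.
    """
    n = int(window) if window is not None else video.window_length
    if n < 2:
        raise ValueError(f"window must be >= 2 frames, got {n}")
    t = video.n_frames
    if n > t:
        raise ValueError(f"window ({n}) exceeds the number of frames ({t})")
    n_win = t // n
    x = video.frames[: n_win * n].reshape(n_win, n, *video.frames.shape[1:])
    mean = x.mean(axis=1, keepdims=True)
    mad = np.abs(x - mean).mean(axis=1)  # per-window A(x,y)
    return AmplitudeMap(values=mad.mean(axis=0), window_length=n)


def compute_frequency_map(
    video: VideoCube,
    band: tuple[float, float] = DEFAULT_BAND,
    stft_window: int | None = None,
    stft_overlap: float = 0.5,
) -> FrequencyMap:
    """Per-pixel dominant frequency via the short-time Fourier transform.

    Each pixel's series is analysed with a Hann-windowed STFT; segment
    magnitudes are averaged and the argmax is taken over the frequency
    band ``(f_lo, f_hi)``.  The DC bin is never a candidate.  Ties break
    toward the lowest frequency.  Pixels whose in-band power is zero get
    the NaN sentinel.

    Parameters
    ----------
    band : (float, float)
        In-band limits in Hz; must lie inside (0, frame_rate / 2).
    stft_window : int, optional
        Segment length in frames; default is 4 s of video (capped at T),
        which gives 0.25 Hz native resolution at typical rates.
    stft_overlap : float
        Fractional overlap of consecutive segments, in [0, 1).
    """
    f_lo, f_hi = band
    nyq = video.frame_rate / 2.0
    if not (0 < f_lo < f_hi):
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi, got {band}")
    if f_hi >= nyq:
        raise ValueError(f"band upper edge {f_hi} Hz must be below Nyquist ({nyq} Hz)")
    if not (0 <= stft_overlap < 1):
        raise ValueError(f"stft_overlap must be in [0, 1), got {stft_overlap}")
    t, h, w = video.shape
    if stft_window is None:
        stft_window = min(t, int(round(4 * video.frame_rate)))
    stft_window = int(stft_window)
    if stft_window > t:
        raise ValueError(f"stft_window ({stft_window}) exceeds T ({t})")
    if stft_window < 2:
        raise ValueError("stft_window must be >= 2 frames")

    hop = max(1, int(round(stft_window * (1 - stft_overlap))))
    window_fn = hann(stft_window, sym=False)
    series = video.frames.reshape(t, h * w).T  # (P, T)
    # mean-removal per pixel: the DC bin is excluded anyway, but detrending
    # keeps spectral leakage from a large baseline out of the low bins
    series = series - series.mean(axis=1, keepdims=True)
    # Hann-windowed segments fully inside the signal, hopped by `hop`
    segs = np.lib.stride_tricks.sliding_window_view(
        series, stft_window, axis=-1)[:, ::hop]  # (P, S, win)
    spec = np.abs(np.fft.rfft(segs * window_fn, axis=-1))  # (P, S, F)
    mag = spec.mean(axis=1)  # average magnitude across STFT segments
    freqs = np.fft.rfftfreq(stft_window, d=1.0 / video.frame_rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not in_band.any():
        raise ValueError(
            f"band {band} Hz contains no STFT bins at resolution "
            f"{freqs[1] - freqs[0]:.4g} Hz; lengthen stft_window"
        )
    band_freqs = freqs[in_band]
    band_mag = mag[:, in_band]
    idx = band_mag.argmax(axis=1)  # np.argmax ties break to the first = lowest f
    dominant = band_freqs[idx]
    dominant[band_mag.sum(axis=1) <= 0] = np.nan
    return FrequencyMap(values=dominant.reshape(h, w), band=(f_lo, f_hi))


def region_statistics(
    map_values: AmplitudeMap | FrequencyMap | np.ndarray,
    region: np.ndarray | None = None,
    n_bins: int = 16,
) -> dict[str, float]:
    """Mean, variance and histogram entropy of a map over a pixel region.

    Entropy is the Shannon entropy in bits of the ``n_bins`` equal-width
    histogram of the masked, defined (non-NaN) values; empty bins
    contribute zero.  A constant region therefore has entropy 0.

    Returns a dict with keys ``mean``, ``variance``, ``entropy``, ``n``.
    """
    values = map_values.values if hasattr(map_values, "values") else np.asarray(map_values)
    if region is None:
        region = np.ones(values.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != values.shape:
        raise ValueError(f"region shape {region.shape} != map shape {values.shape}")
    if not region.any():
        raise ValueError("region mask selects no pixels")
    sel = values[region]
    sel = sel[~np.isnan(sel)]
    if sel.size == 0:
        raise ValueError("all pixels in the region are undefined")
    counts, _ = np.histogram(sel, bins=n_bins)
    p = counts[counts > 0] / sel.size
    return {
        "mean": float(sel.mean()),
        "variance": float(sel.var()),
        "entropy": float(abs((p * np.log2(p)).sum())),
        "n": int(sel.size),
    }


def spectral_features(
    series: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    low_cut: float = 1.0,
) -> dict[str, float]:
    """Low-frequency energy ratio and normalised spectral entropy of a series.

    ``low_freq_energy_ratio`` is the fraction of in-band periodogram power
    below ``low_cut``; ``spectral_entropy`` is the Shannon entropy of the
    in-band power distribution normalised to [0, 1] (0 = a single tone,
    1 = a flat spectrum).

    Raises if the series has zero in-band power.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    f_lo, f_hi = band
    if not (f_lo < low_cut <= f_hi):
        raise ValueError(f"low_cut {low_cut} must lie inside band {band}")
    freqs, pxx = periodogram(series - series.mean(), fs=frame_rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    p = pxx[in_band]
    total = p.sum()
    if total <= 0:
        raise ValueError("series has zero power in the analysis band")
    low = p[freqs[in_band] < low_cut].sum()
    q = p[p > 0] / total
    if q.size > 1:
        ent = float(-(q * np.log2(q)).sum() / np.log2(p.size))
    else:
        ent = 0.0
    return {
        "low_freq_energy_ratio": float(low / total),
        "spectral_entropy": ent,
    }


class VibrationFeatureExtractor(BaseEstimator, TransformerMixin):
    """Turn video cubes into classical vibration-imaging feature rows.

    A stateless transformer (``fit`` only validates parameters) producing,
    per video: amplitude-map and frequency-map region statistics plus
    spectral features of the region-mean intensity series.  Composes with
    sklearn pipelines as the hand-crafted-feature baseline to the learned
    CNN–BiLSTM scorer.

    Parameters
    ----------
    band : (float, float), default (0.1, 10.0)
        Analysis band in Hz.
    low_cut : float, default 1.0
        Boundary for the low-frequency energy ratio, Hz.
    window : int, optional
        Amplitude-map window N in frames (default: each cube's own).
    n_bins : int, default 16
        Histogram bins for map entropies.
    region : ndarray of bool, optional
        Pixel mask applied to every cube (default: full frame).
    """

    def __init__(self, band=DEFAULT_BAND, low_cut=1.0, window=None, n_bins=16,
                 region=None):
        self.band = band
        self.low_cut = low_cut
        self.window = window
        self.n_bins = n_bins
        self.region = region

    feature_names = (
        "amp_mean", "amp_variance", "amp_entropy",
        "freq_mean", "freq_variance", "freq_entropy",
        "low_freq_energy_ratio", "spectral_entropy",
    )

    def fit(self, X, y=None):
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi):
            raise ValueError(f"invalid band {self.band}")
        self.n_features_out_ = len(self.feature_names)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of VideoCube. Returns one feature row per video."""
        rows = []
        for cube in X:
            amp = compute_amplitude_map(cube, self.window)
            freq = compute_frequency_map(cube, band=self.band)
            a_stats = region_statistics(amp, self.region, self.n_bins)
            f_stats = region_statistics(freq, self.region, self.n_bins)
            mask = self.region if self.region is not None else np.ones(
                cube.frames.shape[1:], dtype=bool)
            mean_series = cube.frames[:, mask].mean(axis=1)
            spec = spectral_features(mean_series, cube.frame_rate,
                                     band=self.band, low_cut=self.low_cut)
            rows.append({
                "amp_mean": a_stats["mean"],
                "amp_variance": a_stats["variance"],
                "amp_entropy": a_stats["entropy"],
                "freq_mean": f_stats["mean"],
                "freq_variance": f_stats["variance"],
                "freq_entropy": f_stats["entropy"],
                **spec,
            })
        return pd.DataFrame(rows, columns=list(self.feature_names))
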