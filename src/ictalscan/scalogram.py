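"""Epoch segmentation and continuous-wavelet-transform scalograms.

Continuous records are cut into contiguous, non-overlapping 10 s epochs
(half-open ``[start, start + 10)``; a 0.5 h interval yields exactly 180).
Each epoch is mapped to a scalogram: the magnitude of an analytic Morlet
CWT evaluated on a logarithmic frequency grid spanning 1–100 Hz, rendered
to a fixed-size RGB image for visual inspection and classifier input.

The CWT is computed in the frequency domain: the epoch is FFT'd once and
multiplied by a bank of Gaussian kernels (one per centre frequency, each
``n_cycles`` wide, zero on negative frequencies), then inverse-transformed
row-wise.  Kernel banks are cached per ``(n_samples, fs, grid)`` so that
classifying months of EEG costs one FFT plus one batched inverse FFT per
epoch.  Kernels are L∞-normalized so a unit-amplitude sinusoid at a grid
frequency produces a row magnitude of ~1 regardless of frequency.
Cone-of-influence edge regions are retained, not masked: at 10 s epochs
the low-frequency distortion is unavoidable and the classifier sees it
identically in training and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from matplotlib import colormaps
from scipy import fft as sfft
from scipy import signal as sp_signal
from skimage.transform import resize

from .synthetic import EEGRecord

__all__ = [
    "Epoch",
    "Scalogram",
    "MorletCWT",
    "FeatureConfig",
    "segment_record",
    "cwt_scalogram",
    "render_scalogram",
    "magnitude_to_index",
    "epoch_features",
]

logger = logging.getLogger(__name__)

EPOCH_S = 10.0


@dataclass(frozen=True)
class Epoch:
    """One 10 s analysis segment, addressed by (subject, interval, epoch)."""

    subject_id: str
    interval_index: int
    epoch_index: int
    samples: np.ndarray
    start_s: float              # absolute seconds since implant
    fs: float = 500.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.samples.size / self.fs


@dataclass
class Scalogram:
    """|CWT| magnitudes over a 1–100 Hz grid for one epoch."""

    magnitudes: np.ndarray      # (n_freqs, n_times), >= 0
    freqs_hz: np.ndarray
    fs: float
    image: np.ndarray | None = None


def segment_record(record: EEGRecord, interval_index: int = 0,
                   epoch_s: float = EPOCH_S) -> list[Epoch]:
    """Cut a record into contiguous non-overlapping ``epoch_s`` epochs.

    The epoch count is ``floor(duration / epoch_s)``; a trailing remainder
    is dropped (and logged).  Records shorter than one epoch yield an
    empty list with a warning.
    """
    n_per = int(round(epoch_s * record.fs))
    n_epochs = record.samples.size // n_per
    if n_epochs == 0:
        logger.warning("record %s shorter than one %.0f s epoch (%.1f s); "
                       "no epochs produced", record.subject_id, epoch_s,
                       record.duration_s)
        return []
    dropped = record.samples.size - n_epochs * n_per
    if dropped:
        logger.info("record %s: dropping %.1f s trailing remainder",
                    record.subject_id, dropped / record.fs)
    return [
        Epoch(record.subject_id, interval_index, k,
              record.samples[k * n_per:(k + 1) * n_per],
              start_s=record.start_s + k * epoch_s, fs=record.fs)
        for k in range(n_epochs)
    ]


class MorletCWT:
    """Frequency-domain analytic Morlet CWT for fixed-length inputs.

    Parameters
    ----------
    n_samples, fs : input geometry.
    freqs_hz : centre-frequency grid (Hz).
    n_cycles : wavelet width; the Gaussian frequency kernel at centre f has
        standard deviation ``f / n_cycles`` (constant-Q), i.e. ~``n_cycles``
        oscillation cycles under the time envelope.
    """

    def __init__(self, n_samples: int, fs: float, freqs_hz: np.ndarray,
                 n_cycles: float = 7.0):
        self.n_samples = int(n_samples)
        self.fs = float(fs)
        self.freqs_hz = np.asarray(freqs_hz, dtype=float)
        self.n_cycles = float(n_cycles)
        # zero-pad for linear (non-circular) convolution semantics
        self.nfft = sfft.next_fast_len(int(self.n_samples * 1.5))
        w = np.fft.fftfreq(self.nfft, 1.0 / self.fs)
        K = np.empty((self.freqs_hz.size, self.nfft), dtype=np.float32)
        for i, f in enumerate(self.freqs_hz):
            sf = f / self.n_cycles
            K[i] = np.exp(-0.5 * ((w - f) / sf) ** 2)
            K[i, w < 0] = 0.0
        self._kernels = K

    def magnitudes(self, x: np.ndarray) -> np.ndarray:
        """|CWT| matrix (n_freqs, n_samples) of a real signal."""
        if x.size != self.n_samples:
            raise ValueError(
                f"expected {self.n_samples} samples, got {x.size}")
        X = sfft.fft(np.asarray(x, dtype=np.float64), self.nfft)
        W = sfft.ifft(X[None, :] * self._kernels, axis=1)
        return np.abs(W[:, : self.n_samples])


@lru_cache(maxsize=8)
def _cached_transform(n_samples: int, fs: float, n_freqs: int,
                      fmin: float, fmax: float, n_cycles: float) -> MorletCWT:
    freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
    return MorletCWT(n_samples, fs, freqs, n_cycles)


def cwt_scalogram(epoch: Epoch, n_freqs: int = 96,
                  fmin: float = 1.0, fmax: float = 100.0,
                  n_cycles: float = 7.0) -> Scalogram:
    """Scalogram of one epoch over a log frequency grid in [fmin, fmax] Hz."""
    if not np.all(np.isfinite(epoch.samples)):
        raise ValueError(
            f"non-finite samples in epoch ({epoch.subject_id}, "
            f"interval {epoch.interval_index}, epoch {epoch.epoch_index})")
    tf = _cached_transform(epoch.samples.size, epoch.fs, n_freqs,
                           fmin, fmax, n_cycles)
    return Scalogram(tf.magnitudes(epoch.samples), tf.freqs_hz.copy(),
                     fs=epoch.fs)


def magnitude_to_index(magnitudes: np.ndarray,
                       scaling: str = "log",
                       vmax: float | None = None,
                       beta: float = 100.0) -> np.ndarray:
    """Monotone map from magnitude to colormap index in [0, 1].

    Magnitudes are first normalized by the per-image maximum (``vmax=None``,
    the default) or a fixed ``vmax``, then optionally compressed with a
    logarithmic curve of dynamic range ``beta`` — so under per-image
    normalization the index is invariant to rescaling the input.  A
    constant zero matrix maps to a uniform zero index.
    """
    m = np.asarray(magnitudes, dtype=np.float64)
    top = float(vmax) if vmax is not None else float(m.max())
    if top <= 0:
        return np.zeros_like(m)
    r = np.clip(m / top, 0.0, 1.0)
    if scaling == "log":
        return np.log1p(beta * r) / np.log1p(beta)
    if scaling == "linear":
        return r
    raise ValueError(f"unknown scaling {scaling!r}")


def render_scalogram(scalogram: Scalogram, height: int = 224,
                     width: int = 224, colormap: str = "viridis",
                     scaling: str = "log",
                     vmax: float | None = None) -> np.ndarray:
    """Render a scalogram to a fixed-size uint8 RGB image.

    Low frequencies are drawn at the bottom.  The magnitude→color mapping
    is monotone and, by default, normalized per image (so doubling all
    magnitudes leaves the image unchanged).
    """
    idx = magnitude_to_index(scalogram.magnitudes, scaling=scaling, vmax=vmax)
    idx = resize(idx[::-1], (height, width), order=1, mode="edge",
                 anti_aliasing=True, preserve_range=True)
    rgba = colormaps[colormap](np.clip(idx, 0.0, 1.0))
    img = (rgba[..., :3] * 255).astype(np.uint8)
    scalogram.image = img
    return img


# --------------------------------------------------------------------------
# classifier feature path
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Reduced-resolution scalogram grid fed to the classifier.

    The detector consumes the same |CWT| representation as the rendered
    images, at a coarser grid (48 log-spaced frequencies, 40 time bins,
    signal decimated 2×) so that month-scale EEG classifies quickly.
    Unlike the per-image-normalized rendering, classifier features keep a
    *fixed* magnitude scale (``vmax_uv``): absolute amplitude is part of
    the ictal signature (onset spiking exceeds twice the background), so
    suppressed, background and spiking epochs must not be renormalized
    onto each other.
    """

    n_freqs: int = 48
    fmin: float = 1.0
    fmax: float = 100.0
    n_cycles: float = 7.0
    decimate: int = 2
    time_bins: int = 40
    #: fixed magnitude ceiling (µV) for the log compression.
    vmax_uv: float = 1000.0

    @property
    def n_features(self) -> int:
        return self.n_freqs * self.time_bins


def epoch_features(epoch: Epoch, cfg: FeatureConfig = FeatureConfig()
                   ) -> np.ndarray:
    """Flattened log-magnitude scalogram features on a fixed µV scale."""
    x = epoch.samples
    fs = epoch.fs
    if cfg.decimate > 1:
        x = sp_signal.decimate(np.asarray(x, dtype=np.float64),
                               cfg.decimate, zero_phase=True)
        fs = fs / cfg.decimate
    tf = _cached_transform(x.size, fs, cfg.n_freqs, cfg.fmin, cfg.fmax,
                           cfg.n_cycles)
    mag = tf.magnitudes(x)
    # mean-pool the time axis into cfg.time_bins bins
    nt = mag.shape[1] - mag.shape[1] % cfg.time_bins
    pooled = mag[:, :nt].reshape(cfg.n_freqs, cfg.time_bins, -1).mean(axis=2)
    idx = magnitude_to_index(pooled, scaling="log", vmax=cfg.vmax_uv)
    return idx.astype(np.float32).ravel()
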