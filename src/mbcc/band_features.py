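"""Band-limited power spectral density features from raw multichannel epochs.

EEG rhythms are conventionally split into five frequency bands (delta
1-3 Hz through gamma 30-100 Hz). For each epoch and band this module
computes one band-power value per channel: the integral of the Welch PSD
estimate over the band. An epoch set therefore becomes a multi-band dataset
with ``d = n_channels`` features per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_model import MultiBandDataset, remap_labels


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: half-open passband ``[low, high]`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name}: need 0 < low < high, "
                f"got ({self.low}, {self.high})")


@dataclass
class EpochSet:
    """Raw signal epochs (channels x samples each) at a common rate."""

    epochs: list[np.ndarray]
    rate: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.epochs = [np.atleast_2d(np.asarray(e, dtype=float))
                       for e in self.epochs]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.epochs) == 0:
            raise ValueError("no epochs")
        nch = self.epochs[0].shape[0]
        for i, e in enumerate(self.epochs):
            if e.shape[0] != nch:
                raise ValueError(
                    f"epoch {i} has {e.shape[0]} channels, expected {nch}")
        if self.labels.size != len(self.epochs):
            raise ValueError("label/epoch count mismatch")

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0]


def default_bands() -> list[BandSpec]:
    """The five standard EEG rhythm bands, ordered by lower edge."""
    return [
        BandSpec("delta", 1.0, 3.0),
        BandSpec("theta", 4.0, 7.0),
        BandSpec("alpha", 8.0, 13.0),
        BandSpec("beta", 14.0, 30.0),
        BandSpec("gamma", 30.0, 100.0),
    ]


def bandpass(x: np.ndarray, band: BandSpec, rate: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D signal.

    Forward-backward filtering (``sosfiltfilt``) keeps the operation linear
    and phase-free; the effective attenuation is the squared magnitude
    response of the designed filter.
    """
    nyq = rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz is at or above "
            f"the Nyquist frequency {nyq} Hz")
    sos = sps.butter(order, [band.low, band.high], btype="bandpass",
                     fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def welch_psd_features(epoch: np.ndarray, band: BandSpec, rate: float,
                       window_s: float = 1.0,
                       overlap: float = 0.5) -> np.ndarray:
    """Per-channel band power: Welch PSD integrated over ``[low, high]``.

    Hann window of ``window_s`` seconds with fractional ``overlap``;
    integration by the trapezoidal rule over the in-band frequency grid.
    Returns a nonnegative vector of length ``n_channels``.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(window_s * rate))
    if epoch.shape[1] < nperseg:
        raise ValueError(
            f"epoch has {epoch.shape[1]} samples but one window needs "
            f"{nperseg}; use a smaller window_s")
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(epoch, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=noverlap, axis=1)
    mask = (freqs >= band.low) & (freqs <= band.high)
    if mask.sum() < 2:
        # Band narrower than the frequency resolution: fall back to the
        # single nearest bin scaled by the band width.
        k = np.argmin(np.abs(freqs - 0.5 * (band.low + band.high)))
        return psd[:, k] * (band.high - band.low)
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def slice_epochs(signal: np.ndarray, rate: float, window_s: float,
                 step_s: float | None = None) -> list[np.ndarray]:
    """Cut a continuous recording (channels x samples) into fixed windows.

    ``step_s`` < ``window_s`` gives overlapping epochs (e.g. 4 s windows
    every 2 s); default is non-overlapping.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    win = int(round(window_s * rate))
    step = int(round((step_s if step_s is not None else window_s) * rate))
    if win < 1 or step < 1:
        raise ValueError("window and step must span at least one sample")
    starts = range(0, signal.shape[1] - win + 1, step)
    return [signal[:, s:s + win] for s in starts]


def extract_multiband(epochs: EpochSet, bands: list[BandSpec] | None = None,
                      window_s: float = 1.0, overlap: float = 0.5,
                      log_power: bool = False) -> MultiBandDataset:
    """Epochs -> multi-band dataset of per-channel band powers.

    Band ``m``, column ``j`` is the band-power vector of epoch ``j`` in band
    ``m``; labels are carried through (remapped to 1..C). ``log_power``
    applies ``log(1 + x)`` to stabilize the heavy-tailed power scale.
    """
    if bands is None:
        bands = default_bands()
    nyq = epochs.rate / 2.0
    for b in bands:
        if b.high > nyq:
            raise ValueError(
                f"band {b.name} upper edge {b.high} Hz exceeds Nyquist "
                f"{nyq} Hz of the data")
    Z = []
    for band in bands:
        cols = [welch_psd_features(e, band, epochs.rate, window_s, overlap)
                for e in epochs.epochs]
        mat = np.column_stack(cols)
        if log_power:
            mat = np.log1p(mat)
        Z.append(mat)
    labels, original = remap_labels(epochs.labels)
    return MultiBandDataset(band_names=[b.name for b in bands], Z=Z,
                            labels=labels, original_labels=original)
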