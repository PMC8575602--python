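"""Band-limited, baseline-corrected, downsampled per-trial epochs.

A continuous recording is turned into analysis-ready epochs in a fixed order:
broadband (1-45 Hz) filtering of the continuous signal, anti-aliased
decimation to the processing rate, narrow-band filtering, segmentation around
stimulus onsets, and per-channel baseline correction against the pre-stimulus
fixation interval.

All filters are odd-length linear-phase FIR (Hamming window) applied with
center alignment, i.e. exactly zero-phase: downstream phase-locking estimates
depend on undistorted instantaneous phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import EEGRecording, Marker

#: Canonical EEG frequency bands (Hz).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "whole": (1.0, 45.0),
}


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


def get_band(name: str) -> BandSpec:
    """Look up one of the canonical bands by name."""
    try:
        low, high = CANONICAL_BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; choose from {sorted(CANONICAL_BANDS)}"
        ) from None
    return BandSpec(name, low, high)


@dataclass
class EpochSet:
    """Per-trial, per-band segments with condition labels.

    ``data`` has shape (n_trials, n_channels, n_samples); ``window`` is the
    epoch extent in seconds relative to stimulus onset.
    """

    data: np.ndarray
    fs: float
    condition_labels: list[str]
    window: tuple[float, float]
    band: BandSpec | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.condition_labels) != self.n_trials:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def design_bandpass(band: BandSpec, fs: float,
                    transition_frac: float = 0.25) -> np.ndarray:
    """Odd-length Hamming-window FIR band-pass kernel.

    The transition width is ``transition_frac`` of the lower band edge on
    both sides, the classical ``3.3 / (delta_f / fs)`` Hamming tap-count rule.
    """
    width = transition_frac * band.low
    numtaps = int(np.ceil(3.3 * fs / width))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [band.low, band.high], window="hamming",
                         pass_zero=False, fs=fs)


def bandpass(recording: EEGRecording, band: BandSpec,
             transition_frac: float = 0.25) -> EEGRecording:
    """Zero-phase band-pass of every channel; markers and length unchanged."""
    nyq = recording.fs / 2
    if not 0 < band.low < band.high < nyq:
        raise ValueError(
            f"band {band.low}-{band.high} Hz outside (0, {nyq}) Hz at "
            f"fs={recording.fs}"
        )
    h = design_bandpass(band, recording.fs, transition_frac)
    # symmetric odd-length kernel + 'same' alignment == zero phase
    out = signal.fftconvolve(recording.data, h[None, :], mode="same", axes=1)
    return recording.with_data(out)


def downsample(recording: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased integer-factor decimation; marker indices rescaled."""
    factor = recording.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs {recording.fs} not an integer multiple of target {target_fs}"
        )
    q = int(round(factor))
    if q == 1:
        return recording.with_data(recording.data.copy())
    out = signal.decimate(recording.data, q, axis=1, ftype="fir",
                          zero_phase=True)
    markers = [Marker(m.sample // q, m.condition, m.event)
               for m in recording.markers]
    return EEGRecording(out, target_fs, list(recording.channel_labels), markers)


def segment_epochs(recording: EEGRecording,
                   window: tuple[float, float] = (0.0, 2.0),
                   baseline: tuple[float, float] | None = (-1.0, 0.0),
                   band: BandSpec | None = None) -> EpochSet:
    """Cut per-trial epochs around each onset marker and baseline-correct.

    ``window`` and ``baseline`` are (start_s, end_s) relative to onset with
    half-open sample intervals [start, end). The default baseline is the 1 s
    pre-stimulus fixation; pass ``baseline=None`` to skip correction.
    """
    fs = recording.fs
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    if w1 <= w0:
        raise ValueError("epoch window must have positive length")
    epochs, labels = [], []
    for i, m in enumerate(recording.markers):
        lo, hi = m.sample + w0, m.sample + w1
        if lo < 0 or hi > recording.n_samples:
            raise ValueError(
                f"trial {i} ({m.condition} onset at sample {m.sample}): window "
                f"[{lo}, {hi}) exceeds recording bounds [0, {recording.n_samples})"
            )
        ep = recording.data[:, lo:hi].copy()
        if baseline is not None:
            b0 = m.sample + int(round(baseline[0] * fs))
            b1 = m.sample + int(round(baseline[1] * fs))
            if b0 < 0 or b1 > recording.n_samples or b1 <= b0:
                raise ValueError(
                    f"trial {i}: baseline [{b0}, {b1}) exceeds recording bounds"
                )
            ep -= recording.data[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(ep)
        labels.append(m.condition)
    if not epochs:
        raise ValueError("recording has no onset markers")
    return EpochSet(np.stack(epochs), fs, labels, window, band=band,
                    channel_labels=list(recording.channel_labels))


def preprocess_session(recording: EEGRecording, band: BandSpec | str,
                       target_fs: float = 250.0,
                       window: tuple[float, float] = (0.0, 2.0),
                       baseline: tuple[float, float] | None = (-1.0, 0.0),
                       ) -> EpochSet:
    """Full preprocessing chain for one band.

    Broadband 1-45 Hz filter on the continuous signal, decimation to
    ``target_fs``, narrow-band filter (skipped when ``band`` is the broadband
    itself), segmentation, baseline correction.
    """
    if isinstance(band, str):
        band = get_band(band)
    whole = get_band("whole")
    rec = bandpass(recording, whole)
    rec = downsample(rec, target_fs)
    if (band.low, band.high) != (whole.low, whole.high):
        rec = bandpass(rec, band)
    return segment_epochs(rec, window=window, baseline=baseline, band=band)
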