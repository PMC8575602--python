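"""Continuous multichannel EEG recordings with event markers.

The central in-memory container shared by the simulator, the readers and the
preprocessing stage: a channels x samples array, its sampling rate, channel
labels and a list of stimulus-onset markers labelled by condition (``GST``
for the ordered Gestalt images, ``RSD`` for the random sequence diagrams).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("GST", "RSD")

#: 10-20 labels used when a recording has exactly 19 channels.
LABELS_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


def default_channel_labels(n_channels: int) -> list[str]:
    """Standard 10-20 names for 19 channels, generic ``EEG###`` otherwise."""
    if n_channels == 19:
        return list(LABELS_1020_19)
    return [f"EEG{i + 1:03d}" for i in range(n_channels)]


@dataclass(frozen=True)
class Marker:
    """A stimulus-onset event: sample index and condition label."""

    sample: int
    condition: str
    event: str = "onset"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class EEGRecording:
    """Continuous multichannel signal with stimulus markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-like arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel.
    markers : list of Marker
        Stimulus onsets, strictly increasing sample indices in
        ``[0, n_samples)``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = default_channel_labels(self.n_channels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        last = -1
        for m in self.markers:
            if not (0 <= m.sample < self.n_samples):
                raise ValueError(f"marker sample {m.sample} outside recording")
            if m.sample <= last:
                raise ValueError("marker sample indices must be strictly increasing")
            last = m.sample

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of the recording with ``data`` replaced (markers kept)."""
        return replace(self, data=data, markers=list(self.markers),
                       channel_labels=list(self.channel_labels))
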