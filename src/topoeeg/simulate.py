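"""Seeded synthetic EEG sessions with condition-dependent phase coherence.

The generator emulates a two-condition visual stimulation protocol: a block
of random-sequence-diagram (RSD) trials followed by a block of Gestalt (GST)
trials, each trial being 1 s fixation + 10 s stimulus + 1 s rest at a 1 kHz
acquisition rate. What distinguishes the conditions statistically is
inter-channel phase coherence, the quantity the downstream analysis is built
around: during GST stimuli a designated channel cluster locks tightly to a
common phase process on top of weak diffuse background coupling, while during
RSD stimuli all channels share only the weak diffuse coupling.

Each channel during a stimulus is an amplitude-modulated band-limited
oscillator

    x_i(t) = g_i (1 + m sin(2 pi f_mod t + psi)) cos(2 pi f_c t + theta_i(t))
             + noise,

where the instantaneous phase deviation ``theta_i`` is a convex mixture of a
shared and a private random-walk (Wiener) phase process,

    theta_i = w_i * phi_shared + (1 - w_i) * phi_i,

with mixing weight ``w_i`` equal to ``coupling_gst`` for cluster channels in
GST trials and ``coupling_rsd`` otherwise. The pairwise phase-locking value
is then a monotone function of the mixing weights, which makes the coupling
parameters direct, tunable controls of the coherence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import BandSpec, get_band
from .recording import CONDITIONS, EEGRecording, Marker, default_channel_labels


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic recording session.

    The defaults are the study conditions: 19 channels (10-20-like layout),
    1 kHz acquisition, 30 RSD trials followed by 10 GST trials, each trial
    1 s fixation + 10 s stimulus + 1 s rest, alpha-band carrier.

    ``coupling_gst``/``coupling_rsd`` are the phase-mixture weights in [0, 1]
    (0 = independent phases, 1 = perfect locking); ``cluster_channels`` is the
    coherent assembly recruited in GST trials (default: the 8 posterior
    channels). ``phase_drift`` is the standard deviation of the per-sample
    Wiener phase increments in radians and sets how fast uncoupled channels
    decohere.
    """

    n_channels: int = 19
    fs_acquire: float = 1000.0
    n_rsd_trials: int = 30
    n_gst_trials: int = 10
    fixation_s: float = 1.0
    stimulus_s: float = 10.0
    rest_s: float = 1.0
    carrier_band: BandSpec = field(default_factory=lambda: get_band("alpha"))
    coupling_gst: float = 0.85
    coupling_rsd: float = 0.25
    cluster_channels: tuple[int, ...] | None = None
    noise_sd: float = 1.0
    osc_amplitude: float = 2.0
    mod_depth: float = 0.5
    mod_freq: float = 0.3
    phase_drift: float = 0.15
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs_acquire <= 0:
            raise ValueError("fs_acquire must be positive")
        if min(self.fixation_s, self.stimulus_s, self.rest_s) <= 0:
            raise ValueError("all trial segment durations must be positive")
        if self.n_rsd_trials < 0 or self.n_gst_trials < 0:
            raise ValueError("trial counts must be non-negative")
        if not 0 <= self.coupling_rsd <= self.coupling_gst <= 1:
            raise ValueError(
                "couplings must satisfy 0 <= coupling_rsd <= coupling_gst <= 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_channels is None:
            k = min(8, self.n_channels)
            object.__setattr__(
                self, "cluster_channels",
                tuple(range(self.n_channels - k, self.n_channels)),
            )
        else:
            object.__setattr__(
                self, "cluster_channels",
                tuple(int(c) for c in self.cluster_channels),
            )
        bad = [c for c in self.cluster_channels
               if not 0 <= c < self.n_channels]
        if bad:
            raise ValueError(f"cluster channels {bad} outside 0..{self.n_channels - 1}")

    @property
    def trial_s(self) -> float:
        return self.fixation_s + self.stimulus_s + self.rest_s

    @property
    def n_trials(self) -> int:
        return self.n_rsd_trials + self.n_gst_trials

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carrier_band"] = {"name": self.carrier_band.name,
                             "low": self.carrier_band.low,
                             "high": self.carrier_band.high}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        band = d.get("carrier_band")
        if isinstance(band, dict):
            d["carrier_band"] = BandSpec(band["name"], band["low"], band["high"])
        elif isinstance(band, str):
            d["carrier_band"] = get_band(band)
        if isinstance(d.get("cluster_channels"), list):
            d["cluster_channels"] = tuple(d["cluster_channels"])
        return cls(**d)


def trial_rng(config: SessionConfig, trial_index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one trial.

    Streams are keyed by (session seed, trial index), so any trial can be
    regenerated without generating the ones before it.
    """
    return np.random.default_rng([config.seed, trial_index])


def _noise(config: SessionConfig, rng: np.random.Generator,
           n: int) -> np.ndarray:
    w = rng.standard_normal((config.n_channels, n))
    if config.pink_noise and n > 1:
        # 1/f amplitude shaping via rFFT, variance renormalized
        spec = np.fft.rfft(w, axis=1)
        f = np.fft.rfftfreq(n, d=1.0 / config.fs_acquire)
        f[0] = f[1]
        spec /= np.sqrt(f)
        w = np.fft.irfft(spec, n=n, axis=1)
        w *= 1.0 / w.std(axis=1, keepdims=True)
    return config.noise_sd * w


def generate_trial(config: SessionConfig, condition: str,
                   rng: np.random.Generator) -> np.ndarray:
    """One stimulus segment, shape (n_channels, stimulus_s * fs_acquire).

    GST: cluster channels mix the shared phase with weight ``coupling_gst``,
    the remaining channels with the background weight ``coupling_rsd``.
    RSD: every channel mixes with weight ``coupling_rsd``.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"condition must be one of {CONDITIONS}, got {condition!r}"
        )
    m = config.n_channels
    n = int(round(config.stimulus_s * config.fs_acquire))
    t = np.arange(n) / config.fs_acquire

    # fixed draw order: envelope phase, gains, shared walk, private walks, noise
    psi = rng.uniform(0, 2 * np.pi)
    gains = rng.uniform(0.8, 1.2, size=m)
    phi_shared = np.cumsum(rng.normal(0.0, config.phase_drift, size=n))
    phi_priv = np.cumsum(rng.normal(0.0, config.phase_drift, size=(m, n)),
                         axis=1)

    w = np.full(m, config.coupling_rsd)
    if condition == "GST":
        w[list(config.cluster_channels)] = config.coupling_gst
    theta = w[:, None] * phi_shared[None, :] + (1.0 - w[:, None]) * phi_priv

    f_c = config.carrier_band.center
    envelope = 1.0 + config.mod_depth * np.sin(2 * np.pi * config.mod_freq * t + psi)
    x = gains[:, None] * envelope[None, :] * np.cos(2 * np.pi * f_c * t + theta)
    x += _noise(config, rng, n)
    return x


def generate_session(config: SessionConfig) -> EEGRecording:
    """A full recording: RSD trials then GST trials, markers at each onset."""
    fs = config.fs_acquire
    n_fix = int(round(config.fixation_s * fs))
    n_stim = int(round(config.stimulus_s * fs))
    n_rest = int(round(config.rest_s * fs))
    n_trial = n_fix + n_stim + n_rest

    conditions = ["RSD"] * config.n_rsd_trials + ["GST"] * config.n_gst_trials
    data = np.empty((config.n_channels, n_trial * len(conditions)))
    markers = []
    for i, cond in enumerate(conditions):
        rng = trial_rng(config, i)
        off = i * n_trial
        data[:, off:off + n_fix] = _noise(config, rng, n_fix)
        data[:, off + n_fix:off + n_fix + n_stim] = generate_trial(
            config, cond, rng)
        data[:, off + n_fix + n_stim:off + n_trial] = _noise(config, rng, n_rest)
        markers.append(Marker(off + n_fix, cond))
    return EEGRecording(data, fs, default_channel_labels(config.n_channels),
                        markers)
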