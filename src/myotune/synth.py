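"""Synthetic surface-EMG session generator.

Emulates the acquisition protocol of an 8-channel, 200 Hz consumer armband
recording: each repetition is a fixed-length contraction followed by rest,
repeated for every gesture class.  During a contraction each channel carries
band-limited Gaussian noise (the EMG-like carrier) scaled by a class- and
channel-specific activation amplitude and a trapezoidal onset/offset
envelope; sensor noise is present throughout, and a 50 Hz powerline tone can
be injected.  Class separability is controlled by how far apart the
per-class activation patterns lie.

Units are arbitrary (mV-scale); no attempt is made to model electrode
calibration, motor-unit physiology, electrode shift or fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, ConsistencyError

#: Sentinel label for rest (relaxation) samples; class ids are 0..n_classes-1.
REST: int = -1


@dataclass(frozen=True)
class GestureProtocol:
    """Acquisition schedule: gestures, repetitions and timing."""

    n_classes: int = 10
    n_reps: int = 10
    contraction_s: float = 6.0
    rest_s: float = 4.0
    fs: float = 200.0
    n_channels: int = 8

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_reps < 1 or self.n_channels < 1:
            raise ConfigError("n_classes, n_reps and n_channels must be >= 1")
        if self.contraction_s <= 0:
            raise ConfigError("contraction_s must be > 0")
        if self.rest_s < 0:
            raise ConfigError("rest_s must be >= 0")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")

    @property
    def contraction_samples(self) -> int:
        return int(round(self.contraction_s * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_s * self.fs))

    @property
    def n_samples(self) -> int:
        """Total session length: classes x reps x (contraction + rest) x fs."""
        per_rep = self.contraction_samples + self.rest_samples
        return self.n_classes * self.n_reps * per_rep


@dataclass(frozen=True)
class SubjectModel:
    """Stand-in for one subject's muscle activity.

    ``activation[k, c]`` is the RMS amplitude of the EMG-like carrier on
    channel ``c`` during contractions of class ``k``; the pattern over
    channels is what makes classes separable.
    """

    activation: np.ndarray
    carrier_band: tuple[float, float] = (20.0, 95.0)
    sensor_noise_rms: float = 0.05
    powerline_amp: float = 0.0
    powerline_hz: float = 50.0
    envelope_rise_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        object.__setattr__(self, "activation", act)
        if act.ndim != 2:
            raise ConfigError("activation must be a n_classes x n_channels matrix")
        if np.any(act < 0):
            raise ConfigError("activation must be elementwise >= 0")
        low, high = self.carrier_band
        if not (0 < low < high):
            raise ConfigError("carrier band must satisfy 0 < low < high")
        if self.sensor_noise_rms < 0 or self.powerline_amp < 0:
            raise ConfigError("noise amplitudes must be >= 0")

    @property
    def n_classes(self) -> int:
        return self.activation.shape[0]

    @property
    def n_channels(self) -> int:
        return self.activation.shape[1]


@dataclass
class RecordingSession:
    """Labelled multichannel sEMG time series for one subject."""

    signal: np.ndarray  # n_channels x n_samples
    labels: np.ndarray  # n_samples, values in {REST, 0..n_classes-1}
    fs: float
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signal.ndim != 2:
            raise ConsistencyError("signal must be n_channels x n_samples")
        if self.labels.shape != (self.signal.shape[1],):
            raise ConsistencyError(
                f"labels length {self.labels.shape} does not match "
                f"sample count {self.signal.shape[1]}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ConsistencyError("signal contains non-finite values")
        if self.fs <= 0:
            raise ConsistencyError("fs must be > 0")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy(self) -> "RecordingSession":
        return RecordingSession(
            self.signal.copy(), self.labels.copy(), self.fs, self.subject_id
        )


def make_subject_model(
    protocol: GestureProtocol,
    separability: float,
    seed: int,
    *,
    base_amplitude: float = 1.0,
    sensor_noise_rms: float = 0.05,
    powerline_amp: float = 0.0,
) -> SubjectModel:
    """Draw a subject whose class patterns are ``separability`` apart.

    Per-class activation rows are ``base * (1 + separability * d[k, c])``
    with ``d`` drawn once from U(-0.75, 0.75) given ``seed``, so pairwise
    row distances grow linearly in ``separability`` and vanish at 0.
    """
    if not 0.0 <= separability <= 1.0:
        raise ConfigError(f"separability must be in [0, 1], got {separability}")
    rng = np.random.default_rng(seed)
    d = rng.uniform(-0.75, 0.75, size=(protocol.n_classes, protocol.n_channels))
    activation = base_amplitude * (1.0 + separability * d)
    high = min(95.0, 0.95 * protocol.fs / 2.0)
    return SubjectModel(
        activation=activation,
        carrier_band=(20.0, high),
        sensor_noise_rms=sensor_noise_rms,
        powerline_amp=powerline_amp,
        seed=seed,
    )


def _trapezoid_envelope(n: int, rise_samples: int) -> np.ndarray:
    """Trapezoidal contraction envelope: linear rise, plateau, linear fall."""
    env = np.ones(n)
    r = min(rise_samples, n // 2)
    if r > 0:
        ramp = np.linspace(0.0, 1.0, r, endpoint=False)
        env[:r] = ramp
        env[n - r:] = ramp[::-1]
    return env


def _contraction_order(
    protocol: GestureProtocol, randomize: bool, rng: np.random.Generator
) -> list[int]:
    """Sequence of class ids, one per repetition (grouped by class unless randomised)."""
    order = [k for k in range(protocol.n_classes) for _ in range(protocol.n_reps)]
    if randomize:
        order = [order[i] for i in rng.permutation(len(order))]
    return order


def synthesize_session(
    model: SubjectModel,
    protocol: GestureProtocol,
    seed: int,
    *,
    subject_id: str = "synthetic",
    randomize_order: bool = False,
) -> RecordingSession:
    """Render one labelled session following the protocol schedule.

    Each repetition is ``contraction_s`` of class-labelled activity followed
    by ``rest_s`` of rest.  The carrier is white Gaussian noise band-passed
    to ``model.carrier_band`` and normalised to unit RMS per contraction, so
    the contraction RMS on channel ``c`` equals ``activation[class, c]``
    (times the envelope).  Sensor noise and the powerline tone are additive
    over the whole session.  Bitwise deterministic given ``seed``.
    """
    if model.n_channels != protocol.n_channels:
        raise ConsistencyError(
            f"model has {model.n_channels} channels, protocol {protocol.n_channels}"
        )
    if model.n_classes != protocol.n_classes:
        raise ConsistencyError(
            f"model has {model.n_classes} classes, protocol {protocol.n_classes}"
        )
    low, high = model.carrier_band
    if high >= protocol.fs / 2.0:
        raise ConfigError("carrier band upper edge must be below Nyquist")

    rng = np.random.default_rng(seed)
    n_c = protocol.contraction_samples
    n_r = protocol.rest_samples
    n_total = protocol.n_samples
    n_ch = protocol.n_channels

    sig = np.zeros((n_ch, n_total))
    labels = np.full(n_total, REST, dtype=int)

    sos = sps.butter(4, [low, high], btype="bandpass", fs=protocol.fs, output="sos")
    env = _trapezoid_envelope(n_c, int(round(model.envelope_rise_s * protocol.fs)))

    pos = 0
    for klass in _contraction_order(protocol, randomize_order, rng):
        white = rng.standard_normal((n_ch, n_c))
        carrier = sps.sosfilt(sos, white, axis=1)
        std = carrier.std(axis=1, keepdims=True)
        std[std == 0.0] = 1.0
        carrier /= std
        sig[:, pos : pos + n_c] = (
            model.activation[klass][:, None] * env[None, :] * carrier
        )
        labels[pos : pos + n_c] = klass
        pos += n_c + n_r

    if model.sensor_noise_rms > 0:
        sig += rng.normal(0.0, model.sensor_noise_rms, size=sig.shape)
    if model.powerline_amp > 0:
        t = np.arange(n_total) / protocol.fs
        sig += model.powerline_amp * np.sin(2 * np.pi * model.powerline_hz * t)

    return RecordingSession(sig, labels, protocol.fs, subject_id)


def inject_powerline(
    session: RecordingSession, amplitude: float, f0: float = 50.0
) -> RecordingSession:
    """Add ``amplitude * sin(2*pi*f0*t)`` to every channel; labels unchanged."""
    if not 0 < f0 < session.fs / 2.0:
        raise ConfigError(
            f"powerline frequency {f0} Hz would alias at fs={session.fs} Hz"
        )
    out = session.copy()
    if amplitude != 0.0:
        t = np.arange(session.n_samples) / session.fs
        out.signal = out.signal + amplitude * np.sin(2 * np.pi * f0 * t)[None, :]
    return out
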