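"""Synthetic surface-EMG session generation.

Produces seeded, protocol-structured multi-channel sEMG recordings that
mimic a four-channel bipolar forearm setup: signals amplified (gain 1500),
band-pass filtered 10-500 Hz and sampled at 2048 Hz.  Muscle activity is
modelled as coloured Gaussian noise whose power spectral density follows
the classic parametric surface-EMG shape

    S(f) = f^2 * fh^4 / ((f^2 + fl^2) * (f^2 + fh^2)^2)

with corner frequencies ``fl`` and ``fh``.  With the defaults fl = 60 Hz,
fh = 120 Hz the spectrum peaks near 100 Hz and decays to negligible power
above 500 Hz, matching typical forearm sEMG spectra.  Each gesture
repetition scales the coloured noise on each channel by a per-gesture,
per-channel activation amplitude, with raised-cosine on/off ramps;
baseline instrumentation noise is present throughout.

The generator is not a motor-unit-level physiological model: it captures
amplitude patterns and the broad spectral shape, not crosstalk,
electrode-skin impedance or firing statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "AcquisitionConfig",
    "GestureProtocol",
    "MusclePattern",
    "EmgSession",
    "OFFLINE_GESTURES",
    "ONLINE_GESTURES",
    "ELECTRODE_TYPES",
    "ELECTRODE_SNR_SCALE",
    "offline_protocol",
    "online_protocol",
    "default_pattern",
    "shape_noise",
    "generate_session",
    "write_session",
    "read_session",
]

#: Offline gesture set: eight active gestures plus rest.
OFFLINE_GESTURES: tuple[str, ...] = (
    "closed_hand",
    "open_hand",
    "wrist_extension",
    "wrist_flexion",
    "chuck_grip",
    "index_point",
    "supination",
    "pronation",
    "rest",
)

#: Online (cursor-control) gesture set: the four motion gestures plus rest.
ONLINE_GESTURES: tuple[str, ...] = (
    "closed_hand",
    "open_hand",
    "wrist_extension",
    "wrist_flexion",
    "rest",
)

ELECTRODE_TYPES = ("gel", "fabric")

#: Fabric (embroidered textile) electrodes are modelled as gel electrodes
#: with a reduced signal-to-noise ratio.
ELECTRODE_SNR_SCALE = {"gel": 1.0, "fabric": 0.8}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition-chain parameters of the simulated amplifier."""

    sampling_rate: float = 2048.0
    band_low: float = 10.0
    band_high: float = 500.0
    gain: float = 1500.0
    n_channels: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.sampling_rate / 2):
            raise ValueError(
                "require 0 < band_low < band_high < Nyquist, got "
                f"[{self.band_low}, {self.band_high}] at {self.sampling_rate} Hz"
            )
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass(frozen=True)
class GestureProtocol:
    """Timing structure of a recording session.

    Each repetition consists of a countdown (preparation), the gesture held
    for ``gesture_duration`` seconds, then a rest period before the next
    repetition.
    """

    gesture_labels: tuple[str, ...] = OFFLINE_GESTURES
    reps_per_gesture: int = 4
    gesture_duration: float = 6.0
    countdown: float = 3.0
    rest_between: float = 6.0

    def __post_init__(self) -> None:
        if len(set(self.gesture_labels)) != len(self.gesture_labels):
            raise ValueError("gesture labels must be unique")
        if self.reps_per_gesture < 1:
            raise ValueError("reps_per_gesture must be >= 1")
        for name in ("gesture_duration", "countdown", "rest_between"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_gestures(self) -> int:
        return len(self.gesture_labels)


def offline_protocol() -> GestureProtocol:
    """Nine gestures, four repetitions each."""
    return GestureProtocol(gesture_labels=OFFLINE_GESTURES, reps_per_gesture=4)


def online_protocol() -> GestureProtocol:
    """Five cursor-control classes, three repetitions each."""
    return GestureProtocol(gesture_labels=ONLINE_GESTURES, reps_per_gesture=3)


#: Per-gesture activation amplitudes for the four channels, ordered
#: (extensor_1, extensor_2, flexor_1, flexor_2).  Extensor-pair dominant
#: for extension/open, flexor-pair for flexion/close, mixed patterns for
#: grips and rotations; rest is silent.  Values are partially overlapping
#: so the classes are separable but not trivially so.
ACTIVATION_TEMPLATE: dict[str, tuple[float, float, float, float]] = {
    "closed_hand": (0.20, 0.30, 1.00, 0.90),
    "open_hand": (1.00, 0.90, 0.20, 0.30),
    "wrist_extension": (0.90, 1.10, 0.10, 0.20),
    "wrist_flexion": (0.10, 0.20, 0.90, 1.10),
    "chuck_grip": (0.60, 0.40, 0.70, 0.50),
    "index_point": (0.70, 0.30, 0.40, 0.60),
    "supination": (0.30, 0.60, 0.50, 0.80),
    "pronation": (0.50, 0.80, 0.30, 0.40),
    "rest": (0.0, 0.0, 0.0, 0.0),
}


@dataclass
class MusclePattern:
    """Statistical stand-in for muscle activity during each gesture.

    Parameters
    ----------
    activation
        Non-negative amplitude matrix, shape ``(n_channels, n_gestures)``;
        the column for the rest gesture must be all zeros.
    baseline_noise_rms
        RMS of the ever-present instrumentation/baseline noise, in signal
        units.  Gesture amplitudes of order 1 with the default 0.1 give a
        signal-to-noise ratio around 20 dB.
    snr_scale
        Multiplicative factor on all gesture amplitudes (electrode-type
        factors are applied on top of this at generation time).
    psd_fl, psd_fh
        Corner frequencies of the sEMG spectral shape, Hz.
    ramp
        Raised-cosine onset/offset ramp duration at each gesture boundary,
        seconds.
    """

    activation: np.ndarray
    baseline_noise_rms: float = 0.1
    snr_scale: float = 1.0
    psd_fl: float = 60.0
    psd_fh: float = 120.0
    ramp: float = 0.2

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.ndim != 2:
            raise ValueError("activation must be a 2-D matrix")
        if np.any(self.activation < 0):
            raise ValueError("activation amplitudes must be non-negative")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be > 0")
        if self.baseline_noise_rms < 0:
            raise ValueError("baseline_noise_rms must be >= 0")


def default_pattern(
    protocol: GestureProtocol, n_channels: int = 4, **kwargs
) -> MusclePattern:
    """Build a :class:`MusclePattern` from the built-in activation template.

    Raises if the protocol names a gesture absent from the template or if
    ``n_channels`` differs from the template's four channels.
    """
    if n_channels != 4:
        raise ValueError("the built-in template is defined for 4 channels")
    cols = []
    for label in protocol.gesture_labels:
        if label not in ACTIVATION_TEMPLATE:
            raise KeyError(f"no template activation for gesture {label!r}")
        cols.append(ACTIVATION_TEMPLATE[label])
    return MusclePattern(activation=np.array(cols, dtype=float).T, **kwargs)


@dataclass
class EmgSession:
    """A labelled multi-channel EMG recording plus acquisition metadata.

    ``events`` is a sorted list of ``(label, start, end)`` half-open,
    0-based sample intervals marking gesture repetitions.
    """

    samples: np.ndarray
    sampling_rate: float
    events: list[tuple[str, int, int]]
    electrode_type: str
    seed: int
    protocol: GestureProtocol
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_samples x n_channels] array")
        if self.electrode_type not in ELECTRODE_TYPES:
            raise ValueError(
                f"unknown electrode type {self.electrode_type!r}; "
                f"expected one of {ELECTRODE_TYPES}"
            )
        n = self.samples.shape[0]
        prev_end = 0
        for label, start, end in self.events:
            if label not in self.protocol.gesture_labels:
                raise ValueError(f"event label {label!r} not in protocol")
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"event ({label!r}, {start}, {end}) outside sample range [0, {n})"
                )
            if start < prev_end:
                raise ValueError("events must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


@lru_cache(maxsize=8)
def _bandpass_sos(low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def shape_noise(
    white: np.ndarray, fl: float, fh: float, acq: AcquisitionConfig | None = None
) -> np.ndarray:
    """Colour white noise to the sEMG spectral shape, then band-pass it.

    The input is shaped in the frequency domain by ``sqrt(S(f))`` with
    ``S(f) = f^2 fh^4 / ((f^2+fl^2)(f^2+fh^2)^2)``, band-pass filtered to
    the acquisition band (4th-order zero-phase Butterworth), and
    re-normalised to unit RMS.

    Parameters
    ----------
    white
        Zero-mean, unit-variance sample vector, length >= 64.
    fl, fh
        Spectral corner frequencies in Hz, within (0, Nyquist).
    acq
        Acquisition configuration (sampling rate and pass band).
    """
    acq = acq or AcquisitionConfig()
    x = np.asarray(white, dtype=float)
    if x.ndim != 1:
        raise ValueError("white must be a 1-D sample vector")
    if x.size < 64:
        raise ValueError(f"input too short to shape ({x.size} samples, need >= 64)")
    nyq = acq.sampling_rate / 2
    if not (0 < fl < nyq and 0 < fh < nyq):
        raise ValueError("fl and fh must lie in (0, Nyquist)")
    if not np.any(x):
        return np.zeros_like(x)

    f = np.fft.rfftfreq(x.size, d=1.0 / acq.sampling_rate)
    psd = f**2 * fh**4 / ((f**2 + fl**2) * (f**2 + fh**2) ** 2)
    shaped = np.fft.irfft(np.fft.rfft(x) * np.sqrt(psd), n=x.size)
    y = sps.sosfiltfilt(_bandpass_sos(acq.band_low, acq.band_high, acq.sampling_rate), shaped)
    return y / _rms(y)


def _raised_cosine_envelope(n: int, ramp_samples: int) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps."""
    env = np.ones(n)
    r = min(ramp_samples, n // 2)
    if r > 0:
        t = np.arange(r) / r
        env[:r] = 0.5 * (1 - np.cos(np.pi * t))
        env[n - r:] = env[:r][::-1]
    return env


def generate_session(
    protocol: GestureProtocol,
    pattern: MusclePattern,
    acq: AcquisitionConfig | None = None,
    electrode_type: str = "gel",
    seed: int | None = None,
) -> EmgSession:
    """Simulate a full recording session following the gesture protocol.

    Timeline per repetition: countdown (baseline only), gesture
    (``activation[channel, gesture] * snr_scale``-scaled coloured noise with
    raised-cosine ramps, on top of baseline noise), then an inter-gesture
    rest.  Events mark each repetition's nominal gesture span.  Fully
    deterministic for a fixed seed.
    """
    acq = acq or AcquisitionConfig()
    if electrode_type not in ELECTRODE_TYPES:
        raise ValueError(
            f"unknown electrode type {electrode_type!r}; expected one of {ELECTRODE_TYPES}"
        )
    if seed is None:
        raise ValueError("seed is required for reproducible generation")
    if pattern.activation.shape != (acq.n_channels, protocol.n_gestures):
        raise ValueError(
            f"activation shape {pattern.activation.shape} does not match "
            f"({acq.n_channels} channels, {protocol.n_gestures} gestures)"
        )

    fs = acq.sampling_rate
    n_count = round(protocol.countdown * fs)
    n_gest = round(protocol.gesture_duration * fs)
    n_rest = round(protocol.rest_between * fs)
    n_block = n_count + n_gest + n_rest
    n_total = protocol.n_gestures * protocol.reps_per_gesture * n_block

    rng = np.random.default_rng(seed)
    snr = pattern.snr_scale * ELECTRODE_SNR_SCALE[electrode_type]
    ramp_samples = round(pattern.ramp * fs)

    # Baseline instrumentation noise over the whole session, per channel.
    samples = np.empty((n_total, acq.n_channels))
    for ch in range(acq.n_channels):
        samples[:, ch] = pattern.baseline_noise_rms * shape_noise(
            rng.standard_normal(n_total), pattern.psd_fl, pattern.psd_fh, acq
        )

    events: list[tuple[str, int, int]] = []
    env = _raised_cosine_envelope(n_gest, ramp_samples)
    cursor = 0
    for g_idx, label in enumerate(protocol.gesture_labels):
        for _ in range(protocol.reps_per_gesture):
            start = cursor + n_count
            end = start + n_gest
            for ch in range(acq.n_channels):
                amp = pattern.activation[ch, g_idx] * snr
                if amp > 0:
                    burst = shape_noise(
                        rng.standard_normal(n_gest), pattern.psd_fl, pattern.psd_fh, acq
                    )
                    samples[start:end, ch] += amp * env * burst
            events.append((label, start, end))
            cursor += n_block

    return EmgSession(
        samples=samples,
        sampling_rate=fs,
        events=events,
        electrode_type=electrode_type,
        seed=int(seed),
        protocol=protocol,
        acquisition=acq,
    )


def _session_base(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix in (".csv", ".json"):
        p = p.with_suffix("")
    return p


def write_session(session: EmgSession, path: str | Path) -> None:
    """Write a session as ``<name>.csv`` (samples) + ``<name>.json`` sidecar.

    The CSV holds one column per channel (header ``ch1..chN``), one row per
    sample; the sidecar carries sampling rate, acquisition settings,
    electrode type, seed, protocol and the event list.  The round trip
    through :func:`read_session` is lossless to float repr precision.
    """
    base = _session_base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"ch{i + 1}" for i in range(session.n_channels)]
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(session.samples, columns=cols).to_csv(
        base.with_suffix(".csv"), index=False, float_format="%.17g"
    )
    meta = {
        "sampling_rate": session.sampling_rate,
        "gain": session.acquisition.gain,
        "band": [session.acquisition.band_low, session.acquisition.band_high],
        "n_channels": session.n_channels,
        "electrode_type": session.electrode_type,
        "seed": session.seed,
        "protocol": {
            "gesture_labels": list(session.protocol.gesture_labels),
            "reps_per_gesture": session.protocol.reps_per_gesture,
            "gesture_duration": session.protocol.gesture_duration,
            "countdown": session.protocol.countdown,
            "rest_between": session.protocol.rest_between,
        },
        "events": [[label, start, end] for label, start, end in session.events],
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> EmgSession:
    """Read a session written by :func:`write_session`.

    Raises ``FileNotFoundError`` if the JSON sidecar is missing and
    ``ValueError`` on malformed metadata (channel-count mismatch, events
    outside the sample range, ...).
    """
    base = _session_base(path)
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc

    samples = pd.read_csv(
        base.with_suffix(".csv"), float_precision="round_trip"
    ).to_numpy(dtype=float)
    if samples.ndim != 2 or samples.shape[1] != meta["n_channels"]:
        raise ValueError(
            f"channel-count mismatch: CSV has {samples.shape[1]} columns, "
            f"sidecar declares {meta['n_channels']}"
        )
    proto = GestureProtocol(
        gesture_labels=tuple(meta["protocol"]["gesture_labels"]),
        reps_per_gesture=meta["protocol"]["reps_per_gesture"],
        gesture_duration=meta["protocol"]["gesture_duration"],
        countdown=meta["protocol"]["countdown"],
        rest_between=meta["protocol"]["rest_between"],
    )
    band_low, band_high = meta["band"]
    acq = AcquisitionConfig(
        sampling_rate=meta["sampling_rate"],
        band_low=band_low,
        band_high=band_high,
        gain=meta["gain"],
        n_channels=meta["n_channels"],
    )
    return EmgSession(
        samples=samples,
        sampling_rate=meta["sampling_rate"],
        events=[tuple(ev) for ev in meta["events"]],
        electrode_type=meta["electrode_type"],
        seed=meta["seed"],
        protocol=proto,
        acquisition=acq,
    )
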