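"""Time-domain EMG feature extraction pipeline.

Turns a labelled session into a window-by-feature table: each gesture
event is trimmed (first and last second removed to discard transition
movement), mean-subtracted per channel, cut into overlapping sliding
windows, and summarised by six standard time-domain features per channel:

ZC    zero crossings          #{i : x_i * x_{i+1} < 0 and |x_i - x_{i+1}| >= t_zc}
RMS   root mean square        sqrt(mean(x^2))
MAV   mean absolute value     mean(|x|)
WL    waveform length         sum |x_{i+1} - x_i|
SSC   slope sign changes      #{i : (x_i-x_{i-1})(x_i-x_{i+1}) > 0 and
                                    max(|x_i-x_{i-1}|, |x_i-x_{i+1}|) >= t_ssc}
WAMP  Willison amplitude      #{i : |x_{i+1} - x_i| >= t_wamp}

Default windowing is 200 ms with 50 ms overlap between consecutive
segments (stride 150 ms).  At 2048 Hz, window and stride lengths are
rounded to the nearest sample: 410 and 307.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EmgSession

__all__ = [
    "FEATURE_NAMES",
    "WindowingConfig",
    "FeatureConfig",
    "FeatureTable",
    "trim_event",
    "mean_subtract",
    "segment",
    "extract_features",
    "build_feature_table",
]

#: Fixed feature order within each channel block.
FEATURE_NAMES: tuple[str, ...] = ("zc", "rms", "mav", "wl", "ssc", "wamp")


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window segmentation parameters (milliseconds / seconds)."""

    window_ms: float = 200.0
    overlap_ms: float = 50.0
    trim_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_ms < self.window_ms):
            raise ValueError("require 0 <= overlap < window")
        if self.trim_s < 0:
            raise ValueError("trim must be >= 0")

    @property
    def step_ms(self) -> float:
        return self.window_ms - self.overlap_ms

    def window_samples(self, rate: float) -> int:
        return round(self.window_ms * rate / 1000.0)

    def step_samples(self, rate: float) -> int:
        return round(self.step_ms * rate / 1000.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Deadband thresholds for the counting features (signal units).

    Zero thresholds are workable defaults once the per-event mean has been
    removed; raise them to reject baseline noise on real recordings.
    """

    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    wamp_threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("zc_threshold", "ssc_threshold", "wamp_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def trim_event(signal: np.ndarray, trim: float, rate: float) -> np.ndarray:
    """Drop ``trim`` seconds from each end of an event, keeping the centre.

    A 6 s event trimmed by 1 s per end leaves the central 4 s.  Raises if
    the event is not strictly longer than ``2 * trim``.
    """
    x = np.asarray(signal, dtype=float)
    n_trim = round(trim * rate)
    if x.shape[0] <= 2 * n_trim:
        raise ValueError(
            f"event of {x.shape[0]} samples too short to trim {trim} s per end "
            f"at {rate} Hz"
        )
    if n_trim == 0:
        return x
    return x[n_trim:-n_trim]


def mean_subtract(signal: np.ndarray) -> np.ndarray:
    """Remove the per-channel mean (columns of a samples-by-channels array)."""
    x = np.asarray(signal, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("cannot mean-subtract an empty signal")
    return x - x.mean(axis=0, keepdims=x.ndim > 1)


def segment(signal: np.ndarray, cfg: WindowingConfig, rate: float) -> np.ndarray:
    """Cut a signal into overlapping windows.

    Returns an array of shape ``(n_windows, window_samples, ...)``; window
    starts are at multiples of the stride, and a trailing partial window is
    discarded.  A signal shorter than one window yields an empty result
    with a warning.
    """
    x = np.asarray(signal, dtype=float)
    w = cfg.window_samples(rate)
    s = cfg.step_samples(rate)
    n = x.shape[0]
    if n < w:
        warnings.warn(
            f"signal of {n} samples shorter than one {w}-sample window; "
            "no segments produced",
            stacklevel=2,
        )
        return np.empty((0, w) + x.shape[1:])
    starts = np.arange(0, n - w + 1, s)
    return np.stack([x[i : i + w] for i in starts])


def extract_features(window: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Compute the six time-domain features of a single-channel window.

    Returns ``[ZC, RMS, MAV, WL, SSC, WAMP]`` in that order.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D; extract per channel")
    if x.size < 3:
        raise ValueError(f"window too short ({x.size} samples, need >= 3)")

    d = np.diff(x)
    abs_d = np.abs(d)
    zc = int(np.count_nonzero((x[:-1] * x[1:] < 0) & (abs_d >= cfg.zc_threshold)))
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    wl = float(abs_d.sum())
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    ssc = int(
        np.count_nonzero(
            (d_prev * d_next > 0)
            & (np.maximum(np.abs(d_prev), np.abs(d_next)) >= cfg.ssc_threshold)
        )
    )
    wamp = int(np.count_nonzero(abs_d >= cfg.wamp_threshold))
    return np.array([zc, rms, mav, wl, ssc, wamp])


@dataclass
class FeatureTable:
    """Window-by-feature matrix with labels and provenance.

    ``data`` holds one row per window: feature columns named
    ``ch{c}_{feat}`` (channel-major, feature order within channel) plus
    ``label``, ``session`` and ``event`` provenance columns.
    """

    data: pd.DataFrame
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        for col in ("label", "session", "event"):
            if col not in self.data.columns:
                raise ValueError(f"feature table missing {col!r} column")
        if len(self.feature_columns) % len(FEATURE_NAMES) != 0:
            raise ValueError("feature column count must be a multiple of 6")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("label", "session", "event")]

    @property
    def matrix(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        """(session, event) provenance key per window."""
        return (
            self.data["session"].astype(str) + "/" + self.data["event"].astype(str)
        ).to_numpy()

    @property
    def n_channels(self) -> int:
        return len(self.feature_columns) // len(FEATURE_NAMES)

    @property
    def label_order(self) -> list[str]:
        """Labels in order of first appearance (protocol order for built tables)."""
        return list(dict.fromkeys(self.data["label"]))

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        windowing: WindowingConfig | None = None,
        features: FeatureConfig | None = None,
    ) -> "FeatureTable":
        return cls(
            data=pd.read_csv(path),
            windowing=windowing or WindowingConfig(),
            features=features or FeatureConfig(),
        )


def build_feature_table(
    session: EmgSession,
    wcfg: WindowingConfig | None = None,
    fcfg: FeatureConfig | None = None,
    session_name: str | None = None,
) -> FeatureTable:
    """Run the full pipeline over every labelled event of a session.

    Per event: trim, per-channel mean subtraction, segmentation, feature
    extraction; rows are ordered by (event order, window order) and inherit
    the event's gesture label.
    """
    wcfg = wcfg or WindowingConfig()
    fcfg = fcfg or FeatureConfig()
    if not session.events:
        raise ValueError("session has no labelled events")
    if session_name is None:
        session_name = f"{session.electrode_type}-seed{session.seed}"

    n_feat = len(FEATURE_NAMES)
    columns = [
        f"ch{c + 1}_{feat}"
        for c in range(session.n_channels)
        for feat in FEATURE_NAMES
    ]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    event_ids: list[int] = []
    for ev_idx, (label, start, end) in enumerate(session.events):
        try:
            x = trim_event(session.samples[start:end], wcfg.trim_s, session.sampling_rate)
        except ValueError as exc:
            raise ValueError(f"event {ev_idx} ({label!r}): {exc}") from exc
        x = mean_subtract(x)
        windows = segment(x, wcfg, session.sampling_rate)
        for win in windows:
            feats = np.empty(session.n_channels * n_feat)
            for c in range(session.n_channels):
                feats[c * n_feat : (c + 1) * n_feat] = extract_features(win[:, c], fcfg)
            rows.append(feats)
            labels.append(label)
            event_ids.append(ev_idx)

    data = pd.DataFrame(np.array(rows), columns=columns)
    data["label"] = labels
    data["session"] = session_name
    data["event"] = event_ids
    return FeatureTable(data=data, windowing=wcfg, features=fcfg)
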