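"""Fitts'-law target-acquisition game for 2-DOF myoelectric cursor control.

A cursor starts at the origin of a square grid (both axes -110..+110) and
is driven in fixed steps of 110/28 grid units by classified gestures: the
four motion gestures map to the four orthogonal directions and rest leaves
the cursor in place.  Each game presents 24 square targets — six
distance/width configurations, four targets each, in a seeded random
permutation.  A trial succeeds when the cursor is held inside the target
for one continuous second (five 200 ms ticks) and fails at a 20 s timeout.

Task difficulty follows Shannon's formulation of Fitts' law,

    ID = log2(D / W + 1)   [bits],

for target distance D and width W, and throughput is the mean of ID / C
over successful trials with completion time C (dwell included).  The
completion rate is the percentage of targets successfully acquired.

The human in the loop is replaced by a simulated user: either an intent
+ confusion-matrix model (each tick the greedy intended gesture is passed
through a per-tick misclassification matrix) or a closed-loop model that
synthesises one 200 ms EMG frame per tick and classifies it with a trained
network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureConfig, extract_features, FEATURE_NAMES
from .network import GestureClassifier, predict, transform
from .simulate import (
    AcquisitionConfig,
    MusclePattern,
    ELECTRODE_SNR_SCALE,
    shape_noise,
)

__all__ = [
    "TargetConfiguration",
    "TABLE_CONFIGURATIONS",
    "GameConfig",
    "Target",
    "GameSession",
    "TrialResult",
    "UsabilityMetrics",
    "ConfusionUser",
    "ClosedLoopUser",
    "index_of_difficulty",
    "confusion_from_accuracy",
    "make_game",
    "step_cursor",
    "intended_gesture",
    "run_trial",
    "run_game",
    "score_session",
]


def index_of_difficulty(distance: float, width: float) -> float:
    """Shannon index of difficulty log2(D/W + 1) in bits."""
    if width <= 0:
        raise ValueError("target width must be > 0")
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return math.log2(distance / width + 1.0)


@dataclass(frozen=True)
class TargetConfiguration:
    """A distance/width pair and the target numbers assigned to it."""

    distance: float
    width: float
    target_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.width <= 0:
            raise ValueError("distance and width must be > 0")

    @property
    def index_of_difficulty(self) -> float:
        return index_of_difficulty(self.distance, self.width)


#: The six standard game configurations: distances 50/100, widths 5/10/20,
#: four target numbers each (24 targets per game).
TABLE_CONFIGURATIONS: tuple[TargetConfiguration, ...] = (
    TargetConfiguration(50, 5, (1, 7, 13, 19)),
    TargetConfiguration(50, 10, (2, 8, 14, 20)),
    TargetConfiguration(50, 20, (3, 9, 15, 21)),
    TargetConfiguration(100, 5, (4, 10, 16, 22)),
    TargetConfiguration(100, 10, (5, 11, 17, 23)),
    TargetConfiguration(100, 20, (6, 12, 18, 24)),
)

#: Default assignment of motion gestures to grid directions.
DEFAULT_DIRECTIONS: dict[str, tuple[int, int]] = {
    "wrist_extension": (1, 0),
    "wrist_flexion": (-1, 0),
    "open_hand": (0, 1),
    "closed_hand": (0, -1),
    "rest": (0, 0),
}


@dataclass(frozen=True)
class GameConfig:
    """Grid geometry, timing and trial rules."""

    axis_range: float = 110.0
    step: float = 110.0 / 28.0
    tick: float = 0.2
    dwell: float = 1.0
    timeout: float = 20.0
    configurations: tuple[TargetConfiguration, ...] = TABLE_CONFIGURATIONS
    placement: str = "random_angle"
    directions: tuple[tuple[str, tuple[int, int]], ...] = tuple(
        DEFAULT_DIRECTIONS.items()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not (0 < self.dwell < self.timeout):
            raise ValueError("require 0 < dwell < timeout")
        if self.placement not in ("random_angle", "axis_aligned"):
            raise ValueError(f"unknown placement {self.placement!r}")
        numbers = sorted(
            n for cfg in self.configurations for n in cfg.target_numbers
        )
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError("target numbers must cover 1..N exactly once")

    @property
    def n_targets(self) -> int:
        return sum(len(c.target_numbers) for c in self.configurations)

    @property
    def direction_map(self) -> dict[str, tuple[int, int]]:
        return dict(self.directions)

    @property
    def dwell_ticks(self) -> int:
        return round(self.dwell / self.tick)

    @property
    def max_ticks(self) -> int:
        return round(self.timeout / self.tick)


@dataclass(frozen=True)
class Target:
    number: int
    configuration: TargetConfiguration
    center: tuple[float, float]

    def contains(self, pos: tuple[float, float]) -> bool:
        half = self.configuration.width / 2.0
        return (
            abs(pos[0] - self.center[0]) <= half
            and abs(pos[1] - self.center[1]) <= half
        )


@dataclass
class GameSession:
    """Ordered targets of one game plus the config that produced them."""

    targets: list[Target]
    config: GameConfig


def make_game(cfg: GameConfig | None = None) -> GameSession:
    """Generate one game: a seeded permutation of the 24 numbered targets.

    Each target's centre is placed at its configuration's distance from the
    origin — at a seeded uniform angle by default, or on a seeded random
    half-axis in ``axis_aligned`` mode.  Target squares always fit inside
    the grid with the standard geometry (distance <= 100, width <= 20,
    grid half-range 110).
    """
    cfg = cfg or GameConfig()
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(cfg.n_targets) + 1
    by_number = {
        n: c for c in cfg.configurations for n in c.target_numbers
    }
    targets = []
    for number in order.tolist():
        conf = by_number[number]
        if cfg.placement == "random_angle":
            angle = rng.uniform(0.0, 2.0 * np.pi)
        else:
            angle = rng.integers(0, 4) * np.pi / 2.0
        cx = conf.distance * math.cos(angle)
        cy = conf.distance * math.sin(angle)
        half = conf.width / 2.0
        if max(abs(cx), abs(cy)) + half > cfg.axis_range + 1e-9:
            raise ValueError(
                f"target {number} at ({cx:.1f}, {cy:.1f}) overflows the grid"
            )
        targets.append(Target(number=number, configuration=conf, center=(cx, cy)))
    return GameSession(targets=targets, config=cfg)


def step_cursor(
    pos: tuple[float, float], gesture: str, cfg: GameConfig
) -> tuple[float, float]:
    """Move the cursor one step in the gesture's direction, clamped to grid."""
    dmap = cfg.direction_map
    if gesture not in dmap:
        raise ValueError(f"unknown gesture {gesture!r}; expected one of {sorted(dmap)}")
    dx, dy = dmap[gesture]
    r = cfg.axis_range
    return (
        float(np.clip(pos[0] + dx * cfg.step, -r, r)),
        float(np.clip(pos[1] + dy * cfg.step, -r, r)),
    )


def intended_gesture(
    pos: tuple[float, float], target: Target, cfg: GameConfig
) -> str:
    """Greedy intent: rest inside the target, else move along the axis with
    the larger remaining centre distance."""
    if target.contains(pos):
        return "rest"
    dx = target.center[0] - pos[0]
    dy = target.center[1] - pos[1]
    inverse = {v: k for k, v in cfg.direction_map.items()}
    if abs(dx) >= abs(dy):
        return inverse[(1, 0)] if dx > 0 else inverse[(-1, 0)]
    return inverse[(0, 1)] if dy > 0 else inverse[(0, -1)]


@dataclass
class TrialResult:
    target_number: int
    configuration: TargetConfiguration
    success: bool
    completion_time: float | None
    cursor_trace: list[tuple[int, float, float]]
    intended: list[str]
    classified: list[str]

    @property
    def index_of_difficulty(self) -> float:
        return self.configuration.index_of_difficulty


class ConfusionUser:
    """Intent-level simulated user.

    Each tick the greedy intended gesture is replaced by a draw from the
    corresponding row of a 5x5 per-tick confusion matrix (rows/columns in
    ``labels`` order, rows summing to 1).
    """

    def __init__(self, confusion: np.ndarray, labels: list[str], seed: int = 0):
        self.confusion = np.asarray(confusion, dtype=float)
        self.labels = list(labels)
        k = len(self.labels)
        if self.confusion.shape != (k, k):
            raise ValueError(f"confusion must be {k}x{k}")
        if np.any(self.confusion < 0) or not np.allclose(
            self.confusion.sum(axis=1), 1.0
        ):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        self._idx = {lab: i for i, lab in enumerate(self.labels)}
        self.rng = np.random.default_rng(seed)

    def emit(self, intended: str) -> str:
        row = self.confusion[self._idx[intended]]
        return self.labels[self.rng.choice(len(self.labels), p=row)]


class ClosedLoopUser:
    """Closed-loop simulated user: EMG synthesis -> features -> classifier.

    Each tick, one 200 ms multi-channel EMG frame is synthesised for the
    intended gesture (activation-scaled coloured noise plus baseline, as in
    session generation) and classified with the trained network; the
    classifier's output drives the cursor.
    """

    def __init__(
        self,
        classifier: GestureClassifier,
        pattern: MusclePattern,
        gesture_labels: list[str],
        acq: AcquisitionConfig | None = None,
        electrode_type: str = "gel",
        fcfg: FeatureConfig | None = None,
        frame_samples: int = 410,
        seed: int = 0,
    ):
        self.classifier = classifier
        self.pattern = pattern
        self.labels = list(gesture_labels)
        self.acq = acq or AcquisitionConfig()
        self.snr = pattern.snr_scale * ELECTRODE_SNR_SCALE[electrode_type]
        self.fcfg = fcfg or FeatureConfig()
        self.frame_samples = frame_samples
        self.rng = np.random.default_rng(seed)
        self._gesture_idx = {lab: i for i, lab in enumerate(self.labels)}

    def _synth_frame(self, gesture: str) -> np.ndarray:
        g = self._gesture_idx[gesture]
        n = self.frame_samples
        frame = np.empty((n, self.acq.n_channels))
        for ch in range(self.acq.n_channels):
            x = self.pattern.baseline_noise_rms * shape_noise(
                self.rng.standard_normal(n), self.pattern.psd_fl,
                self.pattern.psd_fh, self.acq,
            )
            amp = self.pattern.activation[ch, g] * self.snr
            if amp > 0:
                x = x + amp * shape_noise(
                    self.rng.standard_normal(n), self.pattern.psd_fl,
                    self.pattern.psd_fh, self.acq,
                )
            frame[:, ch] = x
        return frame - frame.mean(axis=0)

    def emit(self, intended: str) -> str:
        frame = self._synth_frame(intended)
        n_feat = len(FEATURE_NAMES)
        feats = np.empty(frame.shape[1] * n_feat)
        for c in range(frame.shape[1]):
            feats[c * n_feat : (c + 1) * n_feat] = extract_features(
                frame[:, c], self.fcfg
            )
        label, _ = predict(self.classifier, transform(self.classifier.pca, feats))
        return str(label[0])


def run_trial(target: Target, user, cfg: GameConfig | None = None) -> TrialResult:
    """Simulate one trial: tick loop with dwell and timeout rules.

    The cursor starts at the origin.  Each 200 ms tick the user emits a
    gesture and the cursor steps accordingly.  A tick counts toward the
    dwell hold only if the cursor is inside the target both before and
    after the move (the arrival tick starts the hold, it does not count);
    the trial succeeds once the hold spans the full dwell time, with
    ``completion_time = ticks x tick`` inclusive of the dwell.  Reaching
    the timeout first makes the trial unsuccessful.
    """
    cfg = cfg or GameConfig()
    pos = (0.0, 0.0)
    trace = [(0, 0.0, 0.0)]
    intended_log: list[str] = []
    classified_log: list[str] = []
    hold = 0
    success = False
    completion_time: float | None = None
    for t in range(1, cfg.max_ticks + 1):
        inside_before = target.contains(pos)
        intent = intended_gesture(pos, target, cfg)
        emitted = user.emit(intent)
        pos = step_cursor(pos, emitted, cfg)
        trace.append((t, pos[0], pos[1]))
        intended_log.append(intent)
        classified_log.append(emitted)
        hold = hold + 1 if (inside_before and target.contains(pos)) else 0
        if hold >= cfg.dwell_ticks:
            success = True
            completion_time = t * cfg.tick
            break
    return TrialResult(
        target_number=target.number,
        configuration=target.configuration,
        success=success,
        completion_time=completion_time,
        cursor_trace=trace,
        intended=intended_log,
        classified=classified_log,
    )


def run_game(game: GameSession, user) -> list[TrialResult]:
    """Run every target of a game in order with the same user."""
    return [run_trial(t, user, game.config) for t in game.targets]


@dataclass
class UsabilityMetrics:
    """Throughput, completion rate and per-configuration timing summary."""

    throughput: float  # bits/s; NaN when no successful trials
    completion_rate: float  # percent
    n_trials: int
    n_success: int
    per_configuration: dict[tuple[float, float], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "throughput_bits_per_s": self.throughput,
            "completion_rate_percent": self.completion_rate,
            "n_trials": self.n_trials,
            "n_success": self.n_success,
            "mean_completion_time_by_config": {
                f"D{d:g}_W{w:g}": t for (d, w), t in self.per_configuration.items()
            },
        }


def score_session(trials: list[TrialResult]) -> UsabilityMetrics:
    """Throughput (mean ID/C over successes) and completion rate of a session."""
    if not trials:
        raise ValueError("need at least one trial to score")
    successes = [t for t in trials if t.success]
    if successes:
        tp = float(
            np.mean([t.index_of_difficulty / t.completion_time for t in successes])
        )
    else:
        tp = float("nan")
    per_cfg: dict[tuple[float, float], float] = {}
    keys = {(t.configuration.distance, t.configuration.width) for t in trials}
    for key in sorted(keys):
        times = [
            t.completion_time
            for t in successes
            if (t.configuration.distance, t.configuration.width) == key
        ]
        per_cfg[key] = float(np.mean(times)) if times else float("nan")
    return UsabilityMetrics(
        throughput=tp,
        completion_rate=100.0 * len(successes) / len(trials),
        n_trials=len(trials),
        n_success=len(successes),
        per_configuration=per_cfg,
    )


def confusion_from_accuracy(accuracy: float, n_classes: int = 5) -> np.ndarray:
    """Symmetric confusion matrix with ``accuracy`` on the diagonal and the
    remaining mass spread uniformly over the other classes."""
    if not (0 <= accuracy <= 1):
        raise ValueError("accuracy must be in [0, 1]")
    off = (1.0 - accuracy) / (n_classes - 1)
    C = np.full((n_classes, n_classes), off)
    np.fill_diagonal(C, accuracy)
    return C


def write_game_log(
    trials: list[TrialResult], metrics: UsabilityMetrics, out_dir: str | Path
) -> None:
    """Write a session log: per-tick CSV trace + JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["trial,target_number,tick,x,y,intended,classified"]
    for i, tr in enumerate(trials):
        for (tick, x, y), intent, cls in zip(
            tr.cursor_trace[1:], tr.intended, tr.classified
        ):
            lines.append(
                f"{i},{tr.target_number},{tick},{x:.4f},{y:.4f},{intent},{cls}"
            )
    (out / "trace.csv").write_text("\n".join(lines) + "\n")
    summary = {
        "metrics": metrics.to_dict(),
        "trials": [
            {
                "target_number": tr.target_number,
                "distance": tr.configuration.distance,
                "width": tr.configuration.width,
                "index_of_difficulty": tr.index_of_difficulty,
                "success": tr.success,
                "completion_time_s": tr.completion_time,
            }
            for tr in trials
        ],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
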