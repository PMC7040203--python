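"""Velocity computation, movement segmentation, and temporal features.

The hand is tracked by its grip center (mean of thumb, index and middle
fingertip positions).  Speed is the Euclidean norm of the 3-D velocity.
A movement onset is the first sample of a run of at least ``min_run``
consecutive samples above ``velocity_threshold`` (default 30 mm/s over 10
samples at 100 Hz), and the offset — the object-contact or put-down
instant — is the first sample of the subsequent run of at least
``min_run`` samples back below the threshold.

Temporal features per movement: peak velocity (maximum speed, earliest
sample on ties), duration (onset to offset), and — for the reach — the
adjustment time, the deceleration interval from the velocity peak to
object contact, interpreted as the grasp-planning phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mocap_io import MarkerTrajectory, Trial, grip_center

__all__ = [
    "SegmentationConfig",
    "MovementSegment",
    "SegmentationWarning",
    "LabelingError",
    "velocity_norm",
    "segment_movements",
    "label_segments",
    "temporal_features",
    "segment_trial",
]

#: Radius (mm) within which a segment endpoint counts as "at" a landmark.
LANDMARK_RADIUS_MM = 60.0


class SegmentationWarning(UserWarning):
    pass


class LabelingError(ValueError):
    """No segment of the trial qualifies as the reach."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for velocity-based movement segmentation.

    ``smoothing_hz`` applies a zero-phase 4th-order Butterworth low-pass to
    the positions before differentiation; ``None`` (the default) leaves the
    positions untouched.
    """

    velocity_threshold: float = 30.0  # mm/s
    min_run: int = 10  # samples
    smoothing_hz: float | None = None

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0:
            raise ValueError("velocity_threshold must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.smoothing_hz is not None and self.smoothing_hz <= 0:
            raise ValueError("smoothing cutoff must be positive")


@dataclass
class MovementSegment:
    """A labeled movement span, onset inclusive, offset exclusive."""

    label: str  # reach | transport | other
    onset_idx: int
    offset_idx: int
    velocity: np.ndarray  # speed series over [onset_idx, offset_idx)
    frame_period_ms: float
    peak_idx: int = field(init=False)
    peak_velocity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.offset_idx <= self.onset_idx:
            raise ValueError("empty segment")
        local = int(np.argmax(self.velocity))  # argmax takes earliest tie
        self.peak_idx = self.onset_idx + local
        self.peak_velocity = float(self.velocity[local])

    @property
    def duration_ms(self) -> float:
        return (self.offset_idx - self.onset_idx) * self.frame_period_ms

    @property
    def peak_time_ms(self) -> float:
        """Time of the velocity peak, ms after onset."""
        return (self.peak_idx - self.onset_idx) * self.frame_period_ms

    @property
    def adjustment_time_ms(self) -> float | None:
        """Peak-to-offset interval; defined for reach segments only."""
        if self.label != "reach":
            return None
        return (self.offset_idx - self.peak_idx) * self.frame_period_ms

    @property
    def degenerate(self) -> bool:
        """Peak at the first or last sample of the span."""
        return self.peak_idx in (self.onset_idx, self.offset_idx - 1)


def velocity_norm(
    traj: MarkerTrajectory, cfg: SegmentationConfig = SegmentationConfig()
) -> np.ndarray:
    """Per-sample speed (mm/s): Euclidean norm of the 3-D velocity estimate.

    Velocity is estimated by central differences (one-sided at the edges).
    The trajectory must be gap-free: the speed of an untracked sample is
    meaningless and downstream windows must exclude it explicitly.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples to estimate velocity")
    pos = traj.positions
    if not traj.valid_mask.all():
        # derivative estimates through gaps would be fabricated data
        pos = pos.copy()
        pos[~traj.valid_mask] = np.nan
    if cfg.smoothing_hz is not None:
        from scipy.signal import butter, filtfilt

        nyq = traj.sample_rate / 2.0
        b, a = butter(4, cfg.smoothing_hz / nyq)
        pos = filtfilt(b, a, pos, axis=0)
    dt = traj.frame_period_ms / 1000.0
    vel = np.gradient(pos, dt, axis=0)
    return np.linalg.norm(vel, axis=1)


def _first_run_start(flags: np.ndarray, min_run: int, start: int) -> int | None:
    """Index of the first run of >= min_run consecutive True at/after start."""
    f = flags[start:]
    if f.size == 0 or not f.any():
        return None
    edges = np.diff(f.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if f[0]:
        starts = np.concatenate(([0], starts))
    if f[-1]:
        ends = np.concatenate((ends, [f.size]))
    long_enough = np.flatnonzero(ends - starts >= min_run)
    if long_enough.size == 0:
        return None
    return start + int(starts[long_enough[0]])


def segment_movements(
    speed: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
) -> list[tuple[int, int]]:
    """Detect [onset, offset) movement spans in a speed series.

    A movement still above threshold when the series ends has no offset and
    is dropped with a :class:`SegmentationWarning`.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed series")
    if not np.all(np.isfinite(speed)):
        raise ValueError("speed series contains non-finite values")
    above = speed > cfg.velocity_threshold
    segments: list[tuple[int, int]] = []
    cursor = 0
    while True:
        onset = _first_run_start(above, cfg.min_run, cursor)
        if onset is None:
            break
        offset = _first_run_start(~above, cfg.min_run, onset)
        if offset is None:
            warnings.warn(
                f"movement starting at sample {onset} never returns below "
                f"{cfg.velocity_threshold} mm/s for {cfg.min_run} samples; dropped",
                SegmentationWarning,
                stacklevel=2,
            )
            break
        segments.append((onset, offset))
        cursor = offset
    return segments


def label_segments(
    segments: Sequence[tuple[int, int]],
    trial: Trial,
    speed: np.ndarray,
    manual_labels: dict[int, str] | None = None,
) -> list[MovementSegment]:
    """Classify movement spans as reach / transport / other.

    The rule is geometric: a span whose terminal grip-center position lies
    within :data:`LANDMARK_RADIUS_MM` of pick-up location A is the reach; a
    span from near A to near put-down location B is the transport; anything
    else is ``other``.  ``manual_labels`` (span index -> label) overrides the
    geometry, mirroring analyst-coded segment identities.
    """
    gc = grip_center(trial)
    period = gc.frame_period_ms
    a = trial.landmarks["A"]
    b = trial.landmarks["B"]
    manual_labels = manual_labels or {}
    out: list[MovementSegment] = []
    for k, (onset, offset) in enumerate(segments):
        if k in manual_labels:
            label = manual_labels[k]
        else:
            p_start = gc.positions[onset]
            p_end = gc.positions[offset - 1] if offset - 1 < len(gc) else gc.positions[-1]
            # horizontal proximity: the grip center hovers at grasp height
            # above the table-level landmark positions
            near = lambda p, q: bool(np.linalg.norm((p - q)[:2]) <= LANDMARK_RADIUS_MM)
            if near(p_end, a):
                label = "reach"
            elif near(p_start, a) and near(p_end, b):
                label = "transport"
            else:
                label = "other"
        out.append(
            MovementSegment(
                label=label,
                onset_idx=onset,
                offset_idx=offset,
                velocity=np.asarray(speed[onset:offset], dtype=float),
                frame_period_ms=period,
            )
        )
    if not any(s.label == "reach" for s in out):
        raise LabelingError(
            f"trial {trial.trial_id or '?'}: no segment qualifies as the reach"
        )
    return out


def temporal_features(segment: MovementSegment) -> dict:
    """Peak velocity, its timing, duration, and (reach only) adjustment time."""
    return {
        "label": segment.label,
        "onset_ms": segment.onset_idx * segment.frame_period_ms,
        "offset_ms": segment.offset_idx * segment.frame_period_ms,
        "duration_ms": segment.duration_ms,
        "peak_velocity": segment.peak_velocity,
        "peak_time_ms": segment.peak_time_ms,
        "adjustment_time_ms": segment.adjustment_time_ms,
        "degenerate": segment.degenerate,
    }


def segment_trial(
    trial: Trial,
    cfg: SegmentationConfig = SegmentationConfig(),
    manual_labels: dict[int, str] | None = None,
) -> tuple[list[MovementSegment], np.ndarray]:
    """Segment and label one trial from its grip-center speed.

    Returns the labeled segments and the speed series they index into.
    Raises if any fingertip gap survives inside a detected movement span
    (such trials are excluded rather than analysed on fabricated samples).
    """
    gc = grip_center(trial)
    if not gc.valid_mask.any():
        raise ValueError("no sample has all three fingertips tracked")
    speed = velocity_norm(gc, cfg)
    # segmentation cannot run through gaps: treat NaN speed as sub-threshold
    finite_speed = np.nan_to_num(speed, nan=0.0)
    spans = segment_movements(finite_speed, cfg)
    for onset, offset in spans:
        if not gc.valid_mask[onset:offset].all():
            raise ValueError(
                f"unfilled fingertip gap inside movement span [{onset}, {offset})"
            )
    segments = label_segments(spans, trial, finite_speed, manual_labels)
    return segments, finite_speed
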