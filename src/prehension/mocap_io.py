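"""Marker-trajectory data model and file I/O for reach-to-grasp trials.

A trial is a set of fingertip marker trajectories (thumb, index, middle at
minimum) recorded by an optical motion-capture system at a fixed sampling
rate, plus the condition metadata of the experimental design (surface finish
of the cup, its content, and whether the content was visible) and the table
landmarks (start position, pick-up location A, put-down location B).

Coordinate convention: right-handed, X front-back, Y left-right, Z up,
units mm, time in ms from trial start, 0-based sample indices.

Two on-disk formats are supported:

* a fixed tab-separated dialect (header ``frame\\ttime\\t<marker>_X ...``,
  dot decimal, empty fields for untracked samples) emulating the tabular
  export of optical tracking software, and
* standard C3D point files (via the bundled minimal reader); samples with a
  negative residual are flagged invalid, following the C3D convention.

Missing samples are carried in an explicit validity mask and are never
silently interpolated on read; :func:`fill_gaps` performs explicit, bounded
linear interpolation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTrajectory",
    "Trial",
    "RatingRecord",
    "Condition",
    "FormatError",
    "MarkerMappingError",
    "UnusableTrajectoryError",
    "FINGER_MARKERS",
    "DEFAULT_LANDMARKS",
    "read_trial_tsv",
    "write_trial_tsv",
    "read_trial_c3d",
    "fill_gaps",
    "grip_center",
    "write_manifest",
    "read_manifest",
]

#: Marker labels every trial must provide.
FINGER_MARKERS = ("thumb", "index", "middle")

#: Table geometry used when trial metadata carries no landmarks:
#: hand start position, pick-up location A (400 mm ahead), put-down
#: location B (400 mm to the right of A). Units mm.
DEFAULT_LANDMARKS = {
    "start": (0.0, 0.0, 0.0),
    "A": (400.0, 0.0, 0.0),
    "B": (400.0, 400.0, 0.0),
}

#: Tolerance on sampling uniformity, ms.
TIME_TOL_MS = 1e-6


class FormatError(ValueError):
    """Malformed or non-conforming trajectory file."""


class MarkerMappingError(KeyError):
    """A required marker label could not be found in the file."""


class UnusableTrajectoryError(ValueError):
    """Trajectory cannot support the requested analysis (e.g. all samples lost)."""


@dataclass
class MarkerTrajectory:
    """One marker's uniformly sampled 3-D position series.

    Parameters
    ----------
    marker_id:
        Label, e.g. ``"thumb"``.
    times:
        Sample times in ms from trial start, strictly increasing and uniform.
    positions:
        ``(n, 3)`` array of X/Y/Z in mm.  Entries where ``valid_mask`` is
        False are ignored (the marker was not tracked there).
    valid_mask:
        Per-sample boolean, True where the marker was tracked.
    sample_rate:
        Sampling rate in Hz.
    """

    marker_id: str
    times: np.ndarray
    positions: np.ndarray
    valid_mask: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = len(self.times)
        if self.positions.shape != (n, 3):
            raise FormatError(
                f"positions shape {self.positions.shape} != ({n}, 3) for "
                f"marker {self.marker_id!r}"
            )
        if len(self.valid_mask) != n:
            raise FormatError("valid_mask length mismatch")
        if n >= 2:
            deltas = np.diff(self.times)
            period = 1000.0 / self.sample_rate
            if np.any(np.abs(deltas - period) > TIME_TOL_MS):
                raise FormatError(
                    f"non-uniform sampling for marker {self.marker_id!r}: "
                    f"expected {period} ms steps"
                )
        if not np.all(np.isfinite(self.positions[self.valid_mask])):
            raise FormatError(
                f"non-finite position among valid samples of {self.marker_id!r}"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def copy(self) -> "MarkerTrajectory":
        return replace(
            self,
            times=self.times.copy(),
            positions=self.positions.copy(),
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class Condition:
    """Factor levels of the 2x2x2 within-subject design."""

    surface: str  # matte | shiny
    content: str  # empty | filled
    feedback: str  # visible | hidden

    _LEVELS = {
        "surface": ("matte", "shiny"),
        "content": ("empty", "filled"),
        "feedback": ("visible", "hidden"),
    }

    def __post_init__(self) -> None:
        for name, levels in self._LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValueError(f"{name} must be one of {levels}")

    def as_dict(self) -> dict:
        return {
            "surface": self.surface,
            "content": self.content,
            "feedback": self.feedback,
        }


@dataclass
class Trial:
    """All marker trajectories for one reach-and-transport execution."""

    participant_id: str
    block: int
    condition: Condition
    trajectories: dict[str, MarkerTrajectory]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= int(self.block):
            raise ValueError("block must be a positive integer")
        missing = [m for m in FINGER_MARKERS if m not in self.trajectories]
        if missing:
            raise MarkerMappingError(f"missing fingertip trajectories: {missing}")
        ref = self.trajectories[FINGER_MARKERS[0]]
        for m in FINGER_MARKERS[1:]:
            t = self.trajectories[m]
            if len(t) != len(ref) or np.any(np.abs(t.times - ref.times) > TIME_TOL_MS):
                raise FormatError("fingertip trajectories must share one time base")
        if not self.landmarks:
            self.landmarks = {
                k: np.asarray(v, dtype=float) for k, v in DEFAULT_LANDMARKS.items()
            }
        else:
            self.landmarks = {
                k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()
            }
        for key in ("start", "A", "B"):
            if key not in self.landmarks:
                raise ValueError(f"landmark {key!r} missing")
        a, b = self.landmarks["A"], self.landmarks["B"]
        s = self.landmarks["start"]
        if np.linalg.norm((b - a)[:2]) <= 0 or np.linalg.norm((a - s)[:2]) <= 0:
            raise ValueError("degenerate landmark geometry")

    @property
    def sample_rate(self) -> float:
        return self.trajectories[FINGER_MARKERS[0]].sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.trajectories[FINGER_MARKERS[0]])

    def fingers(self) -> tuple[MarkerTrajectory, MarkerTrajectory, MarkerTrajectory]:
        return tuple(self.trajectories[m] for m in FINGER_MARKERS)


@dataclass(frozen=True)
class RatingRecord:
    """One ordinal rating (1-7 semantic differential) of one stimulus."""

    participant_id: str
    stimulus_id: str
    dimension: str  # heaviness | hardness | glossiness
    phase: str  # pre | post
    value: int

    def __post_init__(self) -> None:
        if self.dimension not in ("heaviness", "hardness", "glossiness"):
            raise ValueError(f"unknown rating dimension {self.dimension!r}")
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        if not (isinstance(self.value, (int, np.integer)) and 1 <= self.value <= 7):
            raise ValueError("rating value must be an integer in 1..7")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_trial_tsv(trial: Trial, path: str | Path) -> None:
    """Write a trial in the package's TSV dialect.

    Header is ``frame\\ttime\\t<marker>_X\\t<marker>_Y\\t<marker>_Z ...``;
    untracked samples are written as empty fields.  Numbers use a dot
    decimal and enough digits to round-trip float64 exactly.
    """
    markers = list(trial.trajectories)
    ref = trial.trajectories[markers[0]]
    header = ["frame", "time"]
    for m in markers:
        header += [f"{m}_X", f"{m}_Y", f"{m}_Z"]
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(header)
    for i in range(len(ref)):
        row: list[str] = [str(i), repr(float(ref.times[i]))]
        for m in markers:
            tr = trial.trajectories[m]
            if tr.valid_mask[i]:
                row += [repr(float(v)) for v in tr.positions[i]]
            else:
                row += ["", "", ""]
        w.writerow(row)
    Path(path).write_text(buf.getvalue())


def read_trial_tsv(path: str | Path, metadata: Mapping | None = None) -> Trial:
    """Read a trial from the TSV dialect written by :func:`write_trial_tsv`.

    Parameters
    ----------
    metadata:
        Mapping with keys ``participant_id``, ``block``, ``surface``,
        ``content``, ``feedback`` and optionally ``landmarks`` (mapping of
        start/A/B to xyz) and ``trial_id``.  Defaults describe an anonymous
        single trial.
    """
    md = dict(metadata or {})
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 5 or list(df.columns[:2]) != ["frame", "time"]:
        raise FormatError(f"{path}: header must start with 'frame\\ttime'")
    coord_cols = list(df.columns[2:])
    markers: list[str] = []
    for col in coord_cols:
        if "_" not in col:
            raise FormatError(f"{path}: coordinate column {col!r} lacks _X/_Y/_Z suffix")
        name, axis = col.rsplit("_", 1)
        if axis == "X":
            markers.append(name)
    for m in markers:
        for ax in ("X", "Y", "Z"):
            if f"{m}_{ax}" not in df.columns:
                raise FormatError(f"{path}: marker {m!r} missing axis {ax}")
    times = df["time"].astype(float).to_numpy()
    if len(times) >= 2:
        deltas = np.diff(times)
        if np.any(np.abs(deltas - deltas[0]) > TIME_TOL_MS) or deltas[0] <= 0:
            raise FormatError(f"{path}: non-uniform sampling")
        sample_rate = 1000.0 / deltas[0]
    else:
        sample_rate = float(md.get("sample_rate", 100.0))

    trajectories: dict[str, MarkerTrajectory] = {}
    for m in markers:
        cols = [df[f"{m}_{ax}"].to_numpy() for ax in ("X", "Y", "Z")]
        empty = np.column_stack([c == "" for c in cols])
        if np.any(empty.any(axis=1) != empty.all(axis=1)):
            raise FormatError(f"{path}: partially empty X/Y/Z triplet for {m!r}")
        valid = ~empty.all(axis=1)
        pos = np.full((len(df), 3), np.nan)
        for j, c in enumerate(cols):
            pos[valid, j] = c[valid].astype(float)
        trajectories[m] = MarkerTrajectory(m, times, pos, valid, sample_rate)

    missing = [m for m in FINGER_MARKERS if m not in trajectories]
    if missing:
        raise MarkerMappingError(
            f"{path}: required fingertip markers not found: {missing}"
        )
    return Trial(
        participant_id=str(md.get("participant_id", "P00")),
        block=int(md.get("block", 1)),
        condition=Condition(
            surface=md.get("surface", "matte"),
            content=md.get("content", "empty"),
            feedback=md.get("feedback", "visible"),
        ),
        trajectories=trajectories,
        landmarks=md.get("landmarks", {}),
        trial_id=str(md.get("trial_id", Path(path).stem)),
    )


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_trial_c3d(
    path: str | Path,
    marker_map: Mapping[str, str] | None = None,
    metadata: Mapping | None = None,
) -> Trial:
    """Read a trial from a standard C3D point file.

    ``marker_map`` maps the canonical fingertip names (thumb/index/middle)
    to the point labels used inside the file; identity by default.  Samples
    with a negative C3D residual are flagged invalid, per the format's
    convention.
    """
    from . import _c3d

    marker_map = dict(marker_map or {m: m for m in FINGER_MARKERS})
    data = _c3d.read_c3d(Path(path))
    labels = data.labels
    trajectories: dict[str, MarkerTrajectory] = {}
    n = data.points.shape[1]
    times = np.arange(n) * 1000.0 / data.rate
    label_index = {lab: i for i, lab in enumerate(labels)}
    for canonical, in_file in marker_map.items():
        if in_file not in label_index:
            raise MarkerMappingError(
                f"{path}: marker {in_file!r} (for {canonical!r}) not among "
                f"labels {labels}"
            )
        i = label_index[in_file]
        pos = data.points[i].copy()
        valid = data.residuals[i] >= 0
        pos[~valid] = np.nan
        trajectories[canonical] = MarkerTrajectory(
            canonical, times, pos, valid, data.rate
        )
    # carry along any unmapped labels under their own names
    mapped = set(marker_map.values())
    for lab, i in label_index.items():
        if lab in mapped or lab in trajectories:
            continue
        pos = data.points[i].copy()
        valid = data.residuals[i] >= 0
        pos[~valid] = np.nan
        trajectories[lab] = MarkerTrajectory(lab, times, pos, valid, data.rate)
    md = dict(metadata or {})
    return Trial(
        participant_id=str(md.get("participant_id", "P00")),
        block=int(md.get("block", 1)),
        condition=Condition(
            surface=md.get("surface", "matte"),
            content=md.get("content", "empty"),
            feedback=md.get("feedback", "visible"),
        ),
        trajectories=trajectories,
        landmarks=md.get("landmarks", {}),
        trial_id=str(md.get("trial_id", Path(path).stem)),
    )


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def _invalid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of False in ``mask``."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(traj: MarkerTrajectory, max_gap: int = 5) -> MarkerTrajectory:
    """Linearly interpolate dropout runs of at most ``max_gap`` samples.

    A run is fillable only when flanked by valid samples on both sides;
    gaps touching either end of the recording, and runs longer than
    ``max_gap``, are left invalid.  Valid samples are never modified.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not traj.valid_mask.any():
        raise UnusableTrajectoryError(
            f"marker {traj.marker_id!r}: no valid samples at all"
        )
    out = traj.copy()
    for start, stop in _invalid_runs(traj.valid_mask):
        if stop - start > max_gap or start == 0 or stop == len(traj):
            continue
        left, right = start - 1, stop
        p0, p1 = traj.positions[left], traj.positions[right]
        # fractional position of each gap sample between the flanking samples
        frac = (np.arange(start, stop) - left) / (right - left)
        out.positions[start:stop] = p0 + frac[:, None] * (p1 - p0)
        out.valid_mask[start:stop] = True
    return out


# ---------------------------------------------------------------------------
# Derived trajectories and manifests
# ---------------------------------------------------------------------------

def grip_center(trial: Trial) -> MarkerTrajectory:
    """Mean of the thumb/index/middle fingertip positions per sample.

    The grip-center point drives movement segmentation (a symmetric proxy for
    "the hand") and its vertical coordinate at contact defines grip placement.
    A sample is valid only where all three fingertips are valid.
    """
    thumb, index, middle = trial.fingers()
    valid = thumb.valid_mask & index.valid_mask & middle.valid_mask
    pos = (thumb.positions + index.positions + middle.positions) / 3.0
    pos = np.where(valid[:, None], pos, np.nan)
    return MarkerTrajectory(
        "grip_center", thumb.times, pos, valid, thumb.sample_rate
    )


MANIFEST_COLUMNS = [
    "trial_id", "file", "participant_id", "block",
    "surface", "content", "feedback",
]


def write_manifest(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write the flat one-row-per-trial metadata manifest as CSV."""
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    return df
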