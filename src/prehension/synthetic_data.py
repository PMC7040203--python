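"""Synthetic reach-and-transport trials and ordinal ratings with known truth.

The generator emulates the study design: each participant performs 5 blocks
of 8 trials, one per cell of the 2x2x2 surface x content x feedback
factorial, reaching 400 mm to pick up a paper cup at location A and
transporting it 400 mm to location B, sampled at 100 Hz.

Kinematic family
----------------
The grip-center path of a reach is two half-minimum-jerk pieces joined at
the velocity peak: an acceleration piece of duration ``t1`` and a
(typically longer) deceleration piece of duration ``t2``, with the speed
continuous at the junction and zero at both ends.  This family fixes the
peak speed at ``1.875 * D / T`` (D amplitude, T = t1 + t2) for any split,
and makes the deceleration fraction — hence the adjustment time — directly
injectable.  The transport is a symmetric minimum-jerk whose duration is
chosen to produce the configured transport peak velocity.

Because movement boundaries are *measured* by the 30 mm/s threshold rule,
the profile's sub-threshold tails are clipped from every measured duration.
The generator therefore calibrates the internal profile (closed form plus a
short fixed point) so that the measured duration and adjustment time on the
noise-free profile equal the configured targets; configured means are thus
directly comparable to the analysis output.

The grip aperture rises from a resting opening to its configured maximum at
the configured fraction of the measured reach and closes to the cup
diameter at the grasp height; fingertips sit at plus/minus half the
aperture across the grip center, so the aperture never perturbs grip-center
kinematics.  Grip height is the cup COM plus the configured signed
deviation.  Gaussian marker noise and contiguous dropout runs (geometric
lengths) are applied last.

Every dataset carries a ground-truth table (threshold-rule boundaries of
the noise-free profile, true feature values, subject effects) that the
analysis path never sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grasp_geometry import CupSpec, LiquidSpec
from .mocap_io import (
    Condition,
    MarkerTrajectory,
    RatingRecord,
    Trial,
    write_manifest,
    write_trial_tsv,
)

__all__ = [
    "SimulationConfig",
    "TrialParams",
    "RatingsConfig",
    "simulate_reach",
    "simulate_dataset",
    "simulate_feature_table",
    "simulate_ratings",
    "write_dataset",
    "calibrate_reach_profile",
]

CONTENTS = ("empty", "filled")
SURFACES = ("matte", "shiny")
FEEDBACKS = ("visible", "hidden")


def _minjerk_pos(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the trial generator.

    Per-content targets default to the reference experiment's reported condition means: measured
    reach duration and adjustment time (ms), transport peak velocity (mm/s),
    MGA size (mm) and relative timing (%), and signed grip deviation (mm).
    ``subject_sd``/``trial_sd`` give the random-intercept and residual
    spreads of each feature.  The deceleration fraction of a reach is the
    adjustment/duration ratio implied by the two targets.
    """

    n_participants: int = 14
    n_blocks: int = 5
    sample_rate: float = 100.0
    reach_amplitude: float = 400.0  # mm, start -> A
    transport_amplitude: float = 400.0  # mm, A -> B
    velocity_threshold: float = 30.0  # mm/s, mirrored from segmentation
    min_run: int = 10

    reach_duration_ms: Mapping[str, float] = field(
        default_factory=lambda: {"empty": 1400.0, "filled": 1640.0}
    )
    adjustment_ms: Mapping[str, float] = field(
        default_factory=lambda: {"empty": 881.0, "filled": 1024.0}
    )
    transport_peak: Mapping[str, float] = field(
        default_factory=lambda: {"empty": 834.01, "filled": 657.46}
    )
    mga_rel: Mapping[str, float] = field(
        default_factory=lambda: {"empty": 66.78, "filled": 61.67}
    )
    mga_mm: float = 119.61
    grip_deviation_mm: Mapping[str, float] = field(
        default_factory=lambda: {"empty": 8.0, "filled": -16.57}
    )

    subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "duration": 90.0, "adjustment": 70.0, "transport_peak": 60.0,
            "mga_rel": 3.0, "mga": 8.0, "deviation": 4.0,
        }
    )
    trial_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "duration": 150.0, "adjustment": 110.0, "transport_peak": 90.0,
            "mga_rel": 5.0, "mga": 10.0, "deviation": 6.0,
        }
    )

    marker_noise_sd: float = 0.15  # mm, per axis
    dropout_rate: float = 0.002  # per-sample probability a dropout run starts
    dropout_mean_len: float = 3.0  # samples, geometric

    rest_pre_ms: float = 300.0
    dwell_ms: float = 400.0
    rest_post_ms: float = 300.0
    aperture_rest_mm: float = 40.0

    seed: int = 0

    def __post_init__(self) -> None:
        for c in CONTENTS:
            dur, adj = self.reach_duration_ms[c], self.adjustment_ms[c]
            if not 0 < adj < dur:
                raise ValueError(f"adjustment must lie inside the reach duration ({c})")
            if not 0 < self.mga_rel[c] <= 100:
                raise ValueError("mga_rel must be a percentage in (0, 100]")
            if self.transport_peak[c] <= self.velocity_threshold:
                raise ValueError("transport peak must exceed the threshold")
        if any(v < 0 for v in self.subject_sd.values()):
            raise ValueError("subject SDs must be non-negative")
        if any(v < 0 for v in self.trial_sd.values()):
            raise ValueError("trial SDs must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    def decel_fraction(self, content: str) -> float:
        """Fraction of the measured reach after the velocity peak."""
        return self.adjustment_ms[content] / self.reach_duration_ms[content]

    def null(self) -> "SimulationConfig":
        """Same marginals, all condition effects removed (null generator)."""

        def pooled(m: Mapping[str, float]) -> dict:
            v = float(np.mean(list(m.values())))
            return {c: v for c in CONTENTS}

        return replace(
            self,
            reach_duration_ms=pooled(self.reach_duration_ms),
            adjustment_ms=pooled(self.adjustment_ms),
            transport_peak=pooled(self.transport_peak),
            mga_rel=pooled(self.mga_rel),
            grip_deviation_mm=pooled(self.grip_deviation_mm),
        )

    def cup_for(self, content: str) -> CupSpec:
        return CupSpec.filled() if content == "filled" else CupSpec()


@dataclass(frozen=True)
class TrialParams:
    """Resolved per-trial targets (condition means + random effects)."""

    participant_id: str
    block: int
    condition: Condition
    duration_ms: float
    adjustment_ms: float
    transport_peak: float
    mga_mm: float
    mga_rel: float
    deviation_mm: float
    cup: CupSpec
    trial_id: str = ""


def calibrate_reach_profile(
    duration_ms: float,
    adjustment_ms: float,
    amplitude_mm: float,
    threshold_mms: float,
) -> dict:
    """Internal profile times whose threshold-measured spans hit the targets.

    With peak speed ``v_p = 1875 * D / T_ms`` and the half-min-jerk speed
    shape ``v(u) = v_p * 16 u^2 (1-u)^2``, the threshold crossing sits at
    ``u* = (1 - sqrt(1 - 4 g)) / 2`` with ``g = sqrt(thr / (16 v_p))``, so
    measured duration is ``T (1 - 2 u*)`` and measured adjustment
    ``t2 (1 - 2 u*)``.  Solved for T by a short fixed point.
    """
    if not 0 < adjustment_ms < duration_ms:
        raise ValueError("adjustment time must lie inside the duration")

    def ustar(T: float) -> float:
        v_p = 1875.0 * amplitude_mm / T
        g = math.sqrt(threshold_mms / (16.0 * v_p))
        if 4 * g >= 1:
            raise ValueError(
                "profile never clears the velocity threshold; duration too long "
                "for the amplitude"
            )
        return (1.0 - math.sqrt(1.0 - 4.0 * g)) / 2.0

    T = duration_ms
    for _ in range(12):
        T = duration_ms / (1.0 - 2.0 * ustar(T))
    u = ustar(T)
    t2 = adjustment_ms / (1.0 - 2.0 * u)
    t1 = T - t2
    if t1 <= 0:
        raise ValueError("adjustment target incompatible with duration target")
    return {
        "T": T, "t1": t1, "t2": t2, "ustar": u,
        "v_peak": 1875.0 * amplitude_mm / T,
        "t_on": 2.0 * t1 * u, "t_off": T - 2.0 * t2 * u,
    }


def _reach_position(t: np.ndarray, prof: dict, amplitude: float) -> np.ndarray:
    """Distance along the reach axis at times ``t`` (ms from motion start)."""
    T, t1, t2 = prof["T"], prof["t1"], prof["t2"]
    d1 = amplitude * t1 / T
    d2 = amplitude * t2 / T
    s = np.empty_like(t, dtype=float)
    acc = t <= t1
    u = np.clip(t[acc] / (2.0 * t1), 0.0, 0.5)
    s[acc] = 2.0 * d1 * _minjerk_pos(u)
    u = np.clip(0.5 + (t[~acc] - t1) / (2.0 * t2), 0.5, 1.0)
    s[~acc] = d1 + 2.0 * d2 * (_minjerk_pos(u) - 0.5)
    return s


def _aperture_profile(
    t: np.ndarray,
    t_on: float,
    t_peak: float,
    t_end: float,
    a_rest: float,
    a_peak: float,
    a_grasp: float,
) -> np.ndarray:
    """Smooth rest -> peak -> grasp aperture; unique maximum at ``t_peak``.

    Raised-cosine pieces: zero slope at both ends of each piece but nonzero
    curvature at the peak, so the maximum stays well-defined under marker
    noise (a flatter profile would let noise carry the argmax far along the
    plateau).
    """
    shape = lambda u: 0.5 * (1.0 - np.cos(np.pi * u))
    a = np.full_like(t, a_rest, dtype=float)
    rise = (t > t_on) & (t <= t_peak)
    u = (t[rise] - t_on) / (t_peak - t_on)
    a[rise] = a_rest + (a_peak - a_rest) * shape(u)
    close = (t > t_peak) & (t <= t_end)
    u = (t[close] - t_peak) / (t_end - t_peak)
    a[close] = a_peak + (a_grasp - a_peak) * shape(u)
    a[t > t_end] = a_grasp
    return a


def simulate_reach(
    params: TrialParams, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[Trial, dict]:
    """One full trial (rest, reach, dwell, transport, rest) plus ground truth.

    Returns the :class:`~prehension.mocap_io.Trial` (noise and dropouts
    applied per config) and a dict of noise-free ground-truth features.
    """
    dt = 1000.0 / cfg.sample_rate
    prof = calibrate_reach_profile(
        params.duration_ms, params.adjustment_ms,
        cfg.reach_amplitude, cfg.velocity_threshold,
    )
    T_reach = prof["T"]
    T_trans = 1875.0 * cfg.transport_amplitude / params.transport_peak

    n_pre = int(round(cfg.rest_pre_ms / dt))
    n_reach = int(math.ceil(T_reach / dt)) + 1
    n_dwell = int(round(cfg.dwell_ms / dt))
    n_trans = int(math.ceil(T_trans / dt)) + 1
    n_post = int(round(cfg.rest_post_ms / dt))
    n = n_pre + n_reach + n_dwell + n_trans + n_post

    start = np.asarray([0.0, 0.0, 0.0])
    a_pos = np.asarray([cfg.reach_amplitude, 0.0, 0.0])
    b_pos = np.asarray([cfg.reach_amplitude, cfg.transport_amplitude, 0.0])
    grip_z = params.cup.base_z + params.cup.com() + params.deviation_mm

    center = np.empty((n, 3))
    center[:, :] = start
    center[:, 2] = grip_z

    # reach along +X
    i0 = n_pre
    t_reach = np.arange(n_reach) * dt
    center[i0 : i0 + n_reach, 0] = np.minimum(
        _reach_position(np.minimum(t_reach, T_reach), prof, cfg.reach_amplitude),
        cfg.reach_amplitude,
    )
    center[i0 + n_reach :, 0] = cfg.reach_amplitude
    # transport along +Y
    j0 = n_pre + n_reach + n_dwell
    t_trans = np.arange(n_trans) * dt
    center[j0 : j0 + n_trans, 1] = cfg.transport_amplitude * _minjerk_pos(
        np.clip(t_trans / T_trans, 0.0, 1.0)
    )
    center[j0 + n_trans :, 1] = cfg.transport_amplitude

    # ground-truth movement boundaries under the threshold rule (noise-free)
    on_idx = i0 + int(math.ceil(prof["t_on"] / dt))
    off_idx = i0 + int(math.ceil(prof["t_off"] / dt))
    peak_idx = i0 + int(round(prof["t1"] / dt))

    # aperture: timing expressed on the measured reach span
    t = np.arange(n) * dt
    t_on_abs = on_idx * dt
    t_off_abs = off_idx * dt
    t_peak_abs = t_on_abs + params.mga_rel / 100.0 * (t_off_abs - t_on_abs)
    a_grasp = 2.0 * params.cup.radius_at(
        min(max(grip_z - params.cup.base_z, 0.0), params.cup.h_cup)
    )
    a_peak = max(params.mga_mm, a_grasp + 5.0)
    aperture = _aperture_profile(
        t, t_on_abs, t_peak_abs, i0 * dt + T_reach,
        cfg.aperture_rest_mm, a_peak, a_grasp,
    )

    ey = np.asarray([0.0, 1.0, 0.0])
    thumb_pos = center - 0.5 * aperture[:, None] * ey
    index_pos = center + 0.5 * aperture[:, None] * ey
    middle_pos = center + np.asarray([20.0, 0.0, 0.0])

    # ground-truth MGA on the sampled (noise-free) aperture, so that the
    # analysis of a noise-free trial reproduces it exactly
    reach_ap = aperture[on_idx:off_idx]
    k_true = int(np.argmax(reach_ap))

    truth = {
        "trial_id": params.trial_id,
        "true_reach_onset_idx": on_idx,
        "true_reach_offset_idx": off_idx,
        "true_peak_idx": peak_idx,
        "true_duration_ms": (off_idx - on_idx) * dt,
        "true_adjustment_ms": (off_idx - peak_idx) * dt,
        "true_reach_peak": prof["v_peak"],
        "true_transport_peak": params.transport_peak,
        "true_mga": float(reach_ap[k_true]),
        "true_mga_rel": 100.0 * k_true / (off_idx - on_idx),
        "true_deviation": params.deviation_mm,
        "true_com": params.cup.com(),
    }

    times = t
    trajectories = {}
    for name, pos in (("thumb", thumb_pos), ("index", index_pos), ("middle", middle_pos)):
        pos = pos.copy()
        valid = np.ones(n, dtype=bool)
        if cfg.marker_noise_sd > 0:
            pos += rng.normal(0.0, cfg.marker_noise_sd, size=pos.shape)
        if cfg.dropout_rate > 0:
            starts = np.flatnonzero(rng.random(n) < cfg.dropout_rate)
            for s in starts:
                length = rng.geometric(1.0 / cfg.dropout_mean_len)
                valid[s : s + length] = False
            pos[~valid] = np.nan
        trajectories[name] = MarkerTrajectory(name, times, pos, valid, cfg.sample_rate)

    trial = Trial(
        participant_id=params.participant_id,
        block=params.block,
        condition=params.condition,
        trajectories=trajectories,
        landmarks={"start": start, "A": a_pos, "B": b_pos},
        trial_id=params.trial_id,
    )
    return trial, truth


def _subject_effects(cfg: SimulationConfig, subj: int) -> dict:
    rng = np.random.default_rng([cfg.seed, 1_000_000 + subj])
    return {k: rng.normal(0.0, sd) for k, sd in cfg.subject_sd.items()}


def _trial_params(
    cfg: SimulationConfig,
    subj: int,
    block: int,
    cond: Condition,
    eff: Mapping[str, float],
    rng: np.random.Generator,
) -> TrialParams:
    c = cond.content
    dur = cfg.reach_duration_ms[c] + eff["duration"] + rng.normal(0, cfg.trial_sd["duration"])
    adj = cfg.adjustment_ms[c] + eff["adjustment"] + rng.normal(0, cfg.trial_sd["adjustment"])
    dur = max(dur, 600.0)
    adj = float(np.clip(adj, 0.25 * dur, 0.90 * dur))
    tpk = cfg.transport_peak[c] + eff["transport_peak"] + rng.normal(0, cfg.trial_sd["transport_peak"])
    tpk = max(tpk, 5.0 * cfg.velocity_threshold)
    rel = cfg.mga_rel[c] + eff["mga_rel"] + rng.normal(0, cfg.trial_sd["mga_rel"])
    rel = float(np.clip(rel, 15.0, 95.0))
    mga = cfg.mga_mm + eff["mga"] + rng.normal(0, cfg.trial_sd["mga"])
    dev = cfg.grip_deviation_mm[c] + eff["deviation"] + rng.normal(0, cfg.trial_sd["deviation"])
    pid = f"P{subj + 1:02d}"
    return TrialParams(
        participant_id=pid,
        block=block,
        condition=cond,
        duration_ms=dur,
        adjustment_ms=adj,
        transport_peak=tpk,
        mga_mm=mga,
        mga_rel=rel,
        deviation_mm=dev,
        cup=cfg.cup_for(c),
        trial_id=f"{pid}_b{block}_{cond.surface[0]}{cond.content[0]}{cond.feedback[0]}",
    )


def _condition_cells() -> list[Condition]:
    return [
        Condition(surface=s, content=c, feedback=f)
        for s in SURFACES for c in CONTENTS for f in FEEDBACKS
    ]


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[Trial], pd.DataFrame, pd.DataFrame]:
    """Full factorial dataset: trials, ground truth, and metadata manifest.

    ``n_participants x n_blocks x 8`` trials; per-subject random intercepts
    on every feature; all randomness flows from ``cfg.seed`` via per-trial
    counter-derived substreams, so any subset regenerates identically.
    """
    trials: list[Trial] = []
    truths: list[dict] = []
    manifest: list[dict] = []
    cells = _condition_cells()
    for subj in range(cfg.n_participants):
        eff = _subject_effects(cfg, subj)
        for block in range(1, cfg.n_blocks + 1):
            for ci, cond in enumerate(cells):
                rng = np.random.default_rng([cfg.seed, subj, block, ci])
                params = _trial_params(cfg, subj, block, cond, eff, rng)
                trial, truth = simulate_reach(params, cfg, rng)
                trials.append(trial)
                truth.update(
                    participant_id=params.participant_id, block=block,
                    **cond.as_dict(),
                )
                truths.append(truth)
                manifest.append(
                    {
                        "trial_id": trial.trial_id,
                        "file": f"{trial.trial_id}.tsv",
                        "participant_id": trial.participant_id,
                        "block": block,
                        **cond.as_dict(),
                    }
                )
    return trials, pd.DataFrame(truths), pd.DataFrame(manifest)


def simulate_feature_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample measured features directly from the generative feature model.

    Skips trajectory synthesis entirely: each trial's features are the
    condition target plus its subject intercept plus trial noise — exactly
    the distribution the trajectory route realises (the trajectory layer
    adds only sub-frame discretisation error).  Used for statistical
    calibration studies where thousands of replicate datasets are needed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cells = _condition_cells()
    rows = []
    for subj in range(cfg.n_participants):
        eff = {k: rng.normal(0.0, sd) for k, sd in cfg.subject_sd.items()}
        for block in range(1, cfg.n_blocks + 1):
            for cond in cells:
                c = cond.content
                rows.append(
                    {
                        "participant_id": f"P{subj + 1:02d}",
                        "block": block,
                        **cond.as_dict(),
                        "adjustment_time_ms": cfg.adjustment_ms[c]
                        + eff["adjustment"]
                        + rng.normal(0, cfg.trial_sd["adjustment"]),
                        "transport_peak_velocity": cfg.transport_peak[c]
                        + eff["transport_peak"]
                        + rng.normal(0, cfg.trial_sd["transport_peak"]),
                        "mga_time_rel": cfg.mga_rel[c]
                        + eff["mga_rel"]
                        + rng.normal(0, cfg.trial_sd["mga_rel"]),
                        "mga": cfg.mga_mm + eff["mga"] + rng.normal(0, cfg.trial_sd["mga"]),
                        "grip_deviation": cfg.grip_deviation_mm[c]
                        + eff["deviation"]
                        + rng.normal(0, cfg.trial_sd["deviation"]),
                    }
                )
    return pd.DataFrame(rows)


def write_dataset(
    trials: list[Trial],
    truth: pd.DataFrame,
    manifest: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write TSV trials plus manifest and ground-truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial_tsv(trial, outdir / f"{trial.trial_id}.tsv")
    write_manifest(manifest.to_dict("records"), outdir / "manifest.csv")
    truth.to_csv(outdir / "ground_truth.csv", index=False)


# ---------------------------------------------------------------------------
# Ordinal ratings
# ---------------------------------------------------------------------------

#: Default latent-scale effects per rated dimension (logit scale), taken from
#: the study's fitted coefficients: content drives heaviness and hardness,
#: surface drives glossiness overwhelmingly.
DEFAULT_RATING_EFFECTS: dict[str, dict[str, float]] = {
    "heaviness": {"content": 1.98, "surface": 0.36},
    "hardness": {"content": 1.41, "surface": 0.63},
    "glossiness": {"content": 0.13, "surface": 6.89},
}

#: Six ordered thresholds for the 7-point scale, symmetric about zero.
DEFAULT_THRESHOLDS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass(frozen=True)
class RatingsConfig:
    n_participants: int = 14
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATING_EFFECTS.items()}
    )
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    subject_sd: float = 1.0
    phase: str = "pre"

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if th.size != 6 or np.any(np.diff(th) <= 0):
            raise ValueError("need 6 strictly increasing thresholds for a 7-point scale")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")


def simulate_ratings(
    cfg: RatingsConfig, rng: np.random.Generator
) -> list[RatingRecord]:
    """Draw 7-point ratings from a cumulative-link generative model.

    Latent value = effects . covariates + subject intercept + standard
    logistic noise; the observed category is the latent value binned by the
    ordered thresholds.  Covariates are coded shiny=1/matte=0 and
    filled=1/empty=0; each participant rates all 8 stimuli on each
    dimension.
    """
    th = np.asarray(cfg.thresholds, dtype=float)
    records: list[RatingRecord] = []
    cells = _condition_cells()
    for subj in range(cfg.n_participants):
        pid = f"P{subj + 1:02d}"
        b_subj = rng.normal(0.0, cfg.subject_sd)
        for dim, eff in cfg.effects.items():
            for cond in cells:
                x_surface = 1.0 if cond.surface == "shiny" else 0.0
                x_content = 1.0 if cond.content == "filled" else 0.0
                latent = (
                    eff.get("surface", 0.0) * x_surface
                    + eff.get("content", 0.0) * x_content
                    + b_subj
                    + rng.logistic(0.0, 1.0)
                )
                value = 1 + int(np.searchsorted(th, latent, side="left"))
                records.append(
                    RatingRecord(
                        participant_id=pid,
                        stimulus_id=f"{cond.surface[0]}{cond.content[0]}{cond.feedback[0]}",
                        dimension=dim,
                        phase=cfg.phase,
                        value=value,
                    )
                )
    return records
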