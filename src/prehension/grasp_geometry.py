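"""Grip-aperture features, grip-center placement, and cup center of mass.

The object is a conical-frustum paper cup (base radius ``r1``, top radius
``r2``, height ``h``).  Its vertical center of mass, measured from the
base, is the solid-frustum centroid

    COM = h (r1^2 + 2 r1 r2 + 3 r2^2) / (4 (r1^2 + r1 r2 + r2^2)),

and for a cup holding liquid the cup and liquid centroids are combined by a
mass-weighted mean.  The solid-centroid model is applied to the (hollow)
cup deliberately: the analysis convention is the geometric frustum
centroid, and outer radii stand in for the unspecified wall profile.

Grasp features: the maximum grip aperture (MGA) is the largest thumb-index
distance during the reach, before object contact; the grip center is the
mean vertical (z) position of thumb, index and middle fingertips at
contact; grip deviation is the signed vertical distance of the grip center
from the object's COM (positive above, negative below).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kinematics import MovementSegment
from .mocap_io import MarkerTrajectory

__all__ = [
    "CupSpec",
    "LiquidSpec",
    "GraspFeatures",
    "frustum_centroid",
    "combined_com",
    "aperture_series",
    "mga_features",
    "grip_features",
]


def frustum_centroid(h: float, r1: float, r2: float) -> float:
    """Centroid height of a solid conical frustum, measured from the base.

    ``r1`` is the radius at the base, ``r2`` at the top.  For ``r1 == r2``
    (a cylinder) this is ``h/2``; for ``r1 == 0`` (a cone standing on its
    apex) it is ``0.75 h``.
    """
    if h <= 0:
        raise ValueError("frustum height must be positive")
    if r1 < 0 or r2 < 0 or (r1 == 0 and r2 == 0):
        raise ValueError("radii must be non-negative and not both zero")
    num = h * (r1 * r1 + 2.0 * r1 * r2 + 3.0 * r2 * r2)
    den = 4.0 * (r1 * r1 + r1 * r2 + r2 * r2)
    return num / den


def combined_com(
    com_cup: float, m_cup: float, com_liquid: float, m_liquid: float
) -> float:
    """Mass-weighted COM of the cup-plus-liquid system (mm from base)."""
    if m_cup < 0 or m_liquid < 0:
        raise ValueError("masses must be non-negative")
    total = m_cup + m_liquid
    if total <= 0:
        raise ValueError("total mass must be positive")
    if m_liquid == 0:
        return com_cup
    return (m_liquid * com_liquid + m_cup * com_cup) / total


@dataclass(frozen=True)
class LiquidSpec:
    """Liquid column inside the cup: fill height (mm) and mass (g)."""

    h_liquid: float
    m_liquid: float

    def __post_init__(self) -> None:
        if self.h_liquid <= 0 or self.m_liquid < 0:
            raise ValueError("liquid height must be positive, mass non-negative")


@dataclass(frozen=True)
class CupSpec:
    """Cup geometry and masses.

    Defaults describe the study cup: 114 mm tall, 57 mm outer diameter at
    the base and 87 mm at the top, 11 g empty.  The filled cup adds 241 g
    of liquid; its fill height is an explicit input (default 82 mm — the
    value at which the combined COM reproduces the reported 46 mm; the
    liquid height is not derivable from the printed masses, see the methods
    note).  ``base_z`` locates the cup base on the trial's vertical axis.
    """

    h_cup: float = 114.0
    r1: float = 28.5
    r2: float = 43.5
    m_cup: float = 11.0
    liquid: Optional[LiquidSpec] = None
    base_z: float = 0.0

    DEFAULT_LIQUID_HEIGHT = 82.0
    DEFAULT_LIQUID_MASS = 241.0  # 252 g filled minus 11 g cup

    def __post_init__(self) -> None:
        if self.h_cup <= 0 or self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("cup dimensions must be positive")
        if self.m_cup < 0:
            raise ValueError("cup mass must be non-negative")
        if self.liquid is not None and self.liquid.h_liquid > self.h_cup:
            raise ValueError("liquid cannot stand taller than the cup")

    @classmethod
    def filled(cls, **kwargs) -> "CupSpec":
        """The study cup holding its liquid load."""
        kwargs.setdefault(
            "liquid",
            LiquidSpec(cls.DEFAULT_LIQUID_HEIGHT, cls.DEFAULT_LIQUID_MASS),
        )
        return cls(**kwargs)

    def radius_at(self, z: float) -> float:
        """Interior taper: linear interpolation of the radius at height z."""
        return self.r1 + (self.r2 - self.r1) * z / self.h_cup

    def com(self) -> float:
        """Vertical COM (mm from the base) of the cup-plus-content system."""
        com_cup = frustum_centroid(self.h_cup, self.r1, self.r2)
        if self.liquid is None or self.liquid.m_liquid == 0:
            return com_cup
        h_l = self.liquid.h_liquid
        com_liq = frustum_centroid(h_l, self.r1, self.radius_at(h_l))
        return combined_com(com_cup, self.m_cup, com_liq, self.liquid.m_liquid)


@dataclass
class GraspFeatures:
    """Grasp-related features of one trial."""

    mga: float  # mm
    mga_time_abs_ms: float  # from reach onset
    mga_time_rel: float  # % of reach duration
    grip_center_z: float  # mm, world frame
    com: float  # mm from cup base
    grip_deviation: float  # mm, signed: + above COM, - below


def aperture_series(
    thumb: MarkerTrajectory,
    index: MarkerTrajectory,
    window: tuple[int, int],
) -> np.ndarray:
    """Thumb-index 3-D distance (mm) per sample over ``[start, stop)``."""
    start, stop = window
    if not (0 <= start < stop <= len(thumb)) or stop > len(index):
        raise ValueError(f"window {window} outside trajectory extent")
    if not (thumb.valid_mask[start:stop].all() and index.valid_mask[start:stop].all()):
        raise ValueError("aperture window contains untracked samples")
    diff = thumb.positions[start:stop] - index.positions[start:stop]
    return np.linalg.norm(diff, axis=1)


def mga_features(aperture: np.ndarray, reach: MovementSegment) -> dict:
    """Maximum grip aperture and its absolute/relative timing.

    ``aperture`` must cover exactly ``[reach.onset_idx, reach.offset_idx)``.
    Ties in the maximum go to the earliest sample.
    """
    aperture = np.asarray(aperture, dtype=float)
    n = reach.offset_idx - reach.onset_idx
    if aperture.size != n:
        raise ValueError(
            f"aperture length {aperture.size} != reach span {n}"
        )
    if aperture.size == 0:
        raise ValueError("empty aperture window")
    k = int(np.argmax(aperture))
    mga = float(aperture[k])
    t_abs = k * reach.frame_period_ms
    return {
        "mga": mga,
        "mga_time_abs_ms": t_abs,
        "mga_time_rel": 100.0 * t_abs / reach.duration_ms,
    }


def grip_features(
    thumb: MarkerTrajectory,
    index: MarkerTrajectory,
    middle: MarkerTrajectory,
    contact_idx: int,
    cup: CupSpec,
) -> dict:
    """Grip-center height and signed deviation from the cup COM at contact.

    ``contact_idx`` is the reach offset sample (speed back below the
    segmentation threshold).  All three fingertips must be tracked there;
    no imputation is permitted at the measurement instant.
    """
    i = contact_idx
    for tr in (thumb, index, middle):
        if not (0 <= i < len(tr)):
            raise ValueError("contact index outside trajectory extent")
        if not tr.valid_mask[i]:
            raise ValueError(
                f"marker {tr.marker_id!r} untracked at the contact sample"
            )
    grip_z = float((thumb.positions[i, 2] + index.positions[i, 2] + middle.positions[i, 2]) / 3.0)
    com = cup.com()
    return {
        "grip_center_z": grip_z,
        "com": com,
        "grip_deviation": grip_z - (cup.base_z + com),
    }
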