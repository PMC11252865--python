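"""Residual-strain geometry: ring morphometry, opening angle, axial pre-stretch.

Closed ring morphometry assumes a circular cross-section: the inner radius
``IR`` follows from the inner perimeter and the wall thickness ``T`` is the
difference of outer and inner radii.  The ring-opening test quantifies
circumferential residual strain: after a radial cut the ring springs open
and its opening angle ``alpha`` is measured at the mid-inner-perimeter
vertex between rays to the mid-thickness points of the two cut ends.  The
pre-stretching test quantifies the physiological axial stretch: six
equidistant marks drawn on the vessel in vivo define five segments whose
in-vivo to ex-vivo length ratio is the axial pre-stretch ``lambda_Z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MalformedMarksError

__all__ = [
    "RingSpecimen",
    "OpenedRingLandmarks",
    "PrestretchMarks",
    "PrestretchProfile",
    "SEGMENT_BINS",
    "ring_morphometry",
    "opening_angle",
    "segment_lengths",
    "axial_prestretch",
]

SEGMENT_BINS = ("0-20%", "20-40%", "40-60%", "60-80%", "80-100%")
N_MARKS = 6


@dataclass(frozen=True)
class RingSpecimen:
    """Closed arterial ring described by its inner and outer perimeter (mm)."""

    inner_perimeter: float
    outer_perimeter: float
    region: str = "DTA"
    group: str = "Control"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.inner_perimeter < self.outer_perimeter:
            raise GeometryError(
                "ring requires 0 < inner perimeter < outer perimeter, got "
                f"{self.inner_perimeter} and {self.outer_perimeter}"
            )


@dataclass(frozen=True)
class OpenedRingLandmarks:
    """Planar landmarks (mm) of an opened ring.

    ``vertex`` is the midpoint of the wall's inner-radius perimeter;
    ``end_a``/``end_b`` are the mid-thickness points at the two cut ends.
    """

    vertex: tuple[float, float]
    end_a: tuple[float, float]
    end_b: tuple[float, float]

    def __post_init__(self) -> None:
        pts = (*self.vertex, *self.end_a, *self.end_b)
        if not all(math.isfinite(v) for v in pts):
            raise GeometryError("landmark coordinates must be finite")


@dataclass(frozen=True)
class PrestretchMarks:
    """Ordered arc-length positions (mm) of the six marks, in vivo and ex vivo."""

    in_vivo_positions: tuple
    ex_vivo_positions: tuple

    def __post_init__(self) -> None:
        for name, pos in (
            ("in_vivo", self.in_vivo_positions),
            ("ex_vivo", self.ex_vivo_positions),
        ):
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (N_MARKS,):
                raise MalformedMarksError(f"{name} needs exactly {N_MARKS} marks")
            if np.any(np.diff(arr) <= 0):
                raise MalformedMarksError(f"{name} positions must be strictly increasing")


@dataclass(frozen=True)
class PrestretchProfile:
    """Per-segment axial pre-stretch, ordered proximal (DTA) to distal (DAA)."""

    segment_bins: tuple = SEGMENT_BINS
    lambda_z: tuple = ()

    def as_dict(self) -> dict:
        return dict(zip(self.segment_bins, self.lambda_z))


def ring_morphometry(ring: RingSpecimen) -> tuple[float, float]:
    """Inner radius and wall thickness (mm) of a closed ring.

    Assumes a circular cross-section for both perimeters:
    ``IR = P_in / 2 pi`` and ``T = P_out / 2 pi - IR``.
    """
    ir = ring.inner_perimeter / (2.0 * math.pi)
    thickness = ring.outer_perimeter / (2.0 * math.pi) - ir
    return ir, thickness


def opening_angle(landmarks: OpenedRingLandmarks, allow_reflex: bool = False) -> float:
    """Opening angle alpha (degrees) at the vertex between the rays to the cut ends.

    The default range is [0, 180] degrees from the arccos of the normalised
    dot product; coincident cut ends (an uncut ring) give 0.  With
    ``allow_reflex`` the signed orientation of the two rays extends the
    range to [0, 360), which arterial opening angles do not normally need.
    """
    v = np.asarray(landmarks.vertex, dtype=float)
    u = np.asarray(landmarks.end_a, dtype=float) - v
    w = np.asarray(landmarks.end_b, dtype=float) - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu <= 0 or nw <= 0:
        raise GeometryError("cut-end landmark coincides with the vertex (zero-length ray)")
    cross = u[0] * w[1] - u[1] * w[0]
    dot = float(np.dot(u, w))
    # atan2 form of the arccos of the normalised dot product: exact range
    # [0, 180] and numerically stable near 0 and 180 degrees
    ang = math.degrees(math.atan2(abs(cross), dot))
    if allow_reflex and cross < 0:
        ang = 360.0 - ang
    return ang


def segment_lengths(positions) -> np.ndarray:
    """Lengths (mm) of the five segments between six ordered mark positions."""
    arr = np.asarray(positions, dtype=float)
    if arr.shape != (N_MARKS,):
        raise MalformedMarksError(f"expected {N_MARKS} mark positions, got {arr.shape}")
    lengths = np.diff(arr)
    if np.any(lengths <= 0):
        raise MalformedMarksError("mark positions must be strictly increasing")
    return lengths


def axial_prestretch(marks: PrestretchMarks) -> PrestretchProfile:
    """Per-segment axial pre-stretch lambda_Z = l_in-vivo / l_ex-vivo.

    Segment bins (0-20% ... 80-100% of the in-vivo mark span) are assigned
    from the in-vivo relative position of each segment midpoint; with
    roughly equidistant marks this is the identity ordering, and it falls
    back to the ordinal ordering if midpoint binning would collide.
    """
    in_vivo = np.asarray(marks.in_vivo_positions, dtype=float)
    ex_vivo = np.asarray(marks.ex_vivo_positions, dtype=float)
    l_in = segment_lengths(in_vivo)
    l_ex = segment_lengths(ex_vivo)
    if np.any(l_ex <= 0):
        raise GeometryError("zero or negative ex-vivo segment length")
    lam = l_in / l_ex

    span = in_vivo[-1] - in_vivo[0]
    mids = (in_vivo[:-1] + in_vivo[1:]) / 2.0
    rel = (mids - in_vivo[0]) / span
    bins = np.clip(np.floor(rel * 5).astype(int), 0, 4)
    if sorted(bins) != [0, 1, 2, 3, 4]:
        bins = np.arange(5)  # irregular spacing: keep ordinal assignment
    ordered = np.empty(5, dtype=float)
    ordered[bins] = lam
    return PrestretchProfile(segment_bins=SEGMENT_BINS, lambda_z=tuple(ordered))
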