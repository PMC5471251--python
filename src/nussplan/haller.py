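"""Haller-index morphometry.

The Haller index H = A/B is the standard severity measure for pectus
excavatum: A is the maximum laterolateral inner chest-wall distance and B
the minimum anteroposterior distance from the anterior vertebral body to
the posterior sternal surface, both read off an axial cross section.  Two
derived quantities drive the bar design: the post-/pre-operative transverse
shrinkage rate A'/A (clinically ~0.95) and the orthopedic distance
delta = B' - B, the sternal elevation required to reach a target B'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, LandmarkError, ParameterError
from .geometry import CrossSectionContour


@dataclass(frozen=True)
class HallerMeasurement:
    """A, B and their ratio H at one cross section (A, B in mm)."""

    A: float
    B: float

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ParameterError("A and B must be positive")

    @property
    def H(self) -> float:
        return self.A / self.B

    def rounded(self, ndigits: int = 2) -> float:
        """H rounded half-even to the precision of clinical tables."""
        return round(self.H, ndigits)


@dataclass(frozen=True)
class ShrinkageRecord:
    """Pre-/post-operative transverse diameter pair, mm."""

    A_pre: float
    A_post: float

    def __post_init__(self):
        if self.A_pre <= 0 or self.A_post <= 0:
            raise ParameterError("diameters must be positive")
        if not 0.0 < self.rate <= 1.05:
            raise ParameterError(f"implausible shrinkage rate {self.rate:.3f}")

    @property
    def rate(self) -> float:
        return self.A_post / self.A_pre


@dataclass(frozen=True)
class OrthopedicDistance:
    """Pre-operative and target anteroposterior distances, mm."""

    B_pre: float
    B_target: float

    @property
    def delta(self) -> float:
        return self.B_target - self.B_pre


def transverse_diameter(contour: CrossSectionContour) -> float:
    """Maximum laterolateral extent A of a contour, mm."""
    x = contour.points[:, 0]
    a = float(x.max() - x.min())
    if a <= 1e-9:
        raise GeometryError("degenerate contour: zero laterolateral extent")
    return a


def anteroposterior_distance(contour: CrossSectionContour) -> float:
    """Anteroposterior distance B between the contour landmarks, mm.

    Measured along the y axis only (pure anteroposterior), from the
    anterior-most vertebral point to the posterior sternal surface.
    """
    yv = contour.points[contour.vertebra_anterior_idx, 1]
    ys = contour.points[contour.sternum_posterior_idx, 1]
    b = float(ys - yv)
    if b <= 0:
        raise LandmarkError("landmarks reversed: sternum must be anterior "
                            "to the vertebra")
    return b


def measure(contour: CrossSectionContour) -> HallerMeasurement:
    """A, B and H of one contour."""
    return HallerMeasurement(A=transverse_diameter(contour),
                             B=anteroposterior_distance(contour))


def haller_index(A: float, B: float) -> float:
    """Haller index H = A/B (both arguments in mm)."""
    if A <= 0 or B <= 0:
        raise ParameterError("A and B must be positive")
    return A / B


def shrinkage_rate(A_pre: float, A_post: float) -> float:
    """Post-/pre-operative transverse shrinkage rate A'/A."""
    if A_pre <= 0 or A_post <= 0:
        raise ParameterError("diameters must be positive")
    return A_post / A_pre


def orthopedic_distance(B_pre: float, B_target: float) -> float:
    """Orthopedic distance delta = B' - B, mm (negative if hypercorrected)."""
    if B_pre <= 0 or B_target <= 0:
        raise ParameterError("distances must be positive")
    return B_target - B_pre


def measure_all(contours) -> dict[str, HallerMeasurement]:
    """Measure a collection of contours, keyed by section level."""
    out: dict[str, HallerMeasurement] = {}
    for c in contours:
        out[c.level] = measure(c)
    return out
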