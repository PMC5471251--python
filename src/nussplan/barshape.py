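"""Convex Nuss-bar curve design.

A healthy anterior chest-wall boundary is (to measurement noise) a convex
curve with positive curvature, while a pectus-excavatum boundary shows a
sign-changing curvature profile at the depression.  The bar working shape
is therefore designed as a convex spline: the matched healthy reference
boundary over the bar span, raised at the apex by the orthopedic distance
delta, with convexity enforced as a hard constraint and the span rounded up
to a standard catalogue length.

Curvature sign convention: positive where the curve is convex toward the
anterior (+y) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .errors import (CatalogueError, GeometryError, InfeasibleDesignError,
                     NoMatchError, ParameterError)

#: curvature tolerance below which a curve still counts as convex, mm^-1
CONVEXITY_TOL = 1e-6

#: standard Nuss-bar lengths, 7"-13" in 1" steps, mm
DEFAULT_CATALOGUE = tuple(round(25.4 * n, 1) for n in range(7, 14))


# ---------------------------------------------------------------------------
# curvature analysis
# ---------------------------------------------------------------------------

def _spline(points: np.ndarray, closed: bool):
    """Chord-length-parametrized cubic spline through a point list."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise GeometryError("curve needs >= 4 planar control points")
    if closed and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise GeometryError("degenerate curve: repeated control points")
    if closed:
        pts_ext = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts_ext, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        sp = CubicSpline(t, pts_ext, bc_type="periodic")
    else:
        t = np.concatenate([[0.0], np.cumsum(seg)])
        sp = CubicSpline(t, pts, bc_type="not-a-knot")
    return sp, t[-1]


def curvature_profile(points: np.ndarray, n_samples: int = 64,
                      closed: bool = False) -> np.ndarray:
    """Signed curvature sampled uniformly in arc length, mm^-1.

    For open curves the profile is reported in left-to-right (x increasing)
    orientation so that "convex toward anterior" is positive; closed
    contours are taken counter-clockwise, for which the same convention
    holds automatically.
    """
    if n_samples < 16:
        raise ParameterError("n_samples must be >= 16")
    pts = np.asarray(points, dtype=float)
    flip = False
    if not closed and pts[-1, 0] < pts[0, 0]:
        pts = pts[::-1]
    if closed:
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area < 0:
            pts = pts[::-1]
    sp, t_max = _spline(pts, closed)
    # re-parametrize approximately by arc length
    t_dense = np.linspace(0.0, t_max, max(20 * n_samples, 400))
    d = sp(t_dense, 1)
    speed = np.hypot(d[:, 0], d[:, 1])
    s_dense = np.concatenate([[0.0], np.cumsum(
        0.5 * (speed[1:] + speed[:-1]) * np.diff(t_dense))])
    s_targets = np.linspace(0.0, s_dense[-1], n_samples)
    t_s = np.interp(s_targets, s_dense, t_dense)
    d1 = sp(t_s, 1)
    d2 = sp(t_s, 2)
    denom = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    kappa = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / denom
    if not closed:
        # traversal with x increasing: anterior bulge has y'' < 0, so flip
        kappa = -kappa
    return kappa


def is_convex(points: np.ndarray, closed: bool = False,
              tol: float = CONVEXITY_TOL, n_samples: int = 64) -> bool:
    """True iff the minimum sampled signed curvature is >= -tol."""
    return bool(np.min(curvature_profile(points, n_samples, closed)) >= -tol)


# ---------------------------------------------------------------------------
# reference library
# ---------------------------------------------------------------------------

@dataclass
class ReferenceRecord:
    """One healthy chest record: demographics plus the anterior boundary
    curve at the bar level."""

    id: str
    age: float
    gender: str
    transverse_diameter: float
    boundary: np.ndarray  # (m, 2), mm

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.transverse_diameter <= 0:
            raise ParameterError("transverse_diameter must be positive")
        if not is_convex(self.boundary):
            raise GeometryError(
                f"reference {self.id}: boundary is not convex")


@dataclass(frozen=True)
class PatientInfo:
    """The demographic/morphometric facts used for reference matching."""

    age: float
    gender: str
    A_pre: float  # pre-operative transverse diameter, mm


def generate_reference_library(n_records: int = 40, seed: int = 0
                               ) -> list[ReferenceRecord]:
    """Synthesize a healthy-chest reference library.

    Ages 8-25 y, both genders, transverse diameters 180-300 mm; each
    boundary is the anterior arc of a healthy elliptical section whose
    anteroposterior diameter follows the healthy aspect ratio.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_records):
        d = float(rng.uniform(180.0, 300.0))
        age = float(rng.integers(8, 26))
        gender = "M" if rng.random() < 0.5 else "F"
        a, b = d / 2.0, d / 5.0
        x = np.linspace(-0.92 * a, 0.92 * a, 41)
        y = b * np.sqrt(1.0 - (x / a) ** 2)
        out.append(ReferenceRecord(
            id=f"ref{i:03d}", age=age, gender=gender,
            transverse_diameter=d, boundary=np.column_stack([x, y])))
    return out


def select_reference(patient: PatientInfo, library: list[ReferenceRecord],
                     expected_shrinkage: float = 0.95,
                     age_window: float = 3.0) -> ReferenceRecord:
    """Pick the healthy record whose transverse diameter best matches the
    patient's expected post-operative diameter.

    The target diameter is ``A_pre * expected_shrinkage`` (the transverse
    diameter shrinks by ~5% when the sternum is elevated); candidates must
    match gender and lie within ``age_window`` years.  Ties break on the
    smaller age difference, then lexicographic id, so the selection is
    independent of library order.
    """
    if not library:
        raise NoMatchError("reference library is empty")
    if not 0.8 < expected_shrinkage <= 1.05:
        raise ParameterError("expected_shrinkage must lie in (0.8, 1.05]")
    target = patient.A_pre * expected_shrinkage
    candidates = [r for r in library
                  if r.gender == patient.gender
                  and abs(r.age - patient.age) <= age_window]
    if not candidates:
        nearest = sorted(library,
                         key=lambda r: (abs(r.transverse_diameter - target),
                                        r.id))[:3]
        raise NoMatchError(
            f"no {patient.gender} record within +/-{age_window} y of age "
            f"{patient.age}; nearest by diameter: "
            + ", ".join(f"{r.id} (age {r.age}, {r.transverse_diameter:.0f} mm)"
                        for r in nearest))
    return min(candidates,
               key=lambda r: (abs(r.transverse_diameter - target),
                              abs(r.age - patient.age), r.id))


# ---------------------------------------------------------------------------
# bar curve design
# ---------------------------------------------------------------------------

@dataclass
class BarCurve:
    """Planar working shape of a Nuss bar.

    ``span`` is the chord between the bar ends; ``standard_length`` is set
    once the bar has been rounded to a catalogue size; ``apex_height`` is
    the y of the mid-span apex.
    """

    control_points: np.ndarray  # (n, 2), mm
    span: float
    apex_height: float
    standard_length: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        x = self.control_points[:, 0]
        x_apex = x[np.argmax(self.control_points[:, 1])]
        if abs((x_apex - x[0]) - (x[-1] - x_apex)) > 0.05 * self.span + 1e-9:
            raise GeometryError("bar endpoints are not symmetric about "
                                "the apex")

    def min_curvature(self) -> float:
        return float(np.min(curvature_profile(self.control_points)))


def _project_concave(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Euclidean projection of sampled heights onto the concave cone.

    Solves min ||y' - y||^2 subject to nonpositive second differences, the
    discrete statement of convexity toward +y on a uniform-in-x polygon.
    """
    h = np.diff(x)
    n = len(y)

    def second_diffs(v):
        return (v[2:] - v[1:-1]) / h[1:] - (v[1:-1] - v[:-2]) / h[:-1]

    if np.all(second_diffs(y) <= 1e-12):
        return y
    res = minimize(
        lambda v: 0.5 * np.sum((v - y) ** 2), y, jac=lambda v: v - y,
        constraints=[{"type": "ineq",
                      "fun": lambda v: -second_diffs(v)}],
        method="SLSQP", options={"maxiter": 200, "ftol": 1e-12})
    return res.x


def design_bar_curve(reference_boundary: np.ndarray, delta: float,
                     span: float, n_control: int = 21) -> BarCurve:
    """Design the convex bar curve from a healthy reference boundary.

    The curve follows the reference boundary over the central ``span``,
    raised by a half-cosine bump that peaks at ``delta`` mm at the apex and
    vanishes at the bar ends, so that implantation elevates the sternum by
    the orthopedic distance while the ends stay on the healthy profile.
    Non-convex fits are projected onto the nearest convex control polygon.
    """
    if delta < 0:
        raise ParameterError("delta must be >= 0")
    ref = np.asarray(reference_boundary, dtype=float)
    if ref[-1, 0] < ref[0, 0]:
        ref = ref[::-1]
    chord = float(np.linalg.norm(ref[-1] - ref[0]))
    if span > chord + 1e-9:
        raise ParameterError(
            f"span {span:.1f} mm exceeds the reference chord {chord:.1f} mm")
    if span <= 0:
        raise ParameterError("span must be positive")
    if delta >= 0.5 * span:
        raise InfeasibleDesignError(
            f"delta {delta:.1f} mm cannot be realized convexly over a "
            f"{span:.1f} mm span")
    x_ref, y_ref = ref[:, 0], ref[:, 1]
    if np.any(np.diff(x_ref) <= 0):
        raise GeometryError("reference boundary must be x-monotone")
    x_mid = 0.5 * (x_ref[0] + x_ref[-1])
    x = np.linspace(x_mid - span / 2.0, x_mid + span / 2.0, n_control)
    y = np.interp(x, x_ref, y_ref) \
        + delta * np.cos(np.pi * (x - x_mid) / span)
    y = _project_concave(y, x)
    pts = np.column_stack([x, y])
    for _ in range(3):
        if np.min(curvature_profile(pts)) >= -CONVEXITY_TOL:
            break
        # smooth interior points slightly and re-project
        y_s = pts[:, 1].copy()
        y_s[1:-1] = 0.25 * y_s[:-2] + 0.5 * y_s[1:-1] + 0.25 * y_s[2:]
        pts[:, 1] = _project_concave(y_s, x)
    else:
        raise InfeasibleDesignError(
            "could not enforce convexity of the designed bar curve")
    apex = float(pts[n_control // 2, 1])
    return BarCurve(control_points=pts, span=float(span), apex_height=apex,
                    meta={"delta": float(delta)})


def round_to_standard_length(bar: BarCurve,
                             catalogue=DEFAULT_CATALOGUE) -> BarCurve:
    """Round a bar up to the nearest standard catalogue length.

    The shape is rescaled in span only (x about the apex); the apex height
    is preserved exactly.
    """
    if not catalogue:
        raise CatalogueError("catalogue is empty")
    cat = sorted(float(c) for c in catalogue)
    candidates = [c for c in cat if c >= bar.span - 1e-9]
    if not candidates:
        raise CatalogueError(
            f"span {bar.span:.1f} mm exceeds the largest catalogue length "
            f"{cat[-1]:.1f} mm")
    std = candidates[0]
    pts = bar.control_points.copy()
    x_apex = pts[np.argmax(pts[:, 1]), 0]
    pts[:, 0] = x_apex + (pts[:, 0] - x_apex) * (std / bar.span)
    return BarCurve(control_points=pts, span=std, apex_height=bar.apex_height,
                    standard_length=std, meta=dict(bar.meta))
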