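"""Parametric synthetic thorax geometry.

This module replaces CT-derived anatomy with a parametric stand-in: a stack
of planar elliptical rib rings joined by a sternal bar anteriorly and a
rigid spine column posteriorly.  A pectus-excavatum (PEX) variant is derived
from a healthy model by displacing the anterior chest wall posteriorly with
a smooth, purely anteroposterior depression field.

Coordinate convention (right-handed, all lengths in mm):

* ``x`` — laterolateral (patient left positive),
* ``y`` — anteroposterior, **anterior positive**,
* ``z`` — craniocaudal, cranial positive.

Cross sections ``a``–``d`` are the axial planes of intercostal spaces 2–5,
the candidate Nuss-bar placement levels.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError, LandmarkError, ParameterError

#: number of nodes per rib ring (divisible by 4: spine, two lateral, sternum)
RING_NODES = 24
#: craniocaudal spacing between adjacent rib levels, mm
RIB_SPACING = 25.0
#: z of the first (most cranial) rib level, mm
Z_FIRST_RIB = 300.0
#: healthy transverse / anteroposterior diameter ratio (healthy Haller index)
HEALTHY_ASPECT = 2.5
#: fraction of each rib chain (by arc length, anterior end) that is cartilage
CARTILAGE_FRACTION = 0.20

#: intercostal space -> cross-section label
SPACE_TO_SECTION = {2: "a", 3: "b", 4: "c", 5: "d"}
SECTION_TO_SPACE = {v: k for k, v in SPACE_TO_SECTION.items()}
SECTION_LABELS = ("a", "b", "c", "d")


@dataclass
class Segment:
    """A structural member between two nodes."""

    i: int
    j: int
    tissue: str  # "bone" | "cartilage"
    prop_id: str  # cross-section property id: "rib" | "cartilage" | "sternum" | "spine"

    def as_tuple(self) -> tuple[int, int, str, str]:
        return (self.i, self.j, self.tissue, self.prop_id)


@dataclass
class CrossSectionContour:
    """Ordered planar chest-wall boundary at one axial level.

    Points are counter-clockwise in the (x, y) plane.  Two landmark indices
    identify the anterior-most vertebral point and the posterior sternal
    surface point between which the anteroposterior distance B is measured.
    """

    level: str
    points: np.ndarray  # (n, 2), mm
    vertebra_anterior_idx: int
    sternum_posterior_idx: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.points)
        if n < 8:
            raise GeometryError(f"contour needs >= 8 points, got {n}")
        if self.vertebra_anterior_idx == self.sternum_posterior_idx:
            raise LandmarkError("vertebra and sternum landmarks coincide")
        if not (0 <= self.vertebra_anterior_idx < n
                and 0 <= self.sternum_posterior_idx < n):
            raise LandmarkError("landmark index out of range")
        yv = self.points[self.vertebra_anterior_idx, 1]
        ys = self.points[self.sternum_posterior_idx, 1]
        if not yv < ys:
            raise LandmarkError(
                f"vertebral landmark (y={yv:.3f}) must be posterior to the "
                f"sternal landmark (y={ys:.3f})")
        if self._signed_area() <= 0:
            raise GeometryError("contour must be ordered counter-clockwise")
        if not Polygon(self.points).is_valid:
            raise GeometryError("contour polygon is self-intersecting")

    def _signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def anterior_boundary(contour: CrossSectionContour) -> np.ndarray:
    """Anterior chest-wall boundary of a contour, ordered left-to-right.

    The arc runs counter-clockwise from the rightmost to the leftmost point
    (through the sternum); it is returned with x increasing, which is the
    orientation assumed by the curvature sign convention in
    :mod:`nussplan.barshape`.
    """
    pts = contour.points
    n = len(pts)
    i_right = int(np.argmax(pts[:, 0]))
    i_left = int(np.argmin(pts[:, 0]))
    idx = [i_right]
    k = i_right
    while k != i_left:
        k = (k + 1) % n
        idx.append(k)
    if contour.sternum_posterior_idx not in idx:
        raise LandmarkError("sternal landmark not on the anterior arc")
    return pts[idx[::-1]]


@dataclass
class PexParams:
    """Parameters of a synthetic sternal depression.

    ``affected_levels`` are intercostal spaces (subset of 2..5, contiguous).
    The depression acts purely anteroposteriorly; at every affected section
    the anteroposterior distance B is reduced by exactly ``depression_depth``.
    ``asymmetry`` in [-1, 1] skews the lateral extent of the dip (0 =
    symmetric, positive widens the patient-left side).
    """

    depression_depth: float
    depression_halfwidth: float
    affected_levels: tuple[int, ...] = (2, 3, 4, 5)
    asymmetry: float = 0.0

    def __post_init__(self):
        if self.depression_depth < 0:
            raise ParameterError("depression_depth must be >= 0")
        if self.depression_halfwidth <= 0:
            raise ParameterError("depression_halfwidth must be > 0")
        lv = tuple(sorted(set(self.affected_levels)))
        if not lv or not set(lv) <= {2, 3, 4, 5}:
            raise ParameterError("affected_levels must be a subset of {2..5}")
        if lv != tuple(range(lv[0], lv[-1] + 1)):
            raise ParameterError("affected_levels must be contiguous")
        self.affected_levels = lv
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ParameterError("asymmetry must lie in [-1, 1]")

    @property
    def deepest_level(self) -> int:
        """Intercostal space taken as the center of the depression."""
        return self.affected_levels[len(self.affected_levels) // 2]


@dataclass
class ThoraxModel:
    """Node/segment structural model of the simplified thorax.

    The spine is treated as rigid (its nodes are the fixed boundary of every
    simulation); ribs and costal cartilage are elastic chains from the spine
    to the sternal bar.  ``rib_rings`` lists, per rib level, the node ids of
    the closed chest-wall ring in counter-clockwise order starting at the
    spine node.
    """

    nodes: np.ndarray  # (n, 3), mm
    segments: list[Segment]
    spine_nodes: list[int]
    sternum_nodes: list[int]  # ordered cranio-caudally (z decreasing)
    intercostal_anchor: dict[int, int]  # space (2..5) -> sternum node id
    section_levels: dict[str, float]  # section label -> axial height z, mm
    rib_rings: list[list[int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        levels = [self.section_levels[s] for s in SECTION_LABELS
                  if s in self.section_levels]
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise GeometryError("section levels must decrease cranio-caudally")
        stern = set(self.sternum_nodes)
        for space, nid in self.intercostal_anchor.items():
            if nid not in stern:
                raise GeometryError(
                    f"anchor for space {space} is not a sternum node")

    def copy(self) -> "ThoraxModel":
        return ThoraxModel(
            nodes=self.nodes.copy(),
            segments=[Segment(*s.as_tuple()) for s in self.segments],
            spine_nodes=list(self.spine_nodes),
            sternum_nodes=list(self.sternum_nodes),
            intercostal_anchor=dict(self.intercostal_anchor),
            section_levels=dict(self.section_levels),
            rib_rings=[list(r) for r in self.rib_rings],
            meta=_copy.deepcopy(self.meta),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ring_z(self) -> np.ndarray:
        """Axial height of each rib ring (z of its spine node)."""
        return np.array([self.nodes[r[0], 2] for r in self.rib_rings])


# ---------------------------------------------------------------------------
# healthy generator
# ---------------------------------------------------------------------------

def _ring_xy(a: float, b: float) -> np.ndarray:
    """Elliptical ring nodes, CCW from the spine (posterior) point.

    Built from one half and mirrored so bilateral symmetry is exact in
    floating point.
    """
    n = RING_NODES
    t = -np.pi / 2 + 2 * np.pi * np.arange(n // 2 + 1) / n  # spine -> sternum
    half = np.column_stack([a * np.cos(t), b * np.sin(t)])
    half[0, 0] = 0.0   # spine exactly mid-sagittal
    half[-1, 0] = 0.0  # sternum exactly mid-sagittal
    left = half[1:-1][::-1].copy()
    left[:, 0] *= -1.0
    return np.vstack([half, left])


def generate_healthy_thorax(n_ribs: int = 8, scale: float = 250.0,
                            seed: int = 0) -> ThoraxModel:
    """Generate a bilaterally symmetric healthy thorax model.

    Parameters
    ----------
    n_ribs
        Number of rib levels retained by the simplified model (>= 6 so that
        intercostal spaces 2-5 exist).
    scale
        Target transverse (laterolateral) inner diameter at section ``a``
        (intercostal space 2), mm.  Must lie in [150, 350].
    seed
        Seed of the small smooth per-level jitter; identical parameters and
        seed give bit-identical models.
    """
    if n_ribs < 6:
        raise ParameterError("n_ribs must be >= 6")
    if not 150.0 <= scale <= 350.0:
        raise ParameterError("scale must lie in [150, 350] mm")
    rng = np.random.default_rng(seed)

    z_ribs = Z_FIRST_RIB - RIB_SPACING * np.arange(n_ribs)
    u = np.arange(n_ribs) / (n_ribs - 1)
    u_ref = 1.5 / (n_ribs - 1)  # normalized height of section a
    # mild barrel taper pinned (to jitter level) at section a, plus jitter:
    # <=0.1% on the transverse semi-axis, <=2% on the anteroposterior one.
    ja = np.clip(rng.normal(0.0, 5e-4, n_ribs), -1e-3, 1e-3)
    jb = np.clip(rng.normal(0.0, 1e-2, n_ribs), -2e-2, 2e-2)
    a_lv = 0.5 * scale * (1.0 - 0.10 * (u - u_ref) ** 2) * (1.0 + ja)
    b_lv = a_lv / HEALTHY_ASPECT * (1.0 + jb)

    nodes: list[np.ndarray] = []
    segments: list[Segment] = []
    rib_rings: list[list[int]] = []
    for lv in range(n_ribs):
        xy = _ring_xy(a_lv[lv], b_lv[lv])
        base = len(nodes)
        ids = list(range(base, base + RING_NODES))
        nodes.extend(np.array([x, y, z_ribs[lv]]) for x, y in xy)
        rib_rings.append(ids)
        segments.extend(_ring_segments(ids, xy))

    spine_nodes = [r[0] for r in rib_rings]
    for i, j in zip(spine_nodes, spine_nodes[1:]):
        segments.append(Segment(i, j, "bone", "spine"))

    # sternum chain: ring-top nodes plus one node per intercostal space 2-5,
    # each lying on the ruled surface between adjacent rings.
    stern_tops = [r[RING_NODES // 2] for r in rib_rings]
    section_levels: dict[str, float] = {}
    intercostal_anchor: dict[int, int] = {}
    node_arr = list(nodes)
    chain: list[int] = []
    for lv in range(n_ribs):
        chain.append(stern_tops[lv])
        if lv + 1 < n_ribs:
            space = lv + 1  # intercostal space between ribs lv+1 and lv+2
            if space in SPACE_TO_SECTION:
                z_mid = 0.5 * (z_ribs[lv] + z_ribs[lv + 1])
                y_mid = 0.5 * (node_arr[stern_tops[lv]][1]
                               + node_arr[stern_tops[lv + 1]][1])
                nid = len(node_arr)
                node_arr.append(np.array([0.0, y_mid, z_mid]))
                chain.append(nid)
                intercostal_anchor[space] = nid
                section_levels[SPACE_TO_SECTION[space]] = z_mid
    for i, j in zip(chain, chain[1:]):
        segments.append(Segment(i, j, "bone", "sternum"))

    model = ThoraxModel(
        nodes=np.array(node_arr),
        segments=segments,
        spine_nodes=spine_nodes,
        sternum_nodes=chain,
        intercostal_anchor=intercostal_anchor,
        section_levels=section_levels,
        rib_rings=rib_rings,
        meta={"kind": "healthy", "n_ribs": n_ribs, "scale": scale,
              "seed": seed, "rib_spacing": RIB_SPACING},
    )
    return model


def _ring_segments(ids: list[int], xy: np.ndarray) -> list[Segment]:
    """Close a rib ring with segments, tagging the anterior chain cartilage.

    Each half-ring from the spine (index 0) to the sternum (index n/2) is one
    rib chain; the anterior CARTILAGE_FRACTION of its arc length is costal
    cartilage, the rest bone.
    """
    n = len(ids)
    segs: list[Segment] = []
    edge_len = np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)
    # right chain: edges 0..n/2-1 ; left chain: edges n-1..n/2 (reversed)
    for chain_edges in (range(0, n // 2), range(n - 1, n // 2 - 1, -1)):
        edges = list(chain_edges)
        lens = edge_len[edges]
        total = float(np.sum(lens))
        s = np.concatenate([[0.0], np.cumsum(lens)])
        mid = 0.5 * (s[:-1] + s[1:]) / total  # arc position from the spine
        for e, m in zip(edges, mid):
            cart = m >= 1.0 - CARTILAGE_FRACTION
            segs.append(Segment(ids[e], ids[(e + 1) % n],
                                "cartilage" if cart else "bone",
                                "cartilage" if cart else "rib"))
    return segs


# ---------------------------------------------------------------------------
# depression
# ---------------------------------------------------------------------------

def apply_depression(healthy: ThoraxModel, pex: PexParams) -> ThoraxModel:
    """Derive a PEX thorax by depressing the anterior chest wall.

    The displacement field is purely anteroposterior (no x or z coordinate
    changes, so the transverse diameter A is invariant).  Axially it applies
    the full depth across the affected intercostal sections with a cos^2
    taper one rib spacing beyond; laterally it is a cos^2 bump of the given
    half-width; through the ring it is weighted by the squared normalized
    anterior height, so the posterior wall and vertebra never move.
    """
    model = healthy.copy()
    if pex.depression_depth == 0.0:
        return model
    spacing = float(model.meta.get("rib_spacing", RIB_SPACING))
    sect_z = [model.section_levels[SPACE_TO_SECTION[s]]
              for s in pex.affected_levels]
    z_lo, z_hi = min(sect_z) - 1e-9, max(sect_z) + 1e-9

    def q_axial(z: float) -> float:
        if z_lo <= z <= z_hi:
            return 1.0
        d = (z_lo - z) if z < z_lo else (z - z_hi)
        if d >= spacing:
            return 0.0
        return float(np.cos(0.5 * np.pi * d / spacing) ** 2)

    w_r = pex.depression_halfwidth * (1.0 - 0.5 * pex.asymmetry)
    w_l = pex.depression_halfwidth * (1.0 + 0.5 * pex.asymmetry)

    def p_lateral(x: float) -> float:
        w = w_r if x >= 0 else w_l
        if abs(x) >= w:
            return 0.0
        return float(np.cos(0.5 * np.pi * x / w) ** 2)

    b_local = _anterior_height_per_node(model)
    new_nodes = model.nodes.copy()
    for nid in range(model.n_nodes):
        x, y, z = model.nodes[nid]
        if y <= 0 or b_local[nid] <= 0:
            continue
        wgt = min(1.0, y / b_local[nid]) ** 2
        new_nodes[nid, 1] = y - pex.depression_depth * q_axial(z) \
            * p_lateral(x) * wgt
    model.nodes = new_nodes

    # the chest wall must not invert: the sternum has to stay anterior to
    # the vertebral column at every measured section
    for space, nid in model.intercostal_anchor.items():
        z_s = model.section_levels[SPACE_TO_SECTION[space]]
        y_vert = _interp_ring_point(model, z_s, 0)[1]
        if model.nodes[nid, 1] <= y_vert:
            raise GeometryError(
                f"depression depth {pex.depression_depth} mm inverts the "
                f"chest wall at intercostal space {space}")
    model.meta.update({
        "kind": "pex",
        "pex": {"depression_depth": pex.depression_depth,
                "depression_halfwidth": pex.depression_halfwidth,
                "affected_levels": list(pex.affected_levels),
                "asymmetry": pex.asymmetry},
    })
    return model


def _anterior_height_per_node(model: ThoraxModel) -> np.ndarray:
    """Anterior chest-wall height (sternal y) local to each node's level."""
    b = np.zeros(model.n_nodes)
    for ring in model.rib_rings:
        b[ring] = model.nodes[ring[RING_NODES // 2], 1]
    for nid in model.sternum_nodes:
        b[nid] = model.nodes[nid, 1]
    return b


def _interp_ring_point(model: ThoraxModel, z: float, k: int) -> np.ndarray:
    """(x, y) of ring node k linearly interpolated in z between rib rings."""
    zs = model.ring_z()
    if z > zs[0] + 1e-9 or z < zs[-1] - 1e-9:
        raise GeometryError(f"z={z} outside the rib-ring range")
    i = int(np.searchsorted(-zs, -z, side="right")) - 1
    i = min(max(i, 0), len(zs) - 2)
    t = (zs[i] - z) / (zs[i] - zs[i + 1])
    p0 = model.nodes[model.rib_rings[i][k], :2]
    p1 = model.nodes[model.rib_rings[i + 1][k], :2]
    return (1.0 - t) * p0 + t * p1


# ---------------------------------------------------------------------------
# cross-section extraction
# ---------------------------------------------------------------------------

def extract_cross_section(thorax: ThoraxModel, level: str) -> CrossSectionContour:
    """Slice the chest-wall surface at a named section.

    The surface is ruled between adjacent rib rings, so the contour is the
    pointwise z-interpolation of the two bracketing rings; the anterior
    point is replaced by the exact sternal node of that intercostal space
    (the node where the Nuss bar acts), which keeps contour-level and
    model-level anteroposterior distances identical by construction.
    """
    if level not in thorax.section_levels:
        raise KeyError(f"unknown section level {level!r}; "
                       f"have {sorted(thorax.section_levels)}")
    z_s = thorax.section_levels[level]
    pts = np.array([_interp_ring_point(thorax, z_s, k)
                    for k in range(RING_NODES)])
    space = SECTION_TO_SPACE[level]
    anchor = thorax.intercostal_anchor.get(space)
    if anchor is not None:
        pts[RING_NODES // 2] = thorax.nodes[anchor, :2]
    return CrossSectionContour(
        level=level, points=pts,
        vertebra_anterior_idx=0,
        sternum_posterior_idx=RING_NODES // 2,
    )


# ---------------------------------------------------------------------------
# packaged synthetic patient
# ---------------------------------------------------------------------------

#: depression parameters of the packaged synthetic PEX patient: a deep
#: (28 mm), broad (60 mm half-width) symmetric funnel spanning all four
#: candidate intercostal spaces -- severity comparable to a pre-operative
#: Haller index of ~3.5 on a 250 mm chest.
DEFAULT_PEX = dict(depression_depth=28.0, depression_halfwidth=60.0,
                   affected_levels=(2, 3, 4, 5), asymmetry=0.0)


def synthetic_patient(seed: int = 1, n_ribs: int = 8, scale: float = 250.0,
                      pex: PexParams | None = None
                      ) -> tuple[ThoraxModel, ThoraxModel]:
    """Return ``(pex_thorax, healthy_thorax)`` for the packaged test patient.

    The healthy model doubles as the patient's normal-chest reference for
    hypercorrection checks and bar design.
    """
    healthy = generate_healthy_thorax(n_ribs=n_ribs, scale=scale, seed=seed)
    if pex is None:
        pex = PexParams(**DEFAULT_PEX)
    return apply_depression(healthy, pex), healthy
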